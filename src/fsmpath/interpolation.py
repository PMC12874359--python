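"""Chain-of-states interpolation between two frontier geometries.

Two interpolators are provided:

* **RIC** — linear interpolation in the pruned redundant internal
  coordinates, q(f) = (1−f) q_R + f q_P (torsions along the shortest
  signed arc), each point converted back to Cartesians by the iterative
  back-transformation, seeded from the previously converted neighbor.

* **LST** — linear synchronous transit: every node minimizes

      S = Σ_{a>b} (r_ab(f) − r_ab)² / r_ab(f)⁴  +  w Σ_j (x_j(f) − x_j)²

  where r(f) interpolates all N(N−1)/2 internuclear distances, x(f)
  interpolates Cartesians, and the optimized variables are the node's own
  Cartesians.  The second term (weight w, nominally 1e-6) pins rigid
  translation/rotation.  Minimization uses bounded-memory quasi-Newton
  (L-BFGS-B) started from the Cartesian interpolant.

`take_step` walks a given arc distance in from either end of a dense
interpolated path — the node-placement primitive of the string method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .geometry import Geometry, Path
from .internal_coords import (
    BackTransformError,
    ICSystem,
    cartesian_from_internal,
    measure,
    wrap_angle,
)

#: floor on the r(f)⁴ denominator of the LST objective (Å⁴)
LST_DENOM_FLOOR = 0.5**4
LST_MAXITER = 500
LST_GTOL = 1e-8


class InterpolationError(RuntimeError):
    """Interpolation failed; ``partial`` carries the nodes built so far."""

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial


class StringsMeet(Exception):
    """Requested step exceeds the remaining path length: the strings meet."""


@dataclass
class NodeDiagnostics:
    fraction: float
    converged: bool
    residual: float
    n_iter: int = 0


@dataclass
class InterpolationResult:
    path: Path
    fractions: np.ndarray
    diagnostics: list[NodeDiagnostics] = field(default_factory=list)

    def write_xyz(self, filename) -> None:
        from .geometry import write_xyz

        write_xyz(filename, self.path.nodes)

    def write_diagnostics_tsv(self, filename) -> None:
        with open(filename, "w") as fh:
            fh.write("f\tarc\tconverged\tresidual\n")
            for d, a in zip(self.diagnostics, self.path.arc):
                fh.write(f"{d.fraction:.6f}\t{a:.8f}\t{int(d.converged)}\t{d.residual:.3e}\n")


def ric_interpolate(
    left: Geometry, right: Geometry, icsys: ICSystem, nfractions: int
) -> InterpolationResult:
    """Linear interpolation in redundant internals, back-transformed per node.

    Endpoint frames are passed through bit-exactly; interior nodes are
    seeded from their already-converted neighbor walking outward from the
    left frontier.
    """
    if nfractions < 2:
        raise InterpolationError("need at least two fractions")
    if left.symbols != right.symbols:
        raise InterpolationError("endpoints differ in atoms or ordering")
    fs = np.linspace(0.0, 1.0, nfractions)
    qR = measure(left, icsys.primitives)
    qP = measure(right, icsys.primitives)
    dq = qP - qR
    tmask = icsys.torsion_mask
    if tmask.any():
        dq[tmask] = wrap_angle(dq[tmask])

    nodes = [left]
    diags = [NodeDiagnostics(0.0, True, 0.0)]
    for f in fs[1:-1]:
        target = qR + f * dq
        try:
            res = cartesian_from_internal(target, nodes[-1], icsys)
        except BackTransformError as exc:
            raise InterpolationError(
                f"back-transformation failed at f={f:.4f}: {exc}",
                partial=nodes,
            ) from exc
        nodes.append(res.geometry)
        diags.append(NodeDiagnostics(float(f), res.converged, res.residual, res.n_iter))
    nodes.append(right)
    diags.append(NodeDiagnostics(1.0, True, 0.0))
    return InterpolationResult(Path(nodes), fs, diags)


def _lst_objective(x, xi, ri, pairs_i, pairs_j, denom, w):
    x = x.reshape(-1, 3)
    d = x[pairs_i] - x[pairs_j]
    rc = np.linalg.norm(d, axis=1)
    dr = ri - rc
    dx = x.ravel() - xi
    s = float(np.sum(dr * dr / denom) + w * dx @ dx)
    grad = np.zeros_like(x)
    if len(rc):
        coeff = 2.0 * dr / (denom * np.maximum(rc, 1e-12))
        contrib = coeff[:, None] * d
        np.add.at(grad, pairs_i, contrib)
        np.add.at(grad, pairs_j, -contrib)
    g = grad.ravel() + 2.0 * w * dx
    return s, g


def lst_interpolate(
    left: Geometry, right: Geometry, nfractions: int, w: float = 1e-6
) -> InterpolationResult:
    """Linear synchronous transit chain-of-states between two frontiers.

    Each interior node independently minimizes the LST objective from its
    Cartesian-interpolant starting point.  Endpoints pass through
    bit-exactly.  The r(f)⁴ denominator is floored at (0.5 Å)⁴.
    """
    if nfractions < 2:
        raise InterpolationError("need at least two fractions")
    if left.symbols != right.symbols:
        raise InterpolationError("endpoints differ in atoms or ordering")
    n = left.natoms
    fs = np.linspace(0.0, 1.0, nfractions)
    iu = np.triu_indices(n, k=1)
    pairs_i, pairs_j = iu[0], iu[1]
    rR = np.linalg.norm(left.coords[pairs_i] - left.coords[pairs_j], axis=1)
    rP = np.linalg.norm(right.coords[pairs_i] - right.coords[pairs_j], axis=1)
    xL, xR = left.flat, right.flat

    nodes = [left]
    diags = [NodeDiagnostics(0.0, True, 0.0)]
    for f in fs[1:-1]:
        ri = (1 - f) * rR + f * rP
        xi = (1 - f) * xL + f * xR
        denom = np.maximum(ri, LST_DENOM_FLOOR**0.25) ** 4
        res = minimize(
            _lst_objective,
            xi,
            args=(xi, ri, pairs_i, pairs_j, denom, w),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": LST_MAXITER, "maxcor": 10, "gtol": LST_GTOL, "ftol": 1e-15},
        )
        if not np.all(np.isfinite(res.x)):
            raise InterpolationError(
                f"LST minimizer failed at f={f:.4f} (residual {res.fun:.3e})",
                partial=nodes,
            )
        nodes.append(left.with_coords(res.x))
        diags.append(NodeDiagnostics(float(f), bool(res.success), float(res.fun), int(res.nit)))
    nodes.append(right)
    diags.append(NodeDiagnostics(1.0, True, 0.0))
    return InterpolationResult(Path(nodes), fs, diags)


def interpolate(
    left: Geometry,
    right: Geometry,
    nfractions: int,
    method: str = "ric",
    icsys: ICSystem | None = None,
    lst_w: float = 1e-6,
) -> InterpolationResult:
    """Dispatch to the configured interpolator."""
    if method == "ric":
        if icsys is None:
            raise InterpolationError("RIC interpolation needs an ICSystem")
        return ric_interpolate(left, right, icsys, nfractions)
    if method == "lst":
        return lst_interpolate(left, right, nfractions, w=lst_w)
    raise InterpolationError(f"unknown interpolator {method!r}")


def take_step(interp: InterpolationResult, from_left: bool, s: float) -> Geometry:
    """Point at arc distance ``s`` inward from one end of a dense path.

    Located by monotone linear interpolation of the path's arc-length
    parameterization.  Raises :class:`StringsMeet` when ``s`` exceeds the
    remaining path length.
    """
    path = interp.path
    total = path.length
    if s < 0:
        raise ValueError("step must be nonnegative")
    if s > total:
        raise StringsMeet(f"step {s:.4f} Å exceeds path length {total:.4f} Å")
    target = s if from_left else total - s
    if s == 0.0:
        return path.nodes[0] if from_left else path.nodes[-1]
    arc = path.arc
    j = int(np.searchsorted(arc, target, side="right") - 1)
    j = min(max(j, 0), len(path) - 2)
    seg = arc[j + 1] - arc[j]
    if seg <= 1e-15:
        return path.nodes[j]
    t = (target - arc[j]) / seg
    coords = (1 - t) * path.nodes[j].flat + t * path.nodes[j + 1].flat
    return path.nodes[j].with_coords(coords)
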