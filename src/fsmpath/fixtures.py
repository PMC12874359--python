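"""Deterministic synthetic test inputs.

Endpoint geometry pairs with known internal-coordinate values are built
Z-matrix style (NeRF placement), so each template round-trips: measuring
the built geometry reproduces the declared bonds/angles/torsions to
machine precision.  A matched toy-force-field parameter set is available
for the chain templates, making both endpoints (near-)minima of the toy
surface.  All randomness funnels through one seeded NumPy generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .calculators import CosineTorsion, HarmonicAngle, MorseBond, ToyFFSpec
from .geometry import Geometry

#: idealized construction constants (Å / degrees)
IDEAL = {
    "CC_BOND": 1.54,
    "CH_BOND": 1.09,
    "OH_BOND": 0.96,
    "HH_BOND": 0.74,
    "CO_BOND": 1.16,
    "CCC_ANGLE": 111.0,
    "HOH_ANGLE": 104.5,
}

TEMPLATES = (
    "diatomic",
    "bent-triatomic",
    "linear-triatomic",
    "four-atom-torsion",
    "butane-like",
    "two-fragment",
)


@dataclass
class FixtureSpec:
    """Template name + geometric parameters (Å and degrees) + seed."""

    template: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.template not in TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}; choose from {TEMPLATES}")


def _place_nerf(a, b, c, r, theta, phi):
    """Place a new atom at distance r from c, angle theta (new-c-b) and
    torsion phi (new-c-b-a), standard NeRF construction."""
    d2 = np.array(
        [
            -r * np.cos(theta),
            r * np.sin(theta) * np.cos(phi),
            r * np.sin(theta) * np.sin(phi),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.stack([bc, np.cross(n, bc), n], axis=1)
    return c + m @ d2


def _chain(symbols, rs, thetas, phis):
    """Build an open chain from bond lengths, angles and torsions (radians)."""
    n = len(symbols)
    coords = np.zeros((n, 3))
    if n > 1:
        coords[1] = [rs[0], 0.0, 0.0]
    if n > 2:
        coords[2] = coords[1] + [
            -rs[1] * np.cos(thetas[0]),
            rs[1] * np.sin(thetas[0]),
            0.0,
        ]
    for i in range(3, n):
        coords[i] = _place_nerf(
            coords[i - 3], coords[i - 2], coords[i - 1], rs[i - 1], thetas[i - 2], phis[i - 3]
        )
    return Geometry(tuple(symbols), coords)


def build(spec: FixtureSpec) -> Geometry:
    """Construct the geometry a spec describes."""
    p = spec.params
    t = spec.template
    if t == "diatomic":
        r = p.get("r", IDEAL["HH_BOND"])
        sym = tuple(p.get("symbols", ("H", "H")))
        return Geometry(sym, np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]))
    if t == "bent-triatomic":
        r1 = p.get("r1", IDEAL["OH_BOND"])
        r2 = p.get("r2", IDEAL["OH_BOND"])
        ang = np.deg2rad(p.get("angle", IDEAL["HOH_ANGLE"]))
        sym = tuple(p.get("symbols", ("H", "O", "H")))
        return _chain(sym, [r1, r2], [ang], [])
    if t == "linear-triatomic":
        r1 = p.get("r1", IDEAL["CO_BOND"])
        r2 = p.get("r2", IDEAL["CO_BOND"])
        sym = tuple(p.get("symbols", ("O", "C", "O")))
        coords = np.array([[0.0, 0.0, 0.0], [r1, 0.0, 0.0], [r1 + r2, 0.0, 0.0]])
        return Geometry(sym, coords)
    if t in ("four-atom-torsion", "butane-like"):
        if t == "butane-like":
            r = p.get("r", IDEAL["CC_BOND"])
            ang = p.get("angle", IDEAL["CCC_ANGLE"])
            sym = tuple(p.get("symbols", ("C", "C", "C", "C")))
        else:
            r = p.get("r", 1.5)
            ang = p.get("angle", 109.5)
            sym = tuple(p.get("symbols", ("C", "C", "C", "C")))
        tor = np.deg2rad(p.get("torsion", 180.0))
        angr = np.deg2rad(ang)
        return _chain(sym, [r, r, r], [angr, angr], [tor])
    if t == "two-fragment":
        r = p.get("r", IDEAL["HH_BOND"])
        sep = p.get("sep", 5.0)
        sym = tuple(p.get("symbols", ("H", "H", "H", "H")))
        coords = np.array(
            [[0.0, 0.0, 0.0], [r, 0.0, 0.0], [sep, 0.0, 0.0], [sep + r, 0.0, 0.0]]
        )
        return Geometry(sym, coords)
    raise AssertionError(t)


def make_pair(spec_reactant: FixtureSpec, spec_product: FixtureSpec) -> tuple[Geometry, Geometry]:
    """Build a reactant/product endpoint pair sharing template and atoms."""
    if spec_reactant.template != spec_product.template:
        raise ValueError("endpoint specs must share a template")
    r = build(spec_reactant)
    p = build(spec_product)
    if r.symbols != p.symbols:
        raise ValueError("endpoint specs produced different atom orderings")
    return r, p


def perturb(
    geometry: Geometry, rigid: bool = True, noise_sigma: float = 0.0, seed: int = 0
) -> Geometry:
    """Apply a seeded random proper rotation + translation and/or Gaussian
    per-coordinate noise (σ in Å)."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    coords = geometry.coords.copy()
    if rigid:
        rot = Rotation.random(rng=rng)
        shift = rng.uniform(-5.0, 5.0, size=3)
        coords = rot.apply(coords - coords.mean(axis=0)) + coords.mean(axis=0) + shift
    if noise_sigma > 0:
        coords = coords + rng.normal(0.0, noise_sigma, size=coords.shape)
    return geometry.with_coords(coords)


def toyff_for(template: str, params: dict | None = None) -> ToyFFSpec:
    """Toy force field whose minima match a template's idealized internals."""
    params = params or {}
    if template in ("butane-like", "four-atom-torsion"):
        r0 = params.get("r", IDEAL["CC_BOND"] if template == "butane-like" else 1.5)
        theta0 = np.deg2rad(params.get("angle", IDEAL["CCC_ANGLE"] if template == "butane-like" else 109.5))
        return ToyFFSpec(
            bonds=[MorseBond((i, i + 1), 100.0, 2.0, r0) for i in range(3)],
            angles=[
                HarmonicAngle((0, 1, 2), 50.0, theta0),
                HarmonicAngle((1, 2, 3), 50.0, theta0),
            ],
            torsions=[CosineTorsion((0, 1, 2, 3), 5.0, 3, 0.0)],
            eps=0.05,
            sigma=2.0,
        )
    if template == "diatomic":
        r0 = params.get("r", IDEAL["HH_BOND"])
        return ToyFFSpec(bonds=[MorseBond((0, 1), 100.0, 2.0, r0)])
    if template == "bent-triatomic":
        r0 = params.get("r1", IDEAL["OH_BOND"])
        theta0 = np.deg2rad(params.get("angle", IDEAL["HOH_ANGLE"]))
        return ToyFFSpec(
            bonds=[MorseBond((0, 1), 100.0, 2.0, r0), MorseBond((1, 2), 100.0, 2.0, r0)],
            angles=[HarmonicAngle((0, 1, 2), 50.0, theta0)],
        )
    raise ValueError(f"no toy force field defined for template {template!r}")


#: default endpoint pairs emitted by `fsm fixtures` per template
DEFAULT_PAIRS = {
    "diatomic": ({"r": 0.9}, {"r": 1.6}),
    "bent-triatomic": ({"angle": 104.5}, {"angle": 120.0}),
    "linear-triatomic": ({"r1": 1.16, "r2": 1.16}, {"r1": 1.3, "r2": 1.3}),
    "four-atom-torsion": ({"torsion": 180.0}, {"torsion": 60.0}),
    "butane-like": ({"torsion": 180.0}, {"torsion": 60.0}),
    "two-fragment": ({"sep": 5.0}, {"sep": 3.0}),
}
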