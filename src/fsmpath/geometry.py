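"""Molecular geometries, rigid-body alignment, arc lengths and path tangents.

A :class:`Geometry` is an ordered list of element symbols plus Cartesian
coordinates in Å.  A :class:`Path` is an ordered chain of geometries with a
cumulative arc-length parameterization; the arc metric is the plain
Euclidean norm over all 3N Cartesian coordinates (unweighted).  Tangents
along a path come from a natural cubic spline of each coordinate against
arc length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from .data import COVALENT_RADII


class GeometryError(ValueError):
    """Raised for malformed or mismatched geometries/paths."""


@dataclass(frozen=True)
class Geometry:
    """One molecular structure: element symbols + Cartesian coordinates (Å)."""

    symbols: tuple[str, ...]
    coords: np.ndarray  # shape (N, 3), float64, Å

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "symbols", tuple(self.symbols))
        if coords.ndim == 1:
            coords = coords.reshape(-1, 3)
        if coords.shape != (len(self.symbols), 3):
            raise GeometryError(
                f"coords shape {coords.shape} does not match "
                f"{len(self.symbols)} symbols"
            )
        if len(self.symbols) < 1:
            raise GeometryError("geometry needs at least one atom")
        for s in self.symbols:
            if s not in COVALENT_RADII:
                raise GeometryError(f"unknown element symbol {s!r}")
        object.__setattr__(self, "coords", coords)

    @property
    def natoms(self) -> int:
        return len(self.symbols)

    @property
    def flat(self) -> np.ndarray:
        """Coordinates as a flat 3N vector (copy)."""
        return self.coords.ravel().copy()

    def with_coords(self, coords: np.ndarray) -> "Geometry":
        return Geometry(self.symbols, np.asarray(coords, dtype=float).reshape(-1, 3))

    def same_species(self, other: "Geometry") -> bool:
        return self.symbols == other.symbols


@dataclass
class Path:
    """Ordered chain of geometries sharing atom count and element order."""

    nodes: list[Geometry]
    arc: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.nodes) < 1:
            raise GeometryError("path needs at least one node")
        first = self.nodes[0]
        for g in self.nodes[1:]:
            if not first.same_species(g):
                raise GeometryError("path nodes differ in atoms or ordering")
        self.arc = arc_length(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def length(self) -> float:
        return float(self.arc[-1])


def arc_length(nodes: list[Geometry]) -> np.ndarray:
    """Cumulative arc length (Å) of a node chain, starting at 0.

    Segment lengths are Euclidean norms of the 3N-coordinate displacement.
    """
    if len(nodes) < 1:
        raise GeometryError("need at least one node")
    first = nodes[0]
    arc = np.zeros(len(nodes))
    for i in range(1, len(nodes)):
        if not first.same_species(nodes[i]):
            raise GeometryError("inconsistent atoms along path")
        arc[i] = arc[i - 1] + np.linalg.norm(nodes[i].flat - nodes[i - 1].flat)
    return arc


def kabsch_align(reference: Geometry, mobile: Geometry) -> tuple[Geometry, float]:
    """Rigidly superpose ``mobile`` onto ``reference`` (Kabsch algorithm).

    Returns the aligned copy of ``mobile`` and the minimized RMSD in Å.
    The rotation is proper (determinant +1); the reference is unchanged.
    """
    if reference.symbols != mobile.symbols:
        raise GeometryError("cannot align: atom counts or element orders differ")
    ref = reference.coords
    mob = mobile.coords
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    a = ref - ref_c
    b = mob - mob_c
    # align_vectors enforces a proper rotation via the SVD sign guard;
    # collinear/degenerate sets are fine (any optimal rotation will do),
    # so its non-uniqueness warning is suppressed
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rot, rssd = Rotation.align_vectors(a, b)
    aligned = rot.apply(b) + ref_c
    rmsd = float(np.sqrt(np.sum((aligned - ref) ** 2) / reference.natoms))
    return mobile.with_coords(aligned), rmsd


def _spline(nodes: list[Geometry], arc: np.ndarray) -> CubicSpline:
    """Cubic spline of each Cartesian coordinate against arc length.

    Not-a-knot end conditions (so low-order paths are reproduced exactly);
    consecutive nodes with (numerically) identical arc values are collapsed
    so the knot sequence is strictly increasing.
    """
    keep = [0]
    for i in range(1, len(arc)):
        if arc[i] - arc[keep[-1]] > 1e-12:
            keep.append(i)
    if len(keep) < 2:
        raise GeometryError("degenerate path: all nodes coincide")
    x = arc[keep]
    y = np.stack([nodes[i].flat for i in keep], axis=0)
    bc = "not-a-knot" if len(keep) >= 3 else "natural"
    return CubicSpline(x, y, axis=0, bc_type=bc)


def tangent_at_arc(path: Path, s: float) -> np.ndarray:
    """Unit tangent (3N vector) of the path spline at arc position ``s``."""
    if len(path) < 2:
        raise GeometryError("tangent needs at least two nodes")
    if len(path) == 2 or path.length <= 1e-12:
        d = path.nodes[-1].flat - path.nodes[0].flat
        n = np.linalg.norm(d)
        if n <= 1e-12:
            raise GeometryError("degenerate path: endpoints coincide")
        return d / n
    spl = _spline(path.nodes, path.arc)
    t = spl(float(s), 1)
    n = np.linalg.norm(t)
    if n <= 1e-12:
        raise GeometryError(f"vanishing tangent at arc {s}")
    return t / n


def spline_tangent(path: Path, node_index: int) -> np.ndarray:
    """Unit tangent at a path node (cubic spline against arc length).

    For 2-node paths the straight-line secant direction is returned.
    """
    if not 0 <= node_index < len(path):
        raise GeometryError(f"node index {node_index} out of range")
    return tangent_at_arc(path, float(path.arc[node_index]))


# ---------------------------------------------------------------------------
# XYZ I/O (standard format: count line, comment line, "El x y z" records, Å;
# multi-frame files are plain concatenations).


def read_xyz(filename) -> list[Geometry]:
    """Read all frames of a (possibly multi-frame) XYZ file."""
    frames: list[Geometry] = []
    with open(filename) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise GeometryError(f"bad XYZ count line: {lines[i]!r}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise GeometryError("truncated XYZ frame")
        symbols = []
        coords = np.empty((n, 3))
        for j, rec in enumerate(block):
            parts = rec.split()
            symbols.append(parts[0])
            coords[j] = [float(v) for v in parts[1:4]]
        frames.append(Geometry(tuple(symbols), coords))
        i += 2 + n
    if not frames:
        raise GeometryError(f"no XYZ frames in {filename}")
    return frames


def read_single_xyz(filename) -> Geometry:
    frames = read_xyz(filename)
    if len(frames) != 1:
        raise GeometryError(f"expected one frame in {filename}, got {len(frames)}")
    return frames[0]


def write_xyz(filename, geometries, energies=None, comments=None) -> None:
    """Write one or more geometries as (multi-frame) XYZ.

    When ``energies`` is given, each frame's comment line carries the
    energy as ``E=<value>``.
    """
    if isinstance(geometries, Geometry):
        geometries = [geometries]
    with open(filename, "w") as fh:
        for k, g in enumerate(geometries):
            if comments is not None:
                comment = comments[k]
            elif energies is not None and energies[k] is not None:
                comment = f"E={energies[k]:.10f}"
            else:
                comment = ""
            fh.write(f"{g.natoms}\n{comment}\n")
            for sym, (x, y, z) in zip(g.symbols, g.coords):
                fh.write(f"{sym:<3s} {x:18.10f} {y:18.10f} {z:18.10f}\n")
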