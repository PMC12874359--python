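"""Redundant internal coordinates and the delocalized-coordinate machinery.

Primitive internals (bonds, angles, linear bends, torsions, out-of-plane
bends, auxiliary distances) are detected from covalent-radius connectivity,
pruned so every coordinate is well defined at both reaction endpoints, and
assembled into a delocalized nonredundant basis by diagonalizing
G = B Bᵀ, where B is the Wilson matrix Δq = B Δx.  Cartesian geometries
matching a target internal-coordinate vector are recovered by the standard
iterative back-transformation

    x_{k+1} = x_k + (B(x_k)ᵀ)⁻¹ [q_target − q(x_k)]   (delocalized space)

terminated when successive Cartesians agree within 1e-7 Å.

All angular coordinates are in radians, distances in Å.  Torsion
arithmetic is circular: differences are always wrapped into (−π, π].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .data import COVALENT_RADII
from .geometry import Geometry

#: bond when r_ab < BOND_FACTOR * (r_cov(a) + r_cov(b))
BOND_FACTOR = 1.3
#: angles closer than this to π count as linear in the pruning rules
LINEAR_THRESHOLD = np.deg2rad(175.0)
#: a linear bend is dropped when either endpoint bends back past this
LINEAR_BEND_PRUNE = np.deg2rad(135.0)
#: relative eigenvalue cutoff splitting the nonredundant/redundant subspaces
EIG_REL_THRESHOLD = 1e-10
#: back-transformation controls
BT_TOLERANCE = 1e-7  # Å, max Cartesian change between iterates
BT_MAX_ITERS = 100
BT_MAX_STEP = 0.5  # Å per coordinate per iteration

KIND_ARITY = {
    "bond": 2,
    "distance": 2,
    "angle": 3,
    "linear_bend": 3,
    "torsion": 4,
    "out_of_plane": 4,
}


class InternalCoordinateError(ValueError):
    """Raised for undefined or inconsistent internal coordinates."""


class BackTransformError(RuntimeError):
    """Back-transformation diverged; ``best`` carries the best iterate."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


def wrap_angle(x):
    """Wrap angle(s) into (−π, π], elementwise."""
    return -np.remainder(-np.asarray(x) + np.pi, 2 * np.pi) + np.pi


@dataclass(frozen=True)
class PrimitiveIC:
    """One primitive internal coordinate.

    ``axis`` / ``axis_tag`` are only set for linear-bend members: the two
    orthogonal bending directions are fixed once (from the reference
    endpoint) and stored so every geometry along a path measures the bend
    against identical axes.
    """

    kind: str
    atoms: tuple[int, ...]
    axis_tag: int | None = None
    axis: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.kind not in KIND_ARITY:
            raise InternalCoordinateError(f"unknown primitive kind {self.kind!r}")
        if len(self.atoms) != KIND_ARITY[self.kind]:
            raise InternalCoordinateError(
                f"{self.kind} takes {KIND_ARITY[self.kind]} atoms, got {self.atoms}"
            )
        if len(set(self.atoms)) != len(self.atoms):
            raise InternalCoordinateError(f"repeated atom in {self.atoms}")
        if self.kind == "linear_bend" and (self.axis is None or self.axis_tag is None):
            raise InternalCoordinateError("linear bend needs axis and axis_tag")

    @property
    def is_periodic(self) -> bool:
        return self.kind == "torsion"

    def key(self):
        """Canonical identity used for endpoint-union deduplication."""
        a = self.atoms
        if self.kind in ("bond", "distance"):
            a = tuple(sorted(a))
        elif self.kind in ("angle", "linear_bend"):
            a = (min(a[0], a[2]), a[1], max(a[0], a[2]))
        elif self.kind == "torsion":
            if a[0] > a[3]:
                a = a[::-1]
        elif self.kind == "out_of_plane":
            a = (a[0], a[1]) + tuple(sorted(a[2:]))
        return (self.kind, a, self.axis_tag)

    def __str__(self):
        atoms = "-".join(str(i) for i in self.atoms)
        tag = f"[{self.axis_tag}]" if self.axis_tag is not None else ""
        return f"{self.kind}({atoms}){tag}"


# ---------------------------------------------------------------------------
# values and analytic Cartesian derivatives of the primitives


def _unit(v):
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise InternalCoordinateError("zero-length vector in internal coordinate")
    return v / n, n


def _unit_jacobian(v):
    """d(unit(v))/dv = (I − êêᵀ)/|v|."""
    e, n = _unit(v)
    return (np.eye(3) - np.outer(e, e)) / n


def _bond(coords, i, j):
    d = coords[i] - coords[j]
    e, r = _unit(d)
    grad = {i: e, j: -e}
    return r, grad


def _angle(coords, i, j, k):
    """Angle i-j-k at center j, in [0, π]."""
    u, nu = _unit(coords[i] - coords[j])
    v, nv = _unit(coords[k] - coords[j])
    c = float(np.clip(u @ v, -1.0, 1.0))
    theta = float(np.arccos(c))
    s = np.sin(theta)
    if s < 1e-10:
        raise InternalCoordinateError(
            f"angle {i}-{j}-{k} is numerically linear; gradient undefined"
        )
    gi = (c * u - v) / (nu * s)
    gk = (c * v - u) / (nv * s)
    grad = {i: gi, k: gk, j: -(gi + gk)}
    return theta, grad


def _torsion(coords, i, j, k, l):
    """Signed dihedral i-j-k-l in (−π, π] (IUPAC sign convention)."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    sq1 = n1 @ n1
    sq2 = n2 @ n2
    if nb2 < 1e-12 or sq1 < 1e-16 or sq2 < 1e-16:
        raise InternalCoordinateError(
            f"torsion {i}-{j}-{k}-{l} has collinear internal atoms"
        )
    phi = float(np.arctan2(np.cross(n1, n2) @ b2 / nb2, n1 @ n2))
    gi = -nb2 / sq1 * n1
    gl = nb2 / sq2 * n2
    c1 = (b1 @ b2) / (nb2 * nb2)
    c2 = (b3 @ b2) / (nb2 * nb2)
    gj = -(1.0 + c1) * gi + c2 * gl
    gk = c1 * gi - (1.0 + c2) * gl
    return phi, {i: gi, j: gj, k: gk, l: gl}


def _out_of_plane(coords, a, b, c, d):
    """Wilson out-of-plane angle of bond b→a out of the plane (b→c, b→d).

    χ = arcsin( (ê_bc × ê_bd)·ê_ba / sin∠cbd ), in (−π/2, π/2).
    """
    ra = coords[a] - coords[b]
    rc = coords[c] - coords[b]
    rd = coords[d] - coords[b]
    ea, _ = _unit(ra)
    ec, _ = _unit(rc)
    ed, _ = _unit(rd)
    theta, theta_grad = _angle(coords, c, b, d)
    st = np.sin(theta)
    t = float(ea @ np.cross(ec, ed))
    x = t / st
    if abs(x) > 1.0 - 1e-10:
        raise InternalCoordinateError(
            f"out-of-plane {a}-{b}-{c}-{d} at ±90°; gradient undefined"
        )
    chi = float(np.arcsin(np.clip(x, -1.0, 1.0)))
    # dt via unit-vector Jacobians
    Ja = _unit_jacobian(ra)
    Jc = _unit_jacobian(rc)
    Jd = _unit_jacobian(rd)
    dt_a = Ja @ np.cross(ec, ed)
    dt_c = Jc @ np.cross(ed, ea)
    dt_d = Jd @ np.cross(ea, ec)
    dt = {a: dt_a, c: dt_c, d: dt_d, b: -(dt_a + dt_c + dt_d)}
    pref = 1.0 / (st * np.sqrt(1.0 - x * x))
    ct = np.cos(theta)
    grad = {}
    for atom in (a, b, c, d):
        g = dt.get(atom, np.zeros(3)).copy()
        g -= t * ct / st * theta_grad.get(atom, np.zeros(3))
        grad[atom] = pref * g
    return chi, grad


def _linear_bend(coords, prim):
    """Deviation from linearity of A-B-C projected on the stored axis.

    q_w = w · (ê_BA + ê_BC): zero at exact linearity, radian-scale for
    small bends, smooth through the linear configuration.
    """
    i, j, k = prim.atoms
    w = np.asarray(prim.axis)
    ru = coords[i] - coords[j]
    rv = coords[k] - coords[j]
    eu, _ = _unit(ru)
    ev, _ = _unit(rv)
    q = float(w @ (eu + ev))
    Ju = _unit_jacobian(ru)
    Jv = _unit_jacobian(rv)
    gi = Ju @ w
    gk = Jv @ w
    grad = {i: gi, k: gk, j: -(gi + gk)}
    return q, grad


def _evaluate(geometry: Geometry, prim: PrimitiveIC):
    c = geometry.coords
    try:
        if prim.kind in ("bond", "distance"):
            return _bond(c, *prim.atoms)
        if prim.kind == "angle":
            return _angle(c, *prim.atoms)
        if prim.kind == "linear_bend":
            return _linear_bend(c, prim)
        if prim.kind == "torsion":
            return _torsion(c, *prim.atoms)
        return _out_of_plane(c, *prim.atoms)
    except InternalCoordinateError as exc:
        raise InternalCoordinateError(f"{prim}: {exc}") from exc


def measure_one(geometry: Geometry, prim: PrimitiveIC) -> float:
    return _evaluate(geometry, prim)[0]


def measure(geometry: Geometry, primitives) -> np.ndarray:
    """Values of all primitives: Å for bonds/distances, radians otherwise."""
    return np.array([_evaluate(geometry, p)[0] for p in primitives])


def wilson_b_matrix(geometry: Geometry, primitives) -> np.ndarray:
    """Wilson B matrix (n_prim × 3N): row i = ∂q_i/∂x, analytic."""
    n = geometry.natoms
    B = np.zeros((len(primitives), 3 * n))
    for row, prim in enumerate(primitives):
        _, grad = _evaluate(geometry, prim)
        for atom, g in grad.items():
            B[row, 3 * atom : 3 * atom + 3] = g
    return B


# ---------------------------------------------------------------------------
# primitive detection


def bond_graph(geometry: Geometry, factor: float = BOND_FACTOR) -> nx.Graph:
    """Covalent-radius bond graph: edge when r_ab < factor·(r_a + r_b)."""
    g = nx.Graph()
    g.add_nodes_from(range(geometry.natoms))
    c = geometry.coords
    for i, j in itertools.combinations(range(geometry.natoms), 2):
        r = np.linalg.norm(c[i] - c[j])
        rmax = factor * (COVALENT_RADII[geometry.symbols[i]] + COVALENT_RADII[geometry.symbols[j]])
        if r < rmax:
            g.add_edge(i, j)
    return g


def _connect_fragments(geometry: Geometry, graph: nx.Graph) -> list[tuple[int, int]]:
    """Auxiliary distances joining disconnected fragments.

    For every pair of fragments the single closest atom pair is a
    candidate; candidates are added in order of increasing distance until
    the graph (bonds + auxiliaries) is connected — a minimum-spanning
    connection of the fragment graph.
    """
    comps = [sorted(c) for c in nx.connected_components(graph)]
    if len(comps) == 1:
        return []
    c = geometry.coords
    candidates = []
    for (ia, ca), (ib, cb) in itertools.combinations(enumerate(comps), 2):
        best = min(
            ((np.linalg.norm(c[a] - c[b]), a, b) for a in ca for b in cb),
            key=lambda t: t[0],
        )
        candidates.append((best[0], ia, ib, (min(best[1], best[2]), max(best[1], best[2]))))
    candidates.sort()
    uf = {i: i for i in range(len(comps))}

    def find(i):
        while uf[i] != i:
            uf[i] = uf[uf[i]]
            i = uf[i]
        return i

    links = []
    for _, ia, ib, pair in candidates:
        ra, rb = find(ia), find(ib)
        if ra != rb:
            uf[ra] = rb
            links.append(pair)
    return sorted(links)


def detect_primitives(geometry: Geometry, factor: float = BOND_FACTOR) -> list[PrimitiveIC]:
    """Assign bonds, angles, torsions and out-of-plane bends.

    Bonds come from the covalent-radius criterion; fragments are joined by
    shortest inter-fragment auxiliary distances; angles for every bonded
    A-B-C; torsions for every bonded A-B-C-D path; one out-of-plane bend at
    each trivalent center.  Near-linear replacements/pruning happen later,
    in :func:`build_ic_system`, where both endpoints are known.
    """
    if geometry.natoms < 2:
        raise InternalCoordinateError("need at least two atoms")
    graph = bond_graph(geometry, factor)
    prims: list[PrimitiveIC] = [
        PrimitiveIC("bond", (i, j)) for i, j in sorted(tuple(sorted(e)) for e in graph.edges)
    ]
    prims += [PrimitiveIC("distance", pair) for pair in _connect_fragments(geometry, graph)]
    for b in sorted(graph.nodes):
        nbrs = sorted(graph.neighbors(b))
        for a, c in itertools.combinations(nbrs, 2):
            prims.append(PrimitiveIC("angle", (a, b, c)))
    for b, c in sorted(tuple(sorted(e)) for e in graph.edges):
        for ordered in ((b, c), (c, b)):
            bb, cc = ordered
            for a in sorted(graph.neighbors(bb)):
                if a == cc:
                    continue
                for d in sorted(graph.neighbors(cc)):
                    if d == bb or d == a:
                        continue
                    t = (a, bb, cc, d)
                    if t[0] > t[3]:
                        continue  # canonical direction; mirror comes from the other loop
                    prims.append(PrimitiveIC("torsion", t))
    seen = set()
    unique = []
    for p in prims:
        if p.key() not in seen:
            seen.add(p.key())
            unique.append(p)
    for b in sorted(graph.nodes):
        nbrs = sorted(graph.neighbors(b))
        if len(nbrs) == 3:
            unique.append(PrimitiveIC("out_of_plane", (nbrs[0], b, nbrs[1], nbrs[2])))
    return unique


# ---------------------------------------------------------------------------
# endpoint union + pruning + delocalization


@dataclass
class ICSystem:
    """Pruned endpoint-union primitive set plus the delocalized basis U."""

    primitives: list[PrimitiveIC]
    U: np.ndarray  # n_prim × m, orthonormal columns
    eig_threshold: float
    prune_log: list[str] = field(default_factory=list)

    @property
    def n_dlc(self) -> int:
        return self.U.shape[1]

    @property
    def torsion_mask(self) -> np.ndarray:
        return np.array([p.is_periodic for p in self.primitives])

    def report(self, reactant: Geometry | None = None, product: Geometry | None = None) -> str:
        """Plain-text dump of the primitive list and prune log."""
        lines = ["# primitives"]
        for p in self.primitives:
            vals = ""
            if reactant is not None and product is not None:
                vR = measure_one(reactant, p)
                vP = measure_one(product, p)
                vals = f"  {vR:12.6f} {vP:12.6f}"
            lines.append(f"{p}{vals}")
        lines.append(f"# delocalized dimension: {self.n_dlc}")
        lines.append("# prune log")
        lines.extend(self.prune_log or ["(nothing pruned)"])
        return "\n".join(lines)


def _linear_bend_axes(geometry: Geometry, a: int, c: int) -> list[np.ndarray]:
    """Two orthonormal bending axes ⟂ to the A–C direction.

    The first axis is the lab axis most perpendicular to A–C, projected and
    normalized; the second is the cross product.  Deterministic, and stored
    in the primitives so all geometries use identical axes.
    """
    d, _ = _unit(geometry.coords[c] - geometry.coords[a])
    lab = np.eye(3)
    pick = int(np.argmin(np.abs(lab @ d)))
    w0 = lab[pick] - (lab[pick] @ d) * d
    w0 /= np.linalg.norm(w0)
    w1 = np.cross(d, w0)
    return [w0, w1]


def _angle_at(geom: Geometry, i, j, k) -> float:
    u, _ = _unit(geom.coords[i] - geom.coords[j])
    v, _ = _unit(geom.coords[k] - geom.coords[j])
    return float(np.arccos(np.clip(u @ v, -1.0, 1.0)))


def _torsion_defined(geom: Geometry, t) -> bool:
    a, b, c, d = t
    return (
        _angle_at(geom, a, b, c) < LINEAR_THRESHOLD
        and _angle_at(geom, b, c, d) < LINEAR_THRESHOLD
    )


def build_ic_system(
    reactant: Geometry,
    product: Geometry,
    factor: float = BOND_FACTOR,
    eig_rel_threshold: float = EIG_REL_THRESHOLD,
) -> ICSystem:
    """Union the endpoint primitive sets, prune, and delocalize.

    Pruning rules (each applied to both endpoints):

    a. angles ≥ 175° in either endpoint → replaced by two orthogonal
       linear-bend coordinates (axes fixed from the reactant geometry);
    b. linear bends whose angle deviates from linearity by more than 45°
       (∠ABC < 135°) in either endpoint are dropped;
    c. torsions with |∠ABCD| ≥ 175° in either endpoint → removed, an A–D
       distance coordinate added;
    d. torsions with an internal bend ∠ABC or ∠BCD ≥ 175° → removed;
    e. out-of-plane bends whose improper dihedral is ≥ 175° in either
       endpoint, or whose center changes its bond set between endpoints,
       are removed;
    f. if N > 3 and no torsion survives, atom 4-tuples are scanned in a
       deterministic order for one whose internal bends stay below 175°
       in both endpoints;
    g. failing that, the whole set is replaced by all unique atom–atom
       distances.

    The delocalized basis U is built on the reactant geometry.
    """
    if reactant.symbols != product.symbols:
        raise InternalCoordinateError("endpoints differ in atoms or ordering")
    log: list[str] = []
    union: list[PrimitiveIC] = []
    seen = set()
    for p in detect_primitives(reactant, factor) + detect_primitives(product, factor):
        if p.key() not in seen:
            seen.add(p.key())
            union.append(p)

    gR = bond_graph(reactant, factor)
    gP = bond_graph(product, factor)
    broken_centers = {
        b for b in gR.nodes if set(gR.neighbors(b)) != set(gP.neighbors(b))
    }

    kept: list[PrimitiveIC] = []
    extra: list[PrimitiveIC] = []
    for p in union:
        if p.kind == "angle":
            a, b, c = p.atoms
            if max(_angle_at(reactant, a, b, c), _angle_at(product, a, b, c)) >= LINEAR_THRESHOLD:
                log.append(f"{p}: near-linear angle -> two linear bends")
                axes = _linear_bend_axes(reactant, a, c)
                for tag, w in enumerate(axes):
                    lb = PrimitiveIC("linear_bend", (a, b, c), axis_tag=tag, axis=tuple(w))
                    # rule (b): deviation from linearity > 45° in either endpoint
                    if min(_angle_at(reactant, a, b, c), _angle_at(product, a, b, c)) < LINEAR_BEND_PRUNE:
                        log.append(f"{lb}: bends past 45° from linear -> pruned")
                    else:
                        extra.append(lb)
                continue
        elif p.kind == "torsion":
            a, b, c, d = p.atoms
            if not (_torsion_defined(reactant, p.atoms) and _torsion_defined(product, p.atoms)):
                log.append(f"{p}: internal bend near-linear -> pruned")
                continue
            phiR = measure_one(reactant, p)
            phiP = measure_one(product, p)
            if max(abs(phiR), abs(phiP)) >= LINEAR_THRESHOLD:
                log.append(f"{p}: |torsion| >= 175deg -> replaced by distance {a}-{d}")
                dp = PrimitiveIC("distance", (min(a, d), max(a, d)))
                if dp.key() not in seen:
                    seen.add(dp.key())
                    extra.append(dp)
                continue
        elif p.kind == "out_of_plane":
            a, b, c, d = p.atoms
            if b in broken_centers:
                log.append(f"{p}: center {b} changes bonding -> pruned")
                continue
            try:
                impR = abs(_torsion(reactant.coords, a, b, c, d)[0])
                impP = abs(_torsion(product.coords, a, b, c, d)[0])
            except InternalCoordinateError:
                log.append(f"{p}: degenerate improper -> pruned")
                continue
            if max(impR, impP) >= LINEAR_THRESHOLD:
                log.append(f"{p}: improper >= 175deg -> pruned")
                continue
        kept.append(p)
    kept.extend(extra)

    n = reactant.natoms
    if n > 3 and not any(p.kind == "torsion" for p in kept):
        found = None
        for t in itertools.permutations(range(n), 4):
            if t[0] > t[3]:
                continue
            try:
                if _torsion_defined(reactant, t) and _torsion_defined(product, t):
                    if abs(_torsion(reactant.coords, *t)[0]) < LINEAR_THRESHOLD and abs(
                        _torsion(product.coords, *t)[0]
                    ) < LINEAR_THRESHOLD:
                        found = t
                        break
            except InternalCoordinateError:
                continue
        if found is not None:
            log.append(f"no torsions survived; recovered torsion {found}")
            kept.append(PrimitiveIC("torsion", found))
        else:
            log.append("no valid torsion exists; falling back to all atom-atom distances")
            kept = [
                PrimitiveIC("distance", (i, j))
                for i, j in itertools.combinations(range(n), 2)
            ]

    # final sanity: every primitive finite at both endpoints
    measure(reactant, kept)
    measure(product, kept)

    Bprim = wilson_b_matrix(reactant, kept)
    U, _ = delocalize(Bprim, eig_rel_threshold)
    eig_thr = eig_rel_threshold * float(
        np.linalg.eigvalsh(Bprim @ Bprim.T)[-1]
    )
    return ICSystem(primitives=kept, U=U, eig_threshold=eig_thr, prune_log=log)


def delocalize(Bprim: np.ndarray, eig_rel_threshold: float = EIG_REL_THRESHOLD):
    """Split G = BᵖʳⁱᵐBᵖʳⁱᵐᵀ into nonredundant/redundant subspaces.

    Returns (U, B) with U the eigenvectors of G above the cutoff
    (orthonormal columns, n_prim × m) and B = Uᵀ Bᵖʳⁱᵐ the delocalized
    Wilson matrix.
    """
    Bprim = np.atleast_2d(np.asarray(Bprim, dtype=float))
    if Bprim.size == 0:
        raise InternalCoordinateError("empty primitive B matrix")
    G = Bprim @ Bprim.T
    w, V = np.linalg.eigh(G)
    thr = eig_rel_threshold * w[-1]
    if w[-1] <= 0 or not np.any(w > thr):
        raise InternalCoordinateError("degenerate coordinate system: G has no "
                                      "eigenvalues above threshold")
    keep = w > thr
    U = V[:, keep]
    # deterministic eigenvector signs: largest-|component| entry positive
    for col in range(U.shape[1]):
        pivot = np.argmax(np.abs(U[:, col]))
        if U[pivot, col] < 0:
            U[:, col] = -U[:, col]
    return U, U.T @ Bprim


def b_pseudo_inverse(B: np.ndarray) -> np.ndarray:
    """(Bᵀ)⁻¹ = (BBᵀ)⁻¹B for a full-row-rank delocalized B (m × 3N)."""
    B = np.atleast_2d(np.asarray(B, dtype=float))
    BBt = B @ B.T
    try:
        return np.linalg.solve(BBt, B)
    except np.linalg.LinAlgError as exc:
        raise InternalCoordinateError("singular BBᵀ in pseudo-inverse") from exc


@dataclass
class BackTransformResult:
    geometry: Geometry
    converged: bool
    n_iter: int
    residual: float  # |Δq_dlc| at the returned iterate


def cartesian_from_internal(
    target_q: np.ndarray,
    start: Geometry,
    icsys: ICSystem,
    tol: float = BT_TOLERANCE,
    max_iters: int = BT_MAX_ITERS,
    max_step: float = BT_MAX_STEP,
) -> BackTransformResult:
    """Iteratively find Cartesians whose internals match ``target_q``.

    ``target_q`` is a primitive-space vector (same ordering as
    ``icsys.primitives``); each iteration wraps torsion differences into
    (−π, π], projects into the delocalized basis, and applies
    Δx = (Bᵀ)⁻¹ Δq^dlc with B rebuilt at the current iterate.  Converged
    when the largest per-coordinate change drops below ``tol`` Å; on
    non-convergence the smallest-residual iterate is returned flagged as
    approximate; on sustained residual growth a
    :class:`BackTransformError` carrying the best iterate is raised.
    """
    target_q = np.asarray(target_q, dtype=float)
    if target_q.shape != (len(icsys.primitives),):
        raise InternalCoordinateError(
            f"target has {target_q.shape} entries for {len(icsys.primitives)} primitives"
        )
    tmask = icsys.torsion_mask
    x = start.flat
    best = None
    grow_streak = 0
    prev_res = np.inf
    for it in range(1, max_iters + 1):
        geom = start.with_coords(x)
        q = measure(geom, icsys.primitives)
        dq = target_q - q
        if tmask.any():
            dq[tmask] = wrap_angle(dq[tmask])
        dq_dlc = icsys.U.T @ dq
        res = float(np.linalg.norm(dq_dlc))
        if best is None or res < best.residual:
            best = BackTransformResult(geom, False, it, res)
        if res > prev_res * (1 + 1e-12):
            grow_streak += 1
            if grow_streak >= 10 and res > 10 * best.residual:
                raise BackTransformError(
                    f"back-transformation diverging (residual {res:.3e})", best=best
                )
        else:
            grow_streak = 0
        prev_res = res
        Bprim = wilson_b_matrix(geom, icsys.primitives)
        B = icsys.U.T @ Bprim
        dx = b_pseudo_inverse(B).T @ dq_dlc
        np.clip(dx, -max_step, max_step, out=dx)
        x = x + dx
        if np.max(np.abs(dx)) < tol:
            final = start.with_coords(x)
            qf = measure(final, icsys.primitives)
            dqf = target_q - qf
            if tmask.any():
                dqf[tmask] = wrap_angle(dqf[tmask])
            return BackTransformResult(final, True, it, float(np.linalg.norm(icsys.U.T @ dqf)))
    return best
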