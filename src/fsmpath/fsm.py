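"""The freezing string method.

Two strings grow inward from reactant and product.  Each cycle:

1. interpolate a dense path between the current frontier nodes (RIC or
   LST);
2. if the frontier gap has shrunk to the join threshold, stop;
3. otherwise place new nodes an arc distance *s* in from each frontier,
   take tangents from a cubic spline through the interpolated pathway,
   relax each new node perpendicular to its tangent (bounded quasi-Newton
   with a backtracking line search, at most ``n_opt`` steps of at most
   ``n_ls`` energy/gradient calls each), and freeze it.

The step size *s* is the arc length of the initial interpolated
reactant→product path divided by the nominal node count.  Frozen nodes
never move again; the highest-energy node of the joined string is the
transition-state guess.  Nodes are optimized once and never revisited,
which is what makes the method cheap compared with methods that relax the
whole string.
"""

from __future__ import annotations

import hashlib
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .calculators import Calculator, CalculatorError
from .geometry import Geometry, Path, kabsch_align, tangent_at_arc
from .internal_coords import ICSystem, build_ic_system
from .interpolation import (
    InterpolationError,
    InterpolationResult,
    StringsMeet,
    interpolate,
    take_step,
)


class FSMError(RuntimeError):
    pass


@dataclass
class FSMConfig:
    """Run configuration for the freezing string method.

    Defaults follow the conservative operational settings: nominally 18
    nodes, two optimization steps per new node, at most three line-search
    energy/gradient calls per step, and a 0.3 Å per-coordinate cap on any
    single optimization step.
    """

    n_nodes: int = 18
    n_opt: int = 2
    n_ls: int = 3
    max_disp: float = 0.3  # Å, per coordinate, per optimization step
    interpolator: str = "ric"  # "ric" | "lst"
    grad_tol: float = 1e-4  # max-norm of g⊥ for early node convergence
    join_threshold: float = 1.5  # strings meet when gap <= this × s
    nfractions: int = 21  # dense-grid size per frontier-pair segment
    lst_w: float = 1e-6
    align: bool = True
    seed: int = 0  # plumbing for seeded components; the core loop is deterministic

    def __post_init__(self):
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be at least 3")
        if self.n_opt < 0:
            raise ValueError("n_opt must be nonnegative")
        if self.n_ls < 1:
            raise ValueError("n_ls must be at least 1")
        if self.max_disp <= 0:
            raise ValueError("max_disp must be positive")
        if self.interpolator not in ("ric", "lst"):
            raise ValueError(f"unknown interpolator {self.interpolator!r}")

    def to_yaml(self, filename) -> None:
        with open(filename, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, filename) -> "FSMConfig":
        with open(filename) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class NodeOptResult:
    geometry: Geometry
    evals: int
    energy: float
    gradient: np.ndarray
    converged: bool
    failed: bool = False
    steps: list[np.ndarray] = field(default_factory=list)  # accepted displacements


@dataclass
class StringState:
    """The two growing half-strings plus bookkeeping.

    ``left_nodes`` grows from the reactant, ``right_nodes`` from the
    product; both store frozen geometries only.  ``grad_calls`` mirrors the
    calculator's own evaluation counter at all times.
    """

    left_nodes: list[Geometry] = field(default_factory=list)
    right_nodes: list[Geometry] = field(default_factory=list)
    left_energies: list[float] = field(default_factory=list)
    right_energies: list[float] = field(default_factory=list)
    s: float = 0.0
    grad_calls: int = 0
    status: str = "growing"  # growing | joined | failed
    node_evals: list[int] = field(default_factory=list)
    step_infnorms: list[float] = field(default_factory=list)  # per accepted opt step
    tangents: list[np.ndarray] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[Geometry]:
        return self.left_nodes + list(reversed(self.right_nodes))

    @property
    def energies(self) -> list[float]:
        return self.left_energies + list(reversed(self.right_energies))

    def path(self) -> Path:
        return Path(self.nodes)

    def profile(self) -> list[tuple[int, float, float]]:
        """(node index, arc length Å, energy) rows, reactant → product."""
        p = self.path()
        return [(i, float(p.arc[i]), e) for i, e in enumerate(self.energies)]

    def coordinate_hashes(self) -> list[str]:
        return [
            hashlib.sha256(np.ascontiguousarray(g.coords).tobytes()).hexdigest()
            for g in self.nodes
        ]


def perpendicular_gradient(g: np.ndarray, t: np.ndarray) -> np.ndarray:
    """g⊥ = (I − t̂t̂ᵀ) g — the gradient component orthogonal to the path."""
    g = np.asarray(g, dtype=float)
    t = np.asarray(t, dtype=float)
    if abs(np.linalg.norm(t) - 1.0) > 1e-8:
        raise FSMError("tangent is not unit-normalized")
    return g - (t @ g) * t


def _initial_interpolation(
    reactant: Geometry, product: Geometry, config: FSMConfig, icsys: ICSystem | None
) -> InterpolationResult:
    return interpolate(
        reactant,
        product,
        config.nfractions,
        method=config.interpolator,
        icsys=icsys,
        lst_w=config.lst_w,
    )


def compute_step_size(
    reactant: Geometry,
    product: Geometry,
    config: FSMConfig,
    icsys: ICSystem | None = None,
) -> float:
    """s = arc length of the initial interpolated path / n_nodes."""
    if config.interpolator == "ric" and icsys is None:
        icsys = build_ic_system(reactant, product)
    interp = _initial_interpolation(reactant, product, config, icsys)
    total = interp.path.length
    if total <= 1e-10:
        raise FSMError("identical endpoints: zero-length interpolated path")
    return total / config.n_nodes


def _two_loop(memory, g):
    """L-BFGS two-loop recursion; returns the quasi-Newton direction −H·g."""
    if not memory:
        return -g
    q = g.copy()
    alphas = []
    for s_v, y_v, rho in reversed(memory):
        a = rho * (s_v @ q)
        alphas.append(a)
        q -= a * y_v
    s_v, y_v, rho = memory[-1]
    q *= (s_v @ y_v) / (y_v @ y_v)
    for (s_v, y_v, rho), a in zip(memory, reversed(alphas)):
        b = rho * (y_v @ q)
        q += (a - b) * s_v
    return -q


def optimize_node(
    node: Geometry,
    tangent: np.ndarray,
    calculator: Calculator,
    config: FSMConfig,
) -> NodeOptResult:
    """Relax one node in the subspace perpendicular to its tangent.

    Bounded quasi-Newton (limited memory, 10 correction pairs) on the
    Cartesian coordinates, with the gradient replaced by g⊥; the tangent
    is held fixed for the node's whole optimization.  Each step is bounded
    per coordinate by ``max_disp`` relative to the step's starting point,
    and its length is set by a backtracking Armijo line search using at
    most ``n_ls`` energy/gradient evaluations; on exhaustion the best
    energy seen is accepted.  Stops early when max-norm(g⊥) < grad_tol.
    Total evaluations obey evals ≤ max(1, n_opt·(1 + n_ls)).
    """
    t = np.asarray(tangent, dtype=float)
    if abs(np.linalg.norm(t) - 1.0) > 1e-8:
        raise FSMError("tangent is not unit-normalized")

    try:
        res = calculator.evaluate(node)
    except CalculatorError:
        return NodeOptResult(node, 1, np.nan, np.full(3 * node.natoms, np.nan),
                             False, failed=True)
    evals = 1
    x = node.flat
    energy, grad = res.energy, res.gradient
    if not np.isfinite(energy) or not np.all(np.isfinite(grad)):
        return NodeOptResult(node, evals, energy, grad, False, failed=True)
    gperp = perpendicular_gradient(grad, t)
    steps: list[np.ndarray] = []
    converged = float(np.max(np.abs(gperp))) < config.grad_tol
    if config.n_opt == 0 or converged:
        return NodeOptResult(node, evals, energy, grad, converged, steps=steps)

    memory: deque = deque(maxlen=10)
    for _ in range(config.n_opt):
        d = _two_loop(list(memory), gperp)
        if d @ gperp >= 0:  # safeguard: fall back to steepest descent
            d = -gperp
        dmax = float(np.max(np.abs(d)))
        if dmax <= 1e-15:
            break
        alpha = min(1.0, config.max_disp / dmax)
        slope = float(gperp @ d)
        best = None  # (energy, x, grad, alpha)
        accepted = None
        for _ls in range(config.n_ls):
            xt = x + alpha * d
            try:
                rt = calculator.evaluate(node.with_coords(xt))
            except CalculatorError:
                return NodeOptResult(node.with_coords(x), evals, energy, grad,
                                     False, failed=True, steps=steps)
            evals += 1
            if not np.isfinite(rt.energy) or not np.all(np.isfinite(rt.gradient)):
                return NodeOptResult(node.with_coords(x), evals, energy, grad,
                                     False, failed=True, steps=steps)
            if best is None or rt.energy < best[0]:
                best = (rt.energy, xt, rt.gradient, alpha)
            if rt.energy <= energy + 1e-4 * alpha * slope:  # Armijo
                accepted = (rt.energy, xt, rt.gradient, alpha)
                break
            # backtrack to the minimizer of the quadratic through E(0),
            # slope and the rejected E(alpha); safeguarded into [0.05, 0.5]·alpha
            denom = rt.energy - energy - slope * alpha
            if denom > 0:
                alpha_q = -slope * alpha * alpha / (2.0 * denom)
                alpha = float(np.clip(alpha_q, 0.05 * alpha, 0.5 * alpha))
            else:
                alpha *= 0.5
        if accepted is None:
            # line search exhausted: accept the best-seen point if it improves
            if best is not None and best[0] < energy:
                accepted = best
            else:
                break
        new_energy, new_x, new_grad, used_alpha = accepted
        new_gperp = perpendicular_gradient(new_grad, t)
        s_v = new_x - x
        y_v = new_gperp - gperp
        if s_v @ y_v > 1e-12:
            memory.append((s_v, y_v, 1.0 / (s_v @ y_v)))
        steps.append(s_v)
        x, energy, grad, gperp = new_x, new_energy, new_grad, new_gperp
        if float(np.max(np.abs(gperp))) < config.grad_tol:
            converged = True
            break
    return NodeOptResult(node.with_coords(x), evals, energy, grad, converged, steps=steps)


def run_fsm(
    reactant: Geometry,
    product: Geometry,
    calculator: Calculator,
    config: FSMConfig | None = None,
    on_cycle=None,
) -> tuple[StringState, Geometry | None]:
    """Grow a freezing string from reactant and product; return the state
    and the highest-energy node as the transition-state guess.

    ``on_cycle(state)``, when given, is invoked after every growth cycle
    (progress reporting, convergence monitoring, ...).
    """
    config = config or FSMConfig()
    if reactant.symbols != product.symbols:
        raise FSMError("reactant and product differ in atoms or ordering")

    state = StringState()
    if config.align and reactant.natoms > 1:
        product, rmsd = kabsch_align(reactant, product)
        state.log.append(f"aligned product onto reactant (rmsd {rmsd:.6f} Å)")

    icsys = None
    if config.interpolator == "ric":
        if reactant.natoms < 2:
            raise FSMError("RIC interpolation needs at least two atoms; use lst")
        icsys = build_ic_system(reactant, product)
        state.log.append(
            f"IC system: {len(icsys.primitives)} primitives, {icsys.n_dlc} delocalized"
        )

    def fail(msg):
        state.status = "failed"
        state.grad_calls = calculator.eval_count
        state.log.append(f"FAILED: {msg}")
        return state, _ts_guess(state)

    # endpoint energies (once, at startup); endpoints are ts-guess candidates
    try:
        eR = calculator.evaluate(reactant)
        eP = calculator.evaluate(product)
    except CalculatorError as exc:
        return fail(f"endpoint evaluation failed: {exc}")
    if not (np.isfinite(eR.energy) and np.isfinite(eP.energy)):
        return fail("non-finite endpoint energy")
    state.left_nodes.append(reactant)
    state.right_nodes.append(product)
    state.left_energies.append(eR.energy)
    state.right_energies.append(eP.energy)
    state.node_evals.extend([1, 1])
    state.log.append(f"endpoints: E_R={eR.energy:.8f} E_P={eP.energy:.8f}")

    state.s = compute_step_size(reactant, product, config, icsys)
    state.log.append(f"step size s = {state.s:.6f} Å (n_nodes={config.n_nodes})")

    max_cycles = 5 * config.n_nodes
    for cycle in range(max_cycles):
        left_f = state.left_nodes[-1]
        right_f = state.right_nodes[-1]
        try:
            interp = interpolate(
                left_f,
                right_f,
                config.nfractions,
                method=config.interpolator,
                icsys=icsys,
                lst_w=config.lst_w,
            )
        except InterpolationError as exc:
            return fail(f"interpolation failed in cycle {cycle}: {exc}")
        gap = interp.path.length
        state.log.append(f"cycle {cycle}: frontier gap {gap:.6f} Å")
        if gap <= config.join_threshold * state.s:
            state.status = "joined"
            state.log.append("strings meet")
            break

        def place(from_left: bool, arc_s: float):
            new = take_step(interp, from_left, arc_s)
            pos = arc_s if from_left else gap - arc_s
            tan = tangent_at_arc(interp.path, pos)
            opt = optimize_node(new, tan, calculator, config)
            state.tangents.append(tan)
            state.node_evals.append(opt.evals)
            state.step_infnorms.extend(float(np.max(np.abs(s))) for s in opt.steps)
            return opt

        try:
            if gap < 2.0 * state.s:
                # room for only one more node: single midpoint from the left
                opt = place(True, gap / 2.0)
                if opt.failed:
                    return fail("node optimization failed (midpoint)")
                state.left_nodes.append(opt.geometry)
                state.left_energies.append(opt.energy)
                state.log.append(
                    f"  midpoint node: E={opt.energy:.8f} evals={opt.evals}"
                )
                if on_cycle is not None:
                    on_cycle(state)
                continue
            opt_l = place(True, state.s)
            if opt_l.failed:
                return fail("node optimization failed (left)")
            opt_r = place(False, state.s)
            if opt_r.failed:
                return fail("node optimization failed (right)")
        except StringsMeet:
            state.status = "joined"
            state.log.append("strings meet (step exceeded gap)")
            break
        state.left_nodes.append(opt_l.geometry)
        state.left_energies.append(opt_l.energy)
        state.right_nodes.append(opt_r.geometry)
        state.right_energies.append(opt_r.energy)
        state.log.append(
            f"  new nodes: E_l={opt_l.energy:.8f} ({opt_l.evals} evals) "
            f"E_r={opt_r.energy:.8f} ({opt_r.evals} evals)"
        )
        if on_cycle is not None:
            on_cycle(state)
    else:
        return fail(f"string did not join within {max_cycles} cycles")

    state.grad_calls = calculator.eval_count
    return state, _ts_guess(state)


def _ts_guess(state: StringState) -> Geometry | None:
    energies = state.energies
    if not energies:
        return None
    finite = [(e, i) for i, e in enumerate(energies) if np.isfinite(e)]
    if not finite:
        return None
    _, idx = max(finite)
    return state.nodes[idx]


def pure_interpolation_config(config: FSMConfig) -> FSMConfig:
    """The n_opt = 0 variant: growth by interpolation only, energies
    evaluated solely to pick the transition-state guess."""
    return replace(config, n_opt=0)
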