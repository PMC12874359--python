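"""The freezing string growth loop: projection, step size, node
optimization, freezing, termination and bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fsmpath.calculators import Calculator, DoubleWell2D, MullerBrown, ToyForceField
from fsmpath.fixtures import FixtureSpec, build, toyff_for
from fsmpath.fsm import (
    FSMConfig,
    FSMError,
    compute_step_size,
    optimize_node,
    perpendicular_gradient,
    run_fsm,
)
from fsmpath.geometry import Geometry


def particle(x, y):
    return Geometry(("X",), np.array([[x, y, 0.0]]))


class TestPerpendicularGradient:
    def test_parallel_gradient_projects_to_zero(self):
        t = np.array([1.0, 0.0, 0.0])
        np.testing.assert_allclose(perpendicular_gradient(3.0 * t, t), 0.0, atol=1e-14)

    def test_orthogonal_gradient_unchanged(self):
        t = np.array([1.0, 0.0, 0.0])
        g = np.array([0.0, 2.0, -1.0])
        np.testing.assert_allclose(perpendicular_gradient(g, t), g, atol=1e-14)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_pythagoras_decomposition(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.normal(size=6)
        t = rng.normal(size=6)
        t /= np.linalg.norm(t)
        gp = perpendicular_gradient(g, t)
        assert abs(t @ gp) < 1e-12
        assert g @ g == pytest.approx(gp @ gp + (t @ g) ** 2, rel=1e-12)

    def test_non_unit_tangent_rejected(self):
        with pytest.raises(FSMError):
            perpendicular_gradient(np.ones(3), np.array([1.0, 1.0, 0.0]))


class TestStepSize:
    def test_straight_path_divided_by_n_nodes(self):
        a = particle(0.0, 0.0)
        b = particle(9.0, 0.0)
        cfg = FSMConfig(n_nodes=9, interpolator="lst", align=False)
        assert compute_step_size(a, b, cfg) == pytest.approx(1.0, abs=1e-6)

    def test_identical_endpoints_raise(self):
        a = particle(0.5, 0.5)
        with pytest.raises(FSMError):
            compute_step_size(a, a, FSMConfig(interpolator="lst", align=False))

    def test_halving_n_nodes_doubles_s(self, twisted_pair, twisted_icsys):
        s18 = compute_step_size(
            *twisted_pair, FSMConfig(n_nodes=18, interpolator="ric"), twisted_icsys
        )
        s9 = compute_step_size(
            *twisted_pair, FSMConfig(n_nodes=9, interpolator="ric"), twisted_icsys
        )
        assert s9 == pytest.approx(2.0 * s18, rel=1e-12)


class QuadraticBowl(Calculator):
    """E = ½|x|²: isotropic bowl on all 3N coordinates (test surface)."""

    def _compute(self, geometry):
        x = geometry.flat
        return 0.5 * x @ x, x


class SteepQuartic(Calculator):
    """E = Σ x⁴: steep enough that raw quasi-Newton steps exceed the bound."""

    def _compute(self, geometry):
        x = geometry.flat
        return np.sum(x**4), 4 * x**3


class TestOptimizeNode:
    def test_zero_perpendicular_gradient_single_evaluation(self):
        calc = QuadraticBowl()
        t = np.zeros(3)
        t[0] = 1.0
        # at x = (2, 0, 0) the full gradient is parallel to the tangent
        node = Geometry(("X",), np.array([[2.0, 0.0, 0.0]]))
        res = optimize_node(node, t, calc, FSMConfig(interpolator="lst", grad_tol=1e-8))
        assert res.evals == 1
        assert res.converged
        np.testing.assert_allclose(res.geometry.coords, node.coords)

    def test_motion_confined_to_orthogonal_subspace(self):
        calc = QuadraticBowl()
        t = np.zeros(3)
        t[0] = 1.0
        node = Geometry(("X",), np.array([[1.0, 0.8, 0.0]]))
        res = optimize_node(node, t, calc, FSMConfig(n_opt=4, interpolator="lst"))
        disp = res.geometry.flat - node.flat
        assert abs(disp @ t) < 1e-8  # projector kills tangent motion
        assert abs(res.geometry.coords[0, 1]) < abs(node.coords[0, 1])

    def test_per_step_displacement_bound(self):
        calc = SteepQuartic()
        t = np.array([0.0, 0.0, 1.0])
        node = Geometry(("X",), np.array([[3.0, -2.5, 0.0]]))
        cfg = FSMConfig(n_opt=5, n_ls=3, max_disp=0.3, interpolator="lst")
        res = optimize_node(node, t, calc, cfg)
        assert res.steps, "expected at least one accepted step"
        for step in res.steps:
            assert np.abs(step).max() <= 0.3 + 1e-12

    def test_eval_budget(self):
        calc = SteepQuartic()
        t = np.array([0.0, 0.0, 1.0])
        node = Geometry(("X",), np.array([[3.0, -2.5, 0.0]]))
        for n_opt, n_ls in [(1, 1), (2, 3), (3, 2)]:
            c = SteepQuartic()
            cfg = FSMConfig(n_opt=n_opt, n_ls=n_ls, interpolator="lst")
            res = optimize_node(node, t, c, cfg)
            assert res.evals <= n_opt * (1 + n_ls)
            assert res.evals == c.eval_count


class TestRunFSM:
    def test_symmetric_double_well(self):
        a = particle(-1.0, 0.0)
        b = particle(1.0, 0.0)
        cfg = FSMConfig(n_nodes=8, interpolator="lst", align=False)
        state, ts = run_fsm(a, b, DoubleWell2D(), cfg)
        assert state.status == "joined"
        # barrier top at the origin
        np.testing.assert_allclose(ts.coords[0], [0.0, 0.0, 0.0], atol=0.05)
        # string symmetric under left<->right exchange
        xs = np.array([n.coords[0, 0] for n in state.nodes])
        np.testing.assert_allclose(xs, -xs[::-1], atol=1e-6)

    def test_node_count_near_nominal(self, butane_pair, butane_ff):
        cfg = FSMConfig(n_nodes=9, interpolator="ric")
        state, _ = run_fsm(*butane_pair, ToyForceField(butane_ff), cfg)
        assert state.status == "joined"
        assert 9 - 2 <= len(state.nodes) <= 9 + 2

    def test_frozen_nodes_never_move(self, butane_pair, butane_ff):
        # snapshot per-node hashes after every growth cycle: once a node is
        # frozen its coordinates must be bit-identical for the rest of the run
        snapshots = []

        def watch(state):
            snapshots.append(
                (list(state.coordinate_hashes()), len(state.left_nodes))
            )

        calc = ToyForceField(butane_ff)
        state, _ = run_fsm(
            *butane_pair, calc, FSMConfig(n_nodes=9, interpolator="ric"), on_cycle=watch
        )
        assert state.status == "joined" and len(snapshots) >= 2
        final_hashes = state.coordinate_hashes()
        for hashes, nleft in snapshots:
            # left half-string nodes occupy the prefix, right half the suffix
            nright = len(hashes) - nleft
            assert hashes[:nleft] == final_hashes[:nleft]
            assert hashes[-nright:] == final_hashes[-nright:]

    def test_evaluation_accounting(self, butane_pair, butane_ff):
        calc = ToyForceField(butane_ff)
        state, _ = run_fsm(*butane_pair, calc, FSMConfig(n_nodes=9, interpolator="ric"))
        assert state.grad_calls == calc.eval_count
        assert state.grad_calls == sum(state.node_evals)

    def test_deterministic_reruns_bit_identical(self, butane_pair, butane_ff):
        cfg = FSMConfig(n_nodes=9, interpolator="ric")
        s1, t1 = run_fsm(*butane_pair, ToyForceField(butane_ff), cfg)
        s2, t2 = run_fsm(*butane_pair, ToyForceField(butane_ff), cfg)
        assert s1.coordinate_hashes() == s2.coordinate_hashes()
        assert s1.energies == s2.energies
        np.testing.assert_array_equal(t1.coords, t2.coords)

    def test_n_opt_zero_is_pure_interpolation(self, butane_pair, butane_ff):
        cfg = FSMConfig(n_nodes=9, n_opt=0, interpolator="ric")
        calc = ToyForceField(butane_ff)
        state, _ = run_fsm(*butane_pair, calc, cfg)
        assert state.status == "joined"
        # exactly one energy evaluation per node (TS-guess selection only)
        assert state.grad_calls == len(state.nodes)
        assert all(e == 1 for e in state.node_evals)

    def test_ric_refused_for_single_particle(self):
        with pytest.raises(FSMError):
            run_fsm(
                particle(0, 0), particle(1, 0), MullerBrown(), FSMConfig(interpolator="ric")
            )

    def test_mismatched_endpoints_raise(self, water, butane_pair):
        with pytest.raises(FSMError):
            run_fsm(water, butane_pair[0], MullerBrown(), FSMConfig())
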