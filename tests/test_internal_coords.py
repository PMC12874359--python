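"""Primitive internals, pruning, Wilson B matrix, delocalization and the
iterative back-transformation."""

import numpy as np
import pytest

from conftest import finite_difference_b
from fsmpath.fixtures import FixtureSpec, build, perturb
from fsmpath.geometry import Geometry
from fsmpath.internal_coords import (
    BT_TOLERANCE,
    InternalCoordinateError,
    PrimitiveIC,
    b_pseudo_inverse,
    build_ic_system,
    cartesian_from_internal,
    delocalize,
    detect_primitives,
    measure,
    measure_one,
    wilson_b_matrix,
    wrap_angle,
)


class TestDetect:
    def test_diatomic_has_one_bond(self):
        prims = detect_primitives(build(FixtureSpec("diatomic")))
        assert [p.kind for p in prims] == ["bond"]
        assert prims[0].atoms == (0, 1)

    def test_water_has_two_bonds_one_angle(self, water):
        prims = detect_primitives(water)
        kinds = sorted(p.kind for p in prims)
        assert kinds == ["angle", "bond", "bond"]

    def test_separated_fragments_get_connecting_distance(self):
        geom = build(FixtureSpec("two-fragment", {"sep": 5.0}))
        prims = detect_primitives(geom)
        bonds = [p for p in prims if p.kind == "bond"]
        dists = [p for p in prims if p.kind == "distance"]
        assert len(bonds) == 2
        assert len(dists) == 1
        assert dists[0].atoms == (1, 2)  # closest inter-fragment pair

    def test_deterministic(self, butane_pair):
        a = detect_primitives(butane_pair[0])
        b = detect_primitives(butane_pair[0])
        assert [p.key() for p in a] == [p.key() for p in b]


class TestMeasure:
    def test_diatomic_distance(self):
        g = build(FixtureSpec("diatomic", {"r": 1.5}))
        np.testing.assert_allclose(measure(g, [PrimitiveIC("bond", (0, 1))]), [1.5])

    def test_right_angle(self):
        g = build(FixtureSpec("bent-triatomic", {"angle": 90.0}))
        assert measure_one(g, PrimitiveIC("angle", (0, 1, 2))) == pytest.approx(
            np.pi / 2, abs=1e-12
        )

    @pytest.mark.parametrize("deg", [60.0, -60.0, 170.0, -120.0])
    def test_constructed_torsion(self, deg):
        g = build(FixtureSpec("four-atom-torsion", {"torsion": deg}))
        phi = measure_one(g, PrimitiveIC("torsion", (0, 1, 2, 3)))
        assert phi == pytest.approx(np.deg2rad(deg), abs=1e-10)

    def test_collinear_torsion_raises_naming_primitive(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], float)
        g = Geometry(("C", "C", "C", "C"), coords)
        with pytest.raises(InternalCoordinateError, match="torsion"):
            measure_one(g, PrimitiveIC("torsion", (0, 1, 2, 3)))


class TestWilsonB:
    def test_diatomic_bond_row(self):
        g = Geometry(("H", "H"), np.array([[0.0, 0, 0], [1.3, 0, 0]]))
        B = wilson_b_matrix(g, [PrimitiveIC("bond", (0, 1))])
        np.testing.assert_allclose(B[0], [-1, 0, 0, 1, 0, 0], atol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_finite_differences(self, seed, butane_pair):
        geom = perturb(butane_pair[0], rigid=False, noise_sigma=0.05, seed=seed)
        prims = detect_primitives(geom)
        B = wilson_b_matrix(geom, prims)
        assert np.abs(B - finite_difference_b(geom, prims)).max() < 1e-6

    def test_out_of_plane_matches_finite_differences(self):
        coords = np.array(
            [[0, 0, 0.38], [0.94, 0, -0.1], [-0.47, 0.81, -0.1], [-0.47, -0.81, -0.1]]
        )
        g = Geometry(("N", "H", "H", "H"), coords)
        prims = detect_primitives(g)
        assert any(p.kind == "out_of_plane" for p in prims)
        B = wilson_b_matrix(g, prims)
        assert np.abs(B - finite_difference_b(g, prims)).max() < 1e-6

    def test_linear_bend_matches_finite_differences(self):
        g = Geometry(("O", "C", "O"), np.array([[0, 0, 0], [1.16, 0.02, 0], [2.32, 0, 0]]))
        lb0 = PrimitiveIC("linear_bend", (0, 1, 2), axis_tag=0, axis=(0.0, 1.0, 0.0))
        lb1 = PrimitiveIC("linear_bend", (0, 1, 2), axis_tag=1, axis=(0.0, 0.0, 1.0))
        B = wilson_b_matrix(g, [lb0, lb1])
        assert np.abs(B - finite_difference_b(g, [lb0, lb1])).max() < 1e-6

    def test_translation_and_rotation_invariance(self, water):
        geom = perturb(water, rigid=False, noise_sigma=0.02, seed=11)
        prims = detect_primitives(geom)
        B = wilson_b_matrix(geom, prims)
        trans = np.tile([1.0, -2.0, 0.5], geom.natoms)
        assert np.abs(B @ trans).max() < 1e-10
        w = np.array([0.2, 0.7, -0.4])
        centroid = geom.coords.mean(axis=0)
        rotfield = np.cross(np.broadcast_to(w, (geom.natoms, 3)), geom.coords - centroid)
        assert np.abs(B @ rotfield.ravel()).max() < 1e-8


class TestDelocalize:
    def test_water_rank_is_3n_minus_6(self, water):
        B = wilson_b_matrix(water, detect_primitives(water))
        U, Bd = delocalize(B)
        assert U.shape[1] == 3 * water.natoms - 6 == 3
        np.testing.assert_allclose(U.T @ U, np.eye(3), atol=1e-10)

    def test_redundant_extra_distance_does_not_raise_rank(self, water):
        prims = detect_primitives(water) + [PrimitiveIC("distance", (0, 2))]
        B = wilson_b_matrix(water, prims)
        U, _ = delocalize(B)
        assert U.shape == (4, 3)  # 4 primitives, still 3 nonredundant vectors

    def test_g_positive_semidefinite(self, twisted_pair):
        B = wilson_b_matrix(twisted_pair[0], detect_primitives(twisted_pair[0]))
        w = np.linalg.eigvalsh(B @ B.T)
        assert w.min() >= -1e-12


class TestBPseudoInverse:
    def test_orthonormal_rows_self_inverse(self):
        B = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
        np.testing.assert_allclose(b_pseudo_inverse(B), B, atol=1e-12)

    def test_single_row_scalar_case(self):
        B = np.array([[1.0, 2.0, 2.0]])
        np.testing.assert_allclose(b_pseudo_inverse(B), B / 9.0, atol=1e-12)

    def test_composite_is_identity(self):
        rng = np.random.default_rng(5)
        B = rng.normal(size=(3, 9))
        np.testing.assert_allclose(B @ b_pseudo_inverse(B).T, np.eye(3), atol=1e-8)

    def test_dx_satisfies_b_dx_equals_dq(self, twisted_icsys, twisted_pair):
        B = twisted_icsys.U.T @ wilson_b_matrix(twisted_pair[0], twisted_icsys.primitives)
        rng = np.random.default_rng(8)
        dq = rng.normal(size=B.shape[0])
        dx = b_pseudo_inverse(B).T @ dq
        np.testing.assert_allclose(B @ dx, dq, atol=1e-8)


class TestBuildICSystem:
    def test_bent_pair_no_pruning(self, water):
        bent2 = build(FixtureSpec("bent-triatomic", {"angle": 120.0}))
        ic = build_ic_system(water, bent2)
        assert sorted(p.kind for p in ic.primitives) == ["angle", "bond", "bond"]
        assert ic.prune_log == []

    def test_linear_endpoint_spawns_linear_bend_pair(self):
        lin = build(FixtureSpec("linear-triatomic"))
        bent = build(
            FixtureSpec(
                "bent-triatomic",
                {"r1": 1.16, "r2": 1.16, "angle": 150.0, "symbols": ("O", "C", "O")},
            )
        )
        ic = build_ic_system(lin, bent)
        kinds = [p.kind for p in ic.primitives]
        assert kinds.count("linear_bend") == 2
        assert kinds.count("angle") == 0
        axes = [np.array(p.axis) for p in ic.primitives if p.kind == "linear_bend"]
        assert abs(axes[0] @ axes[1]) < 1e-10  # orthogonal bending directions

    def test_trans_torsion_replaced_by_distance(self, butane_pair):
        ic = build_ic_system(*butane_pair)
        kinds = [p.kind for p in ic.primitives]
        assert "distance" in kinds  # the A-D bonding coordinate
        assert any("replaced by distance" in line for line in ic.prune_log)

    def test_all_distances_fallback(self):
        # square pair: every torsion is degenerate (all atoms coplanar with
        # collinear internal bends) -> unique atom-atom distances
        sq = Geometry(
            ("H", "H", "H", "H"),
            np.array([[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]], float),
        )
        sq2 = sq.with_coords(sq.coords * 1.1)
        ic = build_ic_system(sq, sq2)
        assert all(p.kind == "distance" for p in ic.primitives)
        assert len(ic.primitives) == 6  # all unique atom-atom pairs

    def test_pruning_deterministic(self, butane_pair):
        a = build_ic_system(*butane_pair)
        b = build_ic_system(*butane_pair)
        assert [p.key() for p in a.primitives] == [p.key() for p in b.primitives]

    def test_endpoint_mismatch_raises(self, water, butane_pair):
        with pytest.raises(InternalCoordinateError):
            build_ic_system(water, butane_pair[0])

    def test_report_lists_primitives(self, butane_pair):
        ic = build_ic_system(*butane_pair)
        text = ic.report(*butane_pair)
        assert "bond(0-1)" in text and "prune log" in text


class TestBackTransform:
    def test_fixed_point_returns_start(self, twisted_pair, twisted_icsys):
        start = twisted_pair[0]
        q = measure(start, twisted_icsys.primitives)
        res = cartesian_from_internal(q, start, twisted_icsys)
        assert res.converged and res.n_iter <= 1
        np.testing.assert_allclose(res.geometry.coords, start.coords, atol=1e-12)

    def test_diatomic_stretch(self):
        a = build(FixtureSpec("diatomic", {"r": 1.0}))
        b = build(FixtureSpec("diatomic", {"r": 1.1}))
        ic = build_ic_system(a, b)
        res = cartesian_from_internal(np.array([1.2]), a, ic)
        assert res.converged
        r = np.linalg.norm(res.geometry.coords[1] - res.geometry.coords[0])
        assert r == pytest.approx(1.2, abs=1e-7)

    def test_torsion_rotation_by_20_degrees(self, twisted_pair, twisted_icsys):
        start = twisted_pair[0]
        q = measure(start, twisted_icsys.primitives)
        idx = [i for i, p in enumerate(twisted_icsys.primitives) if p.kind == "torsion"][0]
        target = q.copy()
        target[idx] = wrap_angle(target[idx] - np.deg2rad(20.0))
        res = cartesian_from_internal(target, start, twisted_icsys)
        assert res.converged
        phi = measure(res.geometry, twisted_icsys.primitives)[idx]
        assert abs(wrap_angle(phi - target[idx])) < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_random_delocalized_displacement(
        self, seed, twisted_pair, twisted_icsys
    ):
        start = twisted_pair[0]
        ic = twisted_icsys
        rng = np.random.default_rng(seed)
        dq_dlc = rng.normal(size=ic.n_dlc)
        dq_dlc *= 0.3 / max(np.linalg.norm(dq_dlc), 1.0)
        target = measure(start, ic.primitives) + ic.U @ dq_dlc
        res = cartesian_from_internal(target, start, ic)
        assert res.converged, f"not converged at tol {BT_TOLERANCE}"
        q = measure(res.geometry, ic.primitives)
        dq = target - q
        dq[ic.torsion_mask] = wrap_angle(dq[ic.torsion_mask])
        assert np.abs(dq).max() < 1e-6
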