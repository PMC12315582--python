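"""Q-score sampling geometry, interpolation, correlation and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qmetric as qm
from qmetric.qscore import (
    ZeroVarianceError,
    correlation_about_mean,
    generate_shell_points,
    golden_spiral_points,
    qscore_atom,
    reference_profile,
    sample_map_values,
)

PROTOCOL = qm.SamplingProtocol()


class TestShellPoints:
    def test_isolated_atom_full_shells(self):
        pos = np.array([0.0, 0.0, 0.0])
        pts, radii, n_rej = generate_shell_points(pos, None, PROTOCOL, rng=0)
        assert n_rej == 0
        assert len(pts) == PROTOCOL.nominal_points
        # every accepted point sits at its nominal radius
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), radii, atol=1e-9)
        for r in PROTOCOL.shell_radii:
            assert np.sum(np.isclose(radii, r)) == PROTOCOL.pts_per_shell

    def test_center_point_is_included_once(self):
        pts, radii, _ = generate_shell_points(np.zeros(3), None, PROTOCOL, rng=0)
        assert np.sum(radii == 0.0) == 1
        np.testing.assert_array_equal(pts[0], np.zeros(3))

    def test_ownership_rule_brute_force(self):
        # two atoms 1.0 A apart: no accepted point may be strictly closer to
        # the neighbor than to the target (checked point-by-point)
        target = np.zeros(3)
        neighbor = np.array([[1.0, 0.0, 0.0]])
        pts, radii, n_rej = generate_shell_points(target, neighbor, PROTOCOL, rng=1)
        d_target = np.linalg.norm(pts - target, axis=1)
        d_neighbor = np.linalg.norm(pts - neighbor[0], axis=1)
        assert np.all(d_neighbor >= d_target - 1e-12)
        assert n_rej > 0  # shells at r ~ 0.9+ must lose points to the neighbor
        # in particular no point at radius >= 0.9 is past the bisecting plane
        far = radii >= 0.9
        assert np.all(pts[far, 0] <= 0.5 + 1e-12)

    def test_deterministic_given_seed(self):
        a = generate_shell_points(np.zeros(3), None, PROTOCOL, rng=7)
        b = generate_shell_points(np.zeros(3), None, PROTOCOL, rng=7)
        np.testing.assert_array_equal(a[0], b[0])

    def test_golden_spiral_unit_vectors(self):
        v = golden_spiral_points(32)
        np.testing.assert_allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-12)
        # quasi-uniform: centroid near origin
        assert np.linalg.norm(v.mean(axis=0)) < 0.05


class TestInterpolation:
    def test_constant_map(self):
        dmap = qm.DensityMap(np.full((8, 8, 8), 3.7), [0.5] * 3, [0, 0, 0])
        pts = np.random.default_rng(0).uniform(0.2, 3.2, size=(50, 3))
        s = sample_map_values(dmap, pts, np.zeros(50))
        np.testing.assert_allclose(s.values, 3.7, atol=1e-12)

    def test_linear_field_reproduced_exactly(self):
        # trilinear interpolation is exact on fields linear in x
        nx = 8
        values = np.broadcast_to(
            np.arange(nx)[:, None, None] * 0.5, (nx, nx, nx)
        ).copy()
        dmap = qm.DensityMap(values, [0.5] * 3, [0, 0, 0])
        pts = np.random.default_rng(1).uniform(0.2, 3.2, size=(50, 3))
        s = sample_map_values(dmap, pts, np.zeros(50))
        np.testing.assert_allclose(s.values, pts[:, 0] * 0.5 / 0.5, atol=1e-12)

    def test_matches_weighted_sum_oracle(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(8, 8, 8))
        dmap = qm.DensityMap(values, [0.5] * 3, [1.0, -1.0, 0.5])
        pts = dmap.index_to_position(rng.uniform(0, 7, size=(40, 3)))
        s = sample_map_values(dmap, pts, np.zeros(len(pts)))
        # independent oracle: explicit 8-corner weighted sum
        idx = dmap.position_to_index(pts)
        expected = []
        for fx, fy, fz in idx:
            i0, j0, k0 = int(np.floor(fx)), int(np.floor(fy)), int(np.floor(fz))
            tx, ty, tz = fx - i0, fy - j0, fz - k0
            acc = 0.0
            for di, wx in ((0, 1 - tx), (1, tx)):
                for dj, wy in ((0, 1 - ty), (1, ty)):
                    for dk, wz in ((0, 1 - tz), (1, tz)):
                        acc += wx * wy * wz * values[
                            min(i0 + di, 7), min(j0 + dj, 7), min(k0 + dk, 7)
                        ]
            expected.append(acc)
        np.testing.assert_allclose(s.values, expected, atol=1e-12)

    def test_out_of_grid_points_counted(self):
        dmap = qm.DensityMap(np.zeros((4, 4, 4)), [0.5] * 3, [0, 0, 0])
        pts = np.array([[0.5, 0.5, 0.5], [10.0, 0.0, 0.0]])
        s = sample_map_values(dmap, pts, np.zeros(2))
        assert s.n_out_of_grid == 1 and len(s.values) == 1


class TestReferenceProfile:
    def test_closed_form_values(self):
        v = reference_profile([0.0, PROTOCOL.sigma_ref], PROTOCOL)
        np.testing.assert_allclose(v, [1.0, np.exp(-0.5)], atol=1e-12)

    def test_strictly_decreasing(self):
        r = np.linspace(0, 2, 100)
        v = reference_profile(r, PROTOCOL)
        assert np.all(np.diff(v) < 0)


class TestCorrelation:
    def test_perfect_and_anti_correlation(self):
        u = np.array([0.1, 0.5, 0.9, 1.3])
        assert correlation_about_mean(u, u) == pytest.approx(1.0)
        assert correlation_about_mean(u, -u + 7.0) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        u, v = rng.normal(size=20), rng.normal(size=20)
        # brute-force term-by-term sums
        num = sum((ui - u.mean()) * (vi - v.mean()) for ui, vi in zip(u, v))
        den = np.sqrt(
            sum((ui - u.mean()) ** 2 for ui in u)
            * sum((vi - v.mean()) ** 2 for vi in v)
        )
        assert correlation_about_mean(u, v) == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroVarianceError):
            correlation_about_mean(np.ones(5), np.arange(5.0))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        u, v = rng.normal(size=10), rng.normal(size=10)
        assert correlation_about_mean(u, v) == pytest.approx(
            correlation_about_mean(v, u), abs=1e-14
        )


class TestQScoreAtom:
    def test_ideal_gaussian_scores_near_one(self, isolated_atom_model, ideal_map):
        qres = qm.qscore_model(ideal_map, isolated_atom_model)
        assert qres.model_q >= 0.99

    def test_affine_invariance_and_sign_flip(self, isolated_atom_model, ideal_map):
        q0 = qm.qscore_model(ideal_map, isolated_atom_model).model_q
        up = qm.DensityMap(3.0 * ideal_map.values + 10.0, ideal_map.voxel_size, ideal_map.origin)
        down = qm.DensityMap(-2.0 * ideal_map.values + 5.0, ideal_map.voxel_size, ideal_map.origin)
        assert abs(qm.qscore_model(up, isolated_atom_model).model_q - q0) < 1e-9
        assert abs(qm.qscore_model(down, isolated_atom_model).model_q + q0) < 1e-9

    def test_q_decreases_with_rendering_b(self, isolated_atom_model):
        qs = []
        for b in (0.0, 50.0, 100.0, 200.0):
            dmap = qm.simulate_map(isolated_atom_model, b, voxel=0.25, margin=6.0)
            qs.append(qm.qscore_model(dmap, isolated_atom_model).model_q)
        assert np.all(np.diff(qs) < 0)

    def test_bit_identical_repeats(self, helix_scored):
        model, dmap, qres = helix_scored
        again = qm.qscore_model(dmap, model)
        np.testing.assert_array_equal(qres.q, again.q)
        assert qres.model_q == again.model_q

    def test_flat_map_flagged_unscored(self):
        dmap = qm.DensityMap(np.zeros((16, 16, 16)), [0.5] * 3, [0, 0, 0])
        q, flag, _ = qscore_atom(dmap, np.array([4.0, 4.0, 4.0]), None, PROTOCOL, rng=0)
        assert np.isnan(q) and flag == "zero_variance"

    def test_out_of_grid_atom_flagged(self):
        dmap = qm.DensityMap(np.zeros((8, 8, 8)), [0.5] * 3, [0, 0, 0])
        q, flag, _ = qscore_atom(dmap, np.array([50.0, 50.0, 50.0]), None, PROTOCOL, rng=0)
        assert np.isnan(q) and flag == "out_of_grid"


class TestQScoreModel:
    def test_model_q_is_mean_of_atom_qs(self, helix_scored):
        model, dmap, qres = helix_scored
        scored = qres.q[qres.scored_mask]
        assert qres.model_q == pytest.approx(scored.mean(), abs=1e-15)
        assert qres.n_scored == len(model.atoms)  # all atoms in-grid, non-H

    def test_q_within_bounds(self, helix_scored):
        _, _, qres = helix_scored
        scored = qres.q[qres.scored_mask]
        assert np.all(scored >= -1.0) and np.all(scored <= 1.0)

    def test_equal_atoms_give_model_q(self, isolated_atom_model, ideal_map):
        q0 = qm.qscore_model(ideal_map, isolated_atom_model).model_q
        # duplicate the same density situation far apart: mean stays q0-ish
        assert -1.0 <= q0 <= 1.0

    def test_hydrogens_not_scored(self):
        recs = [
            qm.AtomRecord(1, "O", "O", "A", "HOH", 1, [5.0, 5.0, 5.0]),
            qm.AtomRecord(2, "H1", "H", "A", "HOH", 1, [5.5, 5.0, 5.0]),
        ]
        model = qm.AtomicModel(recs)
        dmap = qm.simulate_map(qm.AtomicModel(recs[:1]), 0.0, voxel=0.25, margin=4.0)
        qres = qm.qscore_model(dmap, model)
        assert np.isnan(qres.q[1]) and np.isfinite(qres.q[0])

    def test_no_scorable_atoms_raises(self):
        model = qm.AtomicModel(
            [qm.AtomRecord(1, "H", "H", "A", "ALA", 1, [0, 0, 0])]
        )
        dmap = qm.DensityMap(np.zeros((4, 4, 4)), [0.5] * 3, [0, 0, 0])
        with pytest.raises(ValueError):
            qm.qscore_model(dmap, model)
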