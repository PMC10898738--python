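"""Kinematic metrics, ranking, stress summaries, prestrain calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from tenodesis_fe.analysis import (ContourGrid, KinematicsTrace,
                                   MetricSeries, calibrate_prestrain,
                                   contour_grid, etr_trace,
                                   mae_vs_reference, make_results_table,
                                   peritunnel_max_vonmises, ptt_ltc_trace,
                                   range_during_reduction, rank_combinations,
                                   stress_reduction_summary)
from tenodesis_fe.errors import AnalysisError
from tenodesis_fe.febio_io import ElementStressRecord
from tenodesis_fe.loading_protocols import tension_grid
from tenodesis_fe.synthetic_fixtures import table1_fixture


def _identity_trace(n=5):
    return KinematicsTrace(np.linspace(0, 40, n),
                           np.repeat(np.eye(3)[None], n, axis=0),
                           np.zeros((n, 3)))


def _gs_oracle_etr(R):
    """Independent joint-coordinate-system decomposition: for the intrinsic
    sequence Rx(a) Ry(b) Rz(g), g = atan2(-R01, R00); ETR = -g."""
    return -np.degrees(np.arctan2(-R[0, 1], R[0, 0]))


class TestETR:
    def test_identity_gives_zeros(self):
        series = etr_trace(_identity_trace())
        np.testing.assert_allclose(series.values, 0.0, atol=1e-12)

    def test_pure_long_axis_rotation(self):
        """A constant 5-degree external rotation of the tibia (femur turned
        -5 degrees about the tibial long axis) reads 5 degrees."""
        R = Rotation.from_euler("z", -5.0, degrees=True).as_matrix()
        trace = KinematicsTrace([0, 20, 40], np.repeat(R[None], 3, axis=0),
                                np.zeros((3, 3)))
        np.testing.assert_allclose(etr_trace(trace).values, 5.0, atol=1e-9)

    def test_matches_jcs_decomposition_oracle(self, rng):
        """Composite rotations below 30 degrees match the explicit
        Grood-Suntay-style closed form to 1e-6 degrees."""
        for _ in range(100):
            ang = rng.uniform(-25, 25, size=3)
            R = Rotation.from_euler("XYZ", ang, degrees=True).as_matrix()
            trace = KinematicsTrace([0.0], R[None], np.zeros((1, 3)))
            got = etr_trace(trace).values[0]
            assert got == pytest.approx(_gs_oracle_etr(R), abs=1e-6)

    def test_nonorthonormal_rotations_rejected(self):
        with pytest.raises(AnalysisError):
            KinematicsTrace([0.0], np.ones((1, 3, 3)), np.zeros((1, 3)))


class TestPTT:
    LFP = np.array([20.0, 5.0, 10.0])

    def test_static_femur_gives_zeros(self):
        series = ptt_ltc_trace(_identity_trace(), self.LFP)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-12)

    def test_pure_posterior_translation(self):
        n = 4
        t = np.zeros((n, 3))
        t[:, 1] = [0.0, -3.0, -3.0, -3.0]  # 3 mm posterior (-y)
        trace = KinematicsTrace(np.linspace(0, 30, n),
                                np.repeat(np.eye(3)[None], n, axis=0), t)
        series = ptt_ltc_trace(trace, self.LFP)
        np.testing.assert_allclose(series.values, [0, 3, 3, 3], atol=1e-12)

    def test_rotation_about_axis_through_lfp_is_invisible(self):
        """Rotating the femur about an axis through the LFP leaves the
        tracked point in place."""
        n = 5
        Rs, ts = [], []
        for a in np.linspace(0, 20, n):
            R = Rotation.from_euler("z", a, degrees=True).as_matrix()
            Rs.append(R)
            ts.append(self.LFP - R @ self.LFP)
        trace = KinematicsTrace(np.linspace(0, 40, n), np.array(Rs),
                                np.array(ts))
        np.testing.assert_allclose(ptt_ltc_trace(trace, self.LFP).values,
                                   0.0, atol=1e-9)

    def test_missing_lfp_rejected(self):
        with pytest.raises(AnalysisError):
            ptt_ltc_trace(_identity_trace(), None)


class TestSeriesReductions:
    def test_constant_series_has_zero_range(self):
        s = MetricSeries(np.linspace(0, 40, 9), np.full(9, 3.3))
        assert range_during_reduction(s, (10, 40)) == 0.0

    def test_identity_series_range_equals_window(self):
        ang = np.linspace(0, 40, 81)
        s = MetricSeries(ang, ang)
        assert range_during_reduction(s, (10, 40)) == pytest.approx(30.0)

    def test_range_matches_bruteforce(self, rng):
        ang = np.linspace(0, 40, 41)
        for _ in range(20):
            vals = rng.normal(size=41)
            s = MetricSeries(ang, vals)
            lo, hi = sorted(rng.uniform(0, 40, size=2))
            if not np.any((ang >= lo) & (ang <= hi)):
                continue
            sel = vals[(ang >= lo) & (ang <= hi)]
            assert range_during_reduction(s, (lo, hi)) == \
                pytest.approx(sel.max() - sel.min())

    def test_empty_window_rejected(self):
        s = MetricSeries([0, 10, 20], [1, 2, 3])
        with pytest.raises(AnalysisError):
            range_during_reduction(s, (12, 13))

    def test_mae_identical_is_zero_and_offset_is_offset(self, rng):
        ang = np.linspace(0, 40, 41)
        vals = rng.normal(size=41)
        a = MetricSeries(ang, vals)
        assert mae_vs_reference(a, a) == 0.0
        b = MetricSeries(ang, vals + 0.75)
        assert mae_vs_reference(b, a) == pytest.approx(0.75)

    def test_mae_matches_direct_summation(self, rng):
        ang = np.linspace(0, 40, 41)
        a = MetricSeries(ang, rng.normal(size=41))
        b = MetricSeries(ang, rng.normal(size=41))
        assert mae_vs_reference(a, b) == \
            pytest.approx(np.abs(a.values - b.values).mean())

    def test_mae_triangle_inequality(self, rng):
        ang = np.linspace(0, 40, 21)
        a, b, c = (MetricSeries(ang, rng.normal(size=21)) for _ in range(3))
        assert mae_vs_reference(a, c) <= \
            mae_vs_reference(a, b) + mae_vs_reference(b, c) + 1e-12

    def test_mae_resamples_differing_grids(self):
        a = MetricSeries(np.linspace(0, 40, 81), np.linspace(0, 40, 81))
        b = MetricSeries(np.linspace(0, 40, 41), np.linspace(0, 40, 41))
        assert mae_vs_reference(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_mae_disjoint_coverage_rejected(self):
        a = MetricSeries([0, 10], [1, 1])
        b = MetricSeries([20, 30], [1, 1])
        with pytest.raises(AnalysisError):
            mae_vs_reference(a, b)


class TestRanking:
    def test_best_etr_combination(self):
        combined, _ = table1_fixture()
        ranked = rank_combinations(combined, by="etr")
        top = ranked.iloc[0]
        assert (top.aclr_tension, top.let_tension) == (80.0, 5.0)
        assert top.etr_mae == 0.659
        assert top.max_von_mises == 21.734

    def test_lowest_ptt_error_among_combined(self):
        combined, _ = table1_fixture()
        ranked = rank_combinations(combined, by="ptt")
        top = ranked.iloc[0]
        assert (top.aclr_tension, top.let_tension) == (90.0, 10.0)
        assert top.ptt_mae == 0.712

    def test_single_row_table(self):
        t = make_results_table([(80.0, 5.0, 0.5, 0.5, 20.0)])
        assert rank_combinations(t, "etr").equals(t)

    def test_ranking_is_a_permutation(self):
        combined, _ = table1_fixture()
        ranked = rank_combinations(combined, by="etr")
        assert sorted(ranked.etr_mae) == sorted(combined.etr_mae)
        assert len(ranked) == len(combined)

    def test_empty_table_rejected(self):
        with pytest.raises(AnalysisError):
            rank_combinations(pd.DataFrame(
                columns=["aclr_tension", "let_tension", "etr_mae",
                         "ptt_mae", "max_von_mises"]), "etr")


class TestStress:
    def _records(self, rng, n=30):
        return [ElementStressRecord(i, tuple(rng.uniform(-10, 10, 3)),
                                    float(rng.uniform(0, 30)), 1)
                for i in range(n)]

    def test_all_within_radius_gives_global_max(self, rng):
        recs = self._records(rng)
        got = peritunnel_max_vonmises(recs, (0, 0, 0), radius=100.0)
        assert got == max(r.von_mises for r in recs)

    def test_radius_smaller_than_nearest_centroid_rejected(self, rng):
        recs = [ElementStressRecord(0, (5.0, 0.0, 0.0), 10.0, 1)]
        with pytest.raises(AnalysisError):
            peritunnel_max_vonmises(recs, (0, 0, 0), radius=1.0)

    def test_default_radius_is_1p5x_tunnel_radius(self):
        recs = [ElementStressRecord(0, (3.0, 0.0, 0.0), 10.0, 1),
                ElementStressRecord(1, (4.0, 0.0, 0.0), 99.0, 1)]
        # tunnel radius 2.5 -> capture radius 3.75: only the first element
        got = peritunnel_max_vonmises(recs, (0, 0, 0), tunnel_radius=2.5)
        assert got == 10.0

    def test_matches_filter_then_max(self, rng):
        recs = self._records(rng)
        pt, r = np.zeros(3), 8.0
        sel = [x.von_mises for x in recs
               if np.linalg.norm(np.array(x.centroid)) <= r]
        assert peritunnel_max_vonmises(recs, pt, r) == max(sel)

    def test_reduction_summary_on_published_table(self):
        combined, standalone = table1_fixture()
        summary = stress_reduction_summary(combined, standalone)
        assert round(summary.max_delta, 2) == 4.04
        assert summary.max_at_tension == 40.0
        assert len(summary.deltas) == 9

    def test_identical_tables_give_zero_deltas(self):
        _, standalone = table1_fixture()
        s = standalone.copy()
        s["let_tension"] = 5.0
        summary = stress_reduction_summary(s, standalone)
        assert np.allclose(summary.deltas.delta_MPa, 0.0)

    def test_constant_offset_gives_that_mean(self):
        _, standalone = table1_fixture()
        comb = standalone.copy()
        comb["let_tension"] = 5.0
        comb["max_von_mises"] = comb["max_von_mises"] - 1.5
        summary = stress_reduction_summary(comb, standalone)
        assert summary.mean_delta == pytest.approx(1.5)

    def test_antisymmetric_under_swap(self):
        combined, standalone = table1_fixture()
        min_let = combined[combined.let_tension == 5.0]
        swapped_combined = standalone.assign(let_tension=5.0)
        swapped_standalone = min_let.assign(let_tension=np.nan)
        a = stress_reduction_summary(min_let, standalone)
        b = stress_reduction_summary(swapped_combined, swapped_standalone)
        np.testing.assert_allclose(
            a.deltas.sort_values("aclr_tension").delta_MPa.to_numpy(),
            -b.deltas.sort_values("aclr_tension").delta_MPa.to_numpy())


class TestContour:
    def test_constructed_minimum_location(self):
        grid = tension_grid()
        rows = [(a, l, abs(a - 80) + abs(l - 5), 1.0, 20.0)
                for a, l in grid.pairs]
        cg = contour_grid(make_results_table(rows), grid, "etr_mae")
        assert cg.min_location == (80.0, 5.0)
        assert isinstance(cg, ContourGrid)

    def test_incomplete_grid_names_missing_pairs(self):
        grid = tension_grid()
        rows = [(a, l, 1.0, 1.0, 20.0) for a, l in grid.pairs[:-2]]
        with pytest.raises(AnalysisError, match="missing"):
            contour_grid(make_results_table(rows), grid)

    def test_minimum_matches_exhaustive_scan(self, rng):
        grid = tension_grid()
        vals = rng.uniform(size=len(grid))
        rows = [(a, l, v, 1.0, 20.0)
                for (a, l), v in zip(grid.pairs, vals)]
        cg = contour_grid(make_results_table(rows), grid, "etr_mae")
        best = grid.pairs[int(np.argmin(vals))]
        assert cg.min_location == tuple(best)


class TestConvergenceHarness:
    def test_detects_convergence_of_swept_volume(self):
        """Tube volume converges to pi r^2 L as the ring resolution grows."""
        from tenodesis_fe.mesh_geometry import TrajectoryPolyline, sweep_graft
        from tenodesis_fe.analysis import mesh_convergence
        traj = TrajectoryPolyline([(0, 0, 0), (0, 0, 50)], radius=4)

        def vol(n_theta):
            return sweep_graft(traj, n_theta=int(n_theta)).volume()

        result = mesh_convergence(vol, [6, 12, 24, 48, 96], rel_tol=0.01)
        assert result.converged_at is not None
        assert result.values[-1] == pytest.approx(np.pi * 16 * 50, rel=0.01)

    def test_requires_two_resolutions(self):
        from tenodesis_fe.analysis import mesh_convergence
        with pytest.raises(AnalysisError):
            mesh_convergence(lambda r: 1.0, [1.0])


class TestPrestrainCalibration:
    EXP = [(0.0, 1.0), (1.0, 3.0), (2.0, 5.0)]  # line y = 2x + 1

    def test_candidate_on_line_selected_with_zero_mse(self):
        xs = np.array([0.0, 1.0, 2.0])
        on_line = (1.02, xs, 2 * xs + 1)
        off = (1.05, xs, 2 * xs + 2)
        best, scores = calibrate_prestrain([off, on_line], self.EXP)
        assert best == 1.02
        assert scores[1.02] == pytest.approx(0.0)

    def test_constant_offsets_score_quadratically(self):
        xs = np.array([0.0, 1.0, 2.0])
        c1 = (1.01, xs, 2 * xs + 1 + 1.0)
        c2 = (1.04, xs, 2 * xs + 1 + 2.0)
        best, scores = calibrate_prestrain([c2, c1], self.EXP)
        assert best == 1.01
        assert scores[1.01] == pytest.approx(1.0)
        assert scores[1.04] == pytest.approx(4.0)

    def test_matches_exhaustive_scan(self, rng):
        xs = np.linspace(0, 2, 7)
        cands = [(float(s), xs, rng.normal(size=7))
                 for s in rng.uniform(1.0, 1.1, size=9)]
        best, scores = calibrate_prestrain(cands, self.EXP)
        line = 2 * xs + 1
        brute = min(((float(np.mean((ys - line) ** 2)), s)
                     for s, _x, ys in cands))
        assert best == brute[1]

    def test_no_candidates_rejected(self):
        with pytest.raises(AnalysisError):
            calibrate_prestrain([], self.EXP)
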