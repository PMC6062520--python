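import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wcmaldi.errors import DataError
from wcmaldi.preprocess import FeatureMatrix
from wcmaldi.response import (
    ConcentrationSeries,
    ResponseConfig,
    average_technical_replicates,
    find_markers,
    fit_ascending,
    fit_best_direction,
    fit_descending,
    logistic_ascending,
    logistic_descending,
    pic50,
    rank_and_call_markers,
    truncate_after_max,
    variance_filter,
)
from wcmaldi.spectra_io import SampleSheet


def _grid_search_ss(x, y):
    """Dense grid over (LogIC50, HillSlope) with analytic top/bottom profile.

    For fixed (L, H) the model is linear in (top, bottom); the 2x2 normal
    equations are solved in closed form for every grid node at once.
    """
    lic = np.linspace(-10.0, -3.0, 351)
    hill = np.linspace(0.05, 10.0, 200)
    L, H = np.meshgrid(lic, hill, indexing="ij")
    w = 1.0 / (1.0 + 10.0 ** ((L[..., None] - x) * H[..., None]))  # (nL, nH, n)
    a = 1.0 - w
    m00 = np.sum(a * a, axis=-1)
    m01 = np.sum(a * w, axis=-1)
    m11 = np.sum(w * w, axis=-1)
    b0 = np.sum(a * y, axis=-1)
    b1 = np.sum(w * y, axis=-1)
    det = m00 * m11 - m01 * m01
    with np.errstate(divide="ignore", invalid="ignore"):
        top = (m11 * b0 - m01 * b1) / det
        bottom = (m00 * b1 - m01 * b0) / det
        ss = np.sum((y - (top[..., None] * a + bottom[..., None] * w)) ** 2, axis=-1)
    ss = np.where(np.isfinite(ss), ss, np.inf)
    return float(ss.min())


def _series(x, y, mz=826.6, bio=1):
    return ConcentrationSeries(mz, np.asarray(x, float), np.asarray(y, float), bio_rep=bio)


def _fm_with_sheet(matrix, sheet_rows, features=None):
    matrix = np.asarray(matrix, dtype=float)
    if features is None:
        features = 500.0 + 10.0 * np.arange(matrix.shape[1])
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    return FeatureMatrix(features, matrix, [r["sample_id"] for r in sheet_rows], sheet)


class TestVarianceFilter:
    def test_mean_threshold_keeps_only_high_variance(self):
        # columns with sample variances exactly {1, 1, 10}: mean 4
        s10 = np.sqrt(10.0)
        matrix = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, s10], [2.0, 2.0, 2 * s10]])
        fm = FeatureMatrix([500.0, 510.0, 520.0], matrix, ["a", "b", "c"])
        kept, variances, threshold = variance_filter(fm)
        assert np.allclose(variances, [1.0, 1.0, 10.0])
        assert threshold == pytest.approx(4.0)
        assert list(kept) == [2]

    def test_equal_variances_keep_nothing(self):
        matrix = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        fm = FeatureMatrix([500.0, 510.0], matrix, ["a", "b", "c"])
        kept, _, _ = variance_filter(fm)
        assert len(kept) == 0

    def test_constant_features_never_kept(self):
        matrix = np.array([[5.0, 1.0], [5.0, 9.0], [5.0, 4.0]])
        fm = FeatureMatrix([500.0, 510.0], matrix, ["a", "b", "c"])
        kept, _, _ = variance_filter(fm)
        assert 0 not in kept

    def test_single_sample_rejected(self):
        fm = FeatureMatrix([500.0], np.array([[1.0]]), ["a"])
        with pytest.raises(DataError):
            variance_filter(fm)

    def test_high_variance_nuisance_features_raise_threshold(self):
        """Adding high-variance features can only shrink the original kept set."""
        rng = np.random.default_rng(21)
        base = rng.random((6, 10))
        fm1 = FeatureMatrix(
            500.0 + 10 * np.arange(10), base, [f"s{i}" for i in range(6)]
        )
        kept1, _, thr1 = variance_filter(fm1)
        loud = np.column_stack([base, 100.0 * rng.random((6, 3))])
        fm2 = FeatureMatrix(
            np.concatenate([fm1.features, [900.0, 910.0, 920.0]]),
            loud,
            [f"s{i}" for i in range(6)],
        )
        kept2, _, thr2 = variance_filter(fm2)
        assert thr2 > thr1
        assert set(kept2) & set(range(10)) <= set(kept1)


class TestAverageTechnicalReplicates:
    def _rows(self, n, conc=1e-6, bio=1):
        return [
            {"sample_id": f"s{bio}_{i}", "compound": "drugX",
             "concentration_molar": conc, "tech_rep": i + 1, "bio_rep": bio}
            for i in range(n)
        ]

    def test_identical_reps_unchanged(self):
        fm = _fm_with_sheet(np.tile([2.0, 4.0], (8, 1)), self._rows(8))
        avg = average_technical_replicates(fm)
        assert avg.n_samples == 1
        assert np.allclose(avg.intensities, [[2.0, 4.0]])

    def test_simple_mean(self):
        fm = _fm_with_sheet([[2.0], [4.0]], self._rows(2))
        avg = average_technical_replicates(fm)
        assert avg.intensities[0, 0] == pytest.approx(3.0)

    def test_mean_beats_single_reps_in_l2(self):
        """The replicate mean is closer to truth than any single replicate
        in the wide majority of seeded trials."""
        truth = np.linspace(10, 50, 20)
        wins = 0
        for trial in range(100):
            rng = np.random.default_rng(1000 + trial)
            reps = truth * rng.lognormal(0, 0.15, size=(8, 20))
            fm = _fm_with_sheet(reps, self._rows(8),
                                features=500.0 + 10 * np.arange(20))
            avg = average_technical_replicates(fm).intensities[0]
            d_avg = np.linalg.norm(avg - truth)
            d_reps = np.linalg.norm(reps - truth, axis=1)
            wins += d_avg < d_reps.min()
        assert wins >= 90

    def test_groups_split_by_bio_rep(self):
        rows = self._rows(2, bio=1) + self._rows(2, bio=2)
        fm = _fm_with_sheet([[1.0], [3.0], [10.0], [20.0]], rows)
        avg = average_technical_replicates(fm)
        assert avg.n_samples == 2
        assert np.allclose(sorted(avg.intensities[:, 0]), [2.0, 15.0])


class TestTruncateAfterMax:
    def test_monotone_series_unchanged(self):
        s = _series([1, 2, 3, 4], [1, 2, 3, 4])
        out = truncate_after_max(s)
        assert len(out) == 4 and not out.truncated

    def test_biphasic_truncated_at_peak(self):
        s = _series([1, 2, 3, 4, 5], [1, 5, 9, 4, 2])
        out = truncate_after_max(s)
        assert len(out) == 3
        assert out.truncated
        assert np.allclose(out.y, [1, 5, 9])

    def test_ties_keep_through_last_max(self):
        s = _series([1, 2, 3], [3, 3, 3])
        out = truncate_after_max(s)
        assert len(out) == 3 and not out.truncated

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=12))
    def test_idempotence(self, ys):
        s = _series(np.arange(len(ys), dtype=float), ys)
        once = truncate_after_max(s)
        twice = truncate_after_max(once)
        assert np.array_equal(once.y, twice.y)
        assert np.array_equal(once.x, twice.x)


class TestLogisticFits:
    X8 = np.linspace(-9.0, -4.5, 8)

    def test_descending_noise_free_recovery(self):
        y = logistic_descending(self.X8, 10.0, 2.0, -6.3, 1.0)
        fit = fit_descending(_series(self.X8, y))
        assert fit.top == pytest.approx(10.0, rel=1e-4)
        assert fit.bottom == pytest.approx(2.0, rel=1e-4)
        assert fit.log_ic50 == pytest.approx(-6.3, rel=1e-4)
        assert fit.hill_slope == pytest.approx(1.0, rel=1e-4)
        assert fit.r2 >= 1 - 1e-9

    def test_descending_with_noise_recovers_log_ic50(self):
        rng = np.random.default_rng(17)
        y = logistic_descending(self.X8, 10.0, 2.0, -6.3, 1.0) + rng.normal(0, 0.2, 8)
        fit = fit_descending(_series(self.X8, np.clip(y, 0, None)))
        assert abs(fit.log_ic50 - (-6.3)) <= 0.2

    def test_sum_of_squares_beats_dense_grid_oracle(self):
        """The optimizer must match a dense grid search with profiled plateaus."""
        x = np.linspace(-8.0, -5.0, 6)
        y = np.array([9.8, 9.1, 6.5, 3.4, 2.3, 2.05])
        fit = fit_descending(_series(x, y))
        ss_fit = float(np.sum((y - fit.predict(x)) ** 2))
        best = _grid_search_ss(x, y)
        assert ss_fit <= best + 1e-6

    def test_ascending_noise_free_recovery(self):
        x = np.linspace(-9.0, -5.0, 6)
        y = logistic_ascending(x, 8.0, 1.0, -6.8, 1.2)
        fit = fit_ascending(_series(x, y))
        assert fit.log_ic50 == pytest.approx(-6.8, rel=1e-4)
        assert fit.r2 >= 1 - 1e-9

    def test_biphasic_truncation_then_recovery(self):
        x = np.linspace(-9.0, -5.0, 9)
        y = logistic_ascending(x, 10.0, 1.0, -6.8, 1.5)
        y[6:] = [y[5] * 0.7, y[5] * 0.4, y[5] * 0.2]  # toxic collapse
        trunc = truncate_after_max(_series(x, y))
        assert len(trunc) == 6 and trunc.truncated
        fit = fit_ascending(trunc)
        assert abs(fit.log_ic50 - (-6.8)) <= 0.05

    def test_too_few_points_after_truncation_skipped(self):
        x = np.array([-9.0, -8.0, -7.0, -6.0, -5.0])
        y = np.array([1.0, 4.0, 9.0, 5.0, 2.0])  # max at 3rd point
        trunc = truncate_after_max(_series(x, y))
        assert len(trunc) == 3
        fit = fit_ascending(trunc)
        assert not fit.ok
        assert "insufficient points" in fit.reason
        assert fit.r2 == -np.inf

    def test_constant_series_flagged_not_raised(self):
        fit = fit_descending(_series(self.X8, np.full(8, 3.0)))
        assert not fit.ok

    def test_canonical_top_above_bottom(self):
        y = logistic_descending(self.X8, 10.0, 2.0, -6.3, 1.0)
        for fitter in (fit_descending, fit_ascending):
            fit = fitter(_series(self.X8, y))
            assert fit.top >= fit.bottom

    def test_descending_data_never_classified_ascending(self):
        y = logistic_descending(self.X8, 10.0, 2.0, -6.3, 1.0)
        best = fit_best_direction(_series(self.X8, y))
        assert best.direction == "descending"


class TestMarkerCalling:
    def _fit(self, r2, direction="descending", log_ic50=-6.0):
        from wcmaldi.response import DoseResponseFit

        return DoseResponseFit(10.0, 2.0, log_ic50, 1.0, direction, r2, 8)

    def test_all_reps_pass_same_direction(self):
        fits = {826.6: {1: self._fit(0.95), 2: self._fit(0.93), 3: self._fit(0.97)}}
        calls = rank_and_call_markers(fits, r2_min=0.9, n_reps_required=3)
        assert calls[0].reproducible

    def test_one_failing_rep_blocks_marker(self):
        fits = {826.6: {1: self._fit(0.95), 2: self._fit(0.85), 3: self._fit(0.97)}}
        calls = rank_and_call_markers(fits, r2_min=0.9, n_reps_required=3)
        assert not calls[0].reproducible

    def test_direction_disagreement_blocks_marker(self):
        fits = {826.6: {1: self._fit(0.95), 2: self._fit(0.95, "ascending"), 3: self._fit(0.95)}}
        calls = rank_and_call_markers(fits, r2_min=0.9, n_reps_required=3)
        assert not calls[0].reproducible

    def test_ranking_by_mean_r2(self):
        fits = {
            500.0: {1: self._fit(0.5)},
            826.6: {1: self._fit(0.99)},
        }
        calls = rank_and_call_markers(fits, n_reps_required=1)
        assert calls[0].feature_mz == 826.6


class TestPic50:
    def test_sign_convention(self):
        from wcmaldi.response import DoseResponseFit

        fit = DoseResponseFit(10, 2, -6.0, 1.0, "descending", 0.99, 8)
        assert pic50(fit) == pytest.approx(6.0)

    def test_generator_oracle_10_nM(self):
        x = np.linspace(-10.0, -6.0, 8)
        y = logistic_descending(x, 10.0, 1.0, -8.0, 1.0)  # IC50 = 10 nM
        fit = fit_descending(_series(x, y))
        assert pic50(fit) == pytest.approx(8.00, abs=0.01)

    def test_potency_ordering(self):
        x = np.linspace(-10.0, -4.0, 8)
        strong = fit_descending(_series(x, logistic_descending(x, 10, 1, -9.0, 1.0)))
        weak = fit_descending(_series(x, logistic_descending(x, 10, 1, -6.0, 1.0)))
        assert pic50(strong) > pic50(weak)

    def test_failed_fit_reports_nan(self):
        from wcmaldi.response import _failed_fit

        assert np.isnan(pic50(_failed_fit("descending", 3, "insufficient points")))


class TestFindMarkers:
    def test_planted_feature_is_the_single_marker(self):
        from wcmaldi.simulate import simulate_feature_matrix

        fm = simulate_feature_matrix(seed=99, n_features=50, responsive_index=17)
        result = find_markers(fm, ResponseConfig())
        markers = result.markers
        assert len(markers) == 1
        assert markers[0].feature_mz == pytest.approx(fm.features[17])
        assert markers[0].direction == "descending"
        assert abs(markers[0].pic50_mean - 6.3) <= 0.2

    def test_exclusion_list_removes_compound_ion(self):
        from wcmaldi.simulate import simulate_feature_matrix

        fm = simulate_feature_matrix(seed=99, n_features=50, responsive_index=17)
        cfg = ResponseConfig(exclude_mz=(float(fm.features[17]),))
        result = find_markers(fm, cfg)
        assert len(result.markers) == 0

    def test_vehicle_rows_anchor_the_plateau(self):
        from wcmaldi.simulate import simulate_feature_matrix

        fm = simulate_feature_matrix(seed=5, n_features=10, responsive_index=3)
        # append vehicle rows (concentration 0) at drug-free intensity
        table = fm.sheet.table
        veh_rows = []
        rng = np.random.default_rng(6)
        base = fm.intensities[:3].mean(axis=0)
        for b in (1, 2, 3):
            for t in (1, 2):
                veh_rows.append(
                    {"sample_id": f"veh_b{b}_t{t}", "compound": "vehicle",
                     "concentration_molar": 0.0, "tech_rep": t, "bio_rep": b}
                )
        veh = base * rng.lognormal(0, 0.15, size=(len(veh_rows), fm.n_features))
        fm2 = FeatureMatrix(
            fm.features,
            np.vstack([fm.intensities, veh]),
            fm.sample_ids + [r["sample_id"] for r in veh_rows],
            SampleSheet(pd.concat([table, pd.DataFrame(veh_rows)], ignore_index=True)),
        )
        result = find_markers(fm2, ResponseConfig(), compound="drugX")
        assert len(result.markers) == 1
        assert result.markers[0].feature_mz == pytest.approx(fm.features[3])
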