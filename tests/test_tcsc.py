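import itertools

import numpy as np
import pytest
from scipy import stats

from ssvep_tcsc.reference_tcsc import (
    ELECTROPHYSIOLOGICAL_RATIONAL,
    PSYCHOPHYSICAL_RATIONAL,
)
from ssvep_tcsc.tcsc import (
    benjamini_hochberg,
    compare_curves,
    curve_peak,
    fit_rational,
    pearson,
    pool_sensitivities,
    prediction_bounds,
    rational_curve,
    storey_qvalues,
)

FIT_GRID = np.array([4.0, 6.0, 8.0, 13.0, 19.0, 24.0, 32.0, 37.0, 40.0,
                     48.0, 60.0])


class TestPooling:
    def test_single_outlier_excluded(self):
        values = [1.0] * 10 + [10.0]
        pooled = pool_sensitivities(values)
        assert pooled.n_excluded == 1
        assert pooled.excluded_mask.tolist() == [False] * 10 + [True]
        assert pooled.mean == pytest.approx(1.0)

    def test_all_equal_untouched(self):
        pooled = pool_sensitivities([5.0, 5.0, 5.0, 5.0])
        assert pooled.n_excluded == 0 and pooled.mean == 5.0

    def test_symmetric_sample(self):
        pooled = pool_sensitivities([9.0, 10.0, 11.0])
        assert pooled.mean == pytest.approx(10.0)
        assert pooled.n_excluded == 0

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            pool_sensitivities([1.0, 2.0])


class TestFitRational:
    def test_self_consistency_on_noiseless_data(self):
        """Points generated from known coefficients are reproduced on the
        grid; the coefficient vector may be non-unique, so curve equality
        is asserted."""
        truth = PSYCHOPHYSICAL_RATIONAL
        y = rational_curve(FIT_GRID, *truth)
        fit = fit_rational(FIT_GRID, y)
        np.testing.assert_allclose(fit.predict(FIT_GRID), y, rtol=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_scale_equivariance(self):
        y = rational_curve(FIT_GRID, *ELECTROPHYSIOLOGICAL_RATIONAL)
        fit1 = fit_rational(FIT_GRID, y)
        fit10 = fit_rational(FIT_GRID, 10.0 * y)
        grid = np.linspace(4, 60, 50)
        np.testing.assert_allclose(
            fit10.predict(grid), 10.0 * fit1.predict(grid), rtol=1e-5
        )

    def test_needs_five_points(self):
        with pytest.raises(ValueError):
            fit_rational([1, 2, 3, 4], [1, 2, 3, 4])


class TestCurvePeak:
    @pytest.mark.parametrize(
        "coeffs",
        [PSYCHOPHYSICAL_RATIONAL, ELECTROPHYSIOLOGICAL_RATIONAL],
        ids=["psychophysical", "electrophysiological"],
    )
    def test_peak_rounds_to_18hz(self, coeffs):
        f_peak, s_peak, at_edge = curve_peak(coeffs, (1.0, 60.0))
        assert round(f_peak) == 18
        assert not at_edge
        # independent oracle: golden-section search on the same curve
        res = stats  # noqa: F841 (keep stats import used)
        from scipy.optimize import golden

        f_gold = golden(
            lambda x: -rational_curve(x, *coeffs), brack=(5.0, 20.0, 40.0)
        )
        assert f_peak == pytest.approx(f_gold, abs=1e-3)

    def test_toy_curve_matches_closed_form(self):
        """For S(f) = (-f^2 + b f) / (f + q) the calculus maximiser is
        f* = -q + sqrt(q^2 + b q)."""
        b, q = 40.0, 5.0
        coeffs = (0.0, -1.0, b, 0.0, q)
        f_peak, s_peak, _ = curve_peak(coeffs, (1.0, 60.0))
        f_true = -q + np.sqrt(q**2 + b * q)  # = 10 exactly
        assert f_peak == pytest.approx(f_true, abs=1e-4)
        assert s_peak == pytest.approx(rational_curve(f_true, *coeffs),
                                       rel=1e-8)

    def test_edge_maximum_flagged(self):
        coeffs = (0.0, 0.0, 1.0, 0.0, 1.0)  # increasing f/(f+1)
        _, _, at_edge = curve_peak(coeffs, (1.0, 60.0))
        assert at_edge

    def test_peak_location_scale_invariant(self):
        f1, _, _ = curve_peak(PSYCHOPHYSICAL_RATIONAL)
        scaled = tuple(12.4 * c for c in PSYCHOPHYSICAL_RATIONAL[:4]) + (
            PSYCHOPHYSICAL_RATIONAL[4],
        )
        f2, _, _ = curve_peak(scaled)
        assert f1 == pytest.approx(f2, abs=1e-6)


class TestPredictionBounds:
    def _noiseless_fit(self):
        y = rational_curve(FIT_GRID, *PSYCHOPHYSICAL_RATIONAL)
        return fit_rational(FIT_GRID, y)

    def test_zero_variance_bounds_collapse(self):
        fit = self._noiseless_fit()
        fit.residual_sd = 0.0
        fit.cov = np.zeros((5, 5))
        bounds = prediction_bounds(fit, [10.0, 20.0])
        np.testing.assert_allclose(bounds["lower"], bounds["fit"],
                                   atol=1e-9)
        np.testing.assert_allclose(bounds["upper"], bounds["fit"],
                                   atol=1e-9)

    def test_bounds_widen_with_residual_sd(self):
        fit = self._noiseless_fit()
        fit.cov = np.zeros((5, 5))
        widths = []
        for s in (0.5, 1.0, 2.0):
            fit.residual_sd = s
            b = prediction_bounds(fit, [20.0])
            widths.append(float(b["upper"][0] - b["lower"][0]))
        assert widths[0] < widths[1] < widths[2]

    def test_monte_carlo_coverage(self):
        """Observation-level 95% bounds cover a held-out noisy observation
        in ~95% of refits from the true model."""
        rng = np.random.default_rng(3)
        truth = PSYCHOPHYSICAL_RATIONAL
        sigma = 1.0
        y_true = rational_curve(FIT_GRID, *truth)
        f_new = 22.0
        y_new_true = rational_curve(f_new, *truth)
        covered = 0
        n_ok = 0
        for _ in range(500):
            y = y_true + rng.normal(0.0, sigma, size=FIT_GRID.size)
            try:
                fit = fit_rational(FIT_GRID, y, init=truth)
            except RuntimeError:
                continue
            b = prediction_bounds(fit, [f_new])
            y_new = y_new_true + rng.normal(0.0, sigma)
            n_ok += 1
            covered += int(b["lower"][0] <= y_new <= b["upper"][0])
        assert n_ok > 450
        assert covered / n_ok == pytest.approx(0.95, abs=0.04)


class TestCompareCurves:
    def test_identical_samples_p_near_one(self):
        x = {10.0: [1.0, 1.0, 1.0, 1.0]}
        res = compare_curves(x, x)
        assert res.table["p"].iloc[0] == pytest.approx(1.0)

    def test_small_sample_matches_exhaustive_permutation(self):
        """Rank-sum p for 4 vs 4 equals the brute-force enumeration over
        all 70 group assignments."""
        x = np.array([1.2, 3.4, 0.5, 2.2])
        y = np.array([4.1, 5.0, 2.9, 6.3])
        res = compare_curves({8.0: x}, {8.0: y})
        p_pkg = res.table["p"].iloc[0]

        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs = ranks[:4].sum()
        count = 0
        total = 0
        mid = pooled.size / 2 * (pooled.size + 1) / 2  # mean rank sum
        for idx in itertools.combinations(range(8), 4):
            rs = ranks[list(idx)].sum()
            total += 1
            if abs(rs - mid) >= abs(obs - mid) - 1e-9:
                count += 1
        assert p_pkg == pytest.approx(count / total, abs=1e-9)

    def test_type_one_error_calibration(self):
        """Under the null the two-sided rank-sum test rejects at ~5%."""
        rng = np.random.default_rng(8)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            x = rng.standard_normal(10)
            y = rng.standard_normal(10)
            p = stats.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact").pvalue
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.015)

    def test_small_groups_skipped(self):
        res = compare_curves({5.0: [1, 2]}, {5.0: [1, 2, 3]})
        assert res.table.empty

    def test_significance_flags(self):
        rng = np.random.default_rng(0)
        psy = {f: rng.normal(10, 1, 12) for f in (5.0, 10.0)}
        eeg = {f: rng.normal(2, 1, 12) for f in (5.0, 10.0)}
        res = compare_curves(psy, eeg)
        assert res.table["sig_q005"].all()


class TestQValues:
    def test_storey_is_pi0_times_bh(self, rng):
        p = rng.uniform(0, 1, 40)
        q_storey = storey_qvalues(p, lam=0.5)
        q_bh = benjamini_hochberg(p)
        pi0 = min(1.0, np.mean(p > 0.5) / 0.5)
        pi0 = max(pi0, 1.0 / p.size)
        np.testing.assert_allclose(
            q_storey, np.clip(pi0 * q_bh, 0, 1), atol=1e-12
        )

    def test_monotone_in_p(self, rng):
        p = rng.uniform(0, 1, 25)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.2, 1.4])


class TestPearson:
    def test_perfect_linear(self):
        rho, p = pearson([1, 2, 3, 4], [2, 4, 6, 8])
        assert rho == pytest.approx(1.0)
        assert p < 1e-6

    def test_anticorrelation(self):
        rho, _ = pearson([1, 2, 3, 4], [-1, -2, -3, -4])
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_small_vector(self):
        x = np.array([1.0, 2.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 3.0, 6.0])
        rho, _ = pearson(x, y)
        manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert rho == pytest.approx(manual, rel=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
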