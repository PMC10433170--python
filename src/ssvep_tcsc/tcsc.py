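"""Pooling, rational TCSC fitting, prediction bounds and the
psychophysical-vs-electrophysiological comparison.

Per-frequency sensitivities (1/threshold) are pooled across subjects with a
single-pass two-standard-deviation outlier exclusion; the pooled means are
fitted with the cubic/linear rational polynomial

    TCSC(f) = (p1 f^3 + p2 f^2 + p3 f + p4) / (f + q1)

by Levenberg-Marquardt least squares.  Observation-level 95% prediction
bounds follow from the delta method, the curve peak from a dense grid with
local refinement, and the two sensitivity samples are compared per frequency
with a two-sided Wilcoxon rank-sum test followed by Storey q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TCSCFit",
    "ComparisonResult",
    "PooledSensitivity",
    "pool_sensitivities",
    "rational_curve",
    "fit_rational",
    "prediction_bounds",
    "curve_peak",
    "compare_curves",
    "storey_qvalues",
    "pearson",
]


def rational_curve(f, p1, p2, p3, p4, q1):
    """Cubic/linear rational polynomial."""
    f = np.asarray(f, dtype=float)
    return (p1 * f**3 + p2 * f**2 + p3 * f + p4) / (f + q1)


@dataclass
class PooledSensitivity:
    """Mean sensitivity at one frequency after outlier exclusion."""

    frequency_hz: float
    mean: float
    n_used: int
    n_excluded: int
    excluded_mask: np.ndarray


def pool_sensitivities(values, frequency_hz: float = np.nan
                       ) -> PooledSensitivity:
    """Mean after a single-pass exclusion of values more than two sample
    standard deviations from the mean.  Requires >= 3 values."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 records to pool")
    sd = x.std(ddof=1)
    mask = np.abs(x - x.mean()) > 2.0 * sd if sd > 0 else np.zeros(
        x.size, dtype=bool
    )
    kept = x[~mask]
    return PooledSensitivity(
        frequency_hz, float(kept.mean()), int(kept.size),
        int(mask.sum()), mask,
    )


@dataclass
class TCSCFit:
    """Rational-polynomial fit of mean sensitivity against frequency."""

    params: np.ndarray  # (p1, p2, p3, p4, q1)
    cov: np.ndarray  # 5 x 5 coefficient covariance
    frequencies: np.ndarray
    values: np.ndarray  # mean sensitivities fitted
    r_squared: float  # against mean sensitivities
    r_squared_thresholds: float  # against mean thresholds (1/S)
    residual_sd: float
    df: int

    def predict(self, f) -> np.ndarray:
        return rational_curve(f, *self.params)


def _linearised_init(f: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Starting point: for candidate q1 values solve the linearised system
    S * (f + q1) = p1 f^3 + ... + p4 by ordinary least squares and keep the
    candidate with the smallest true residual."""
    design = np.column_stack([f**3, f**2, f, np.ones_like(f)])
    best, best_rss = None, np.inf
    for q1 in (1.0, 5.0, 10.0, 20.0, 40.0):
        coef, *_ = np.linalg.lstsq(design, s * (f + q1), rcond=None)
        rss = float(np.sum((s - rational_curve(f, *coef, q1)) ** 2))
        if rss < best_rss:
            best_rss, best = rss, np.append(coef, q1)
    return best


def fit_rational(
    frequencies,
    sensitivities,
    init: Optional[Sequence[float]] = None,
) -> TCSCFit:
    """Levenberg-Marquardt least-squares fit of the rational TCSC.

    Needs at least 5 frequency points (5 free coefficients).  R^2 is
    reported both against the mean sensitivities (the fitted quantity) and
    against the corresponding mean thresholds.
    """
    f = np.asarray(frequencies, dtype=float)
    s = np.asarray(sensitivities, dtype=float)
    if f.size < 5:
        raise ValueError("need at least 5 frequency points for 5 parameters")
    p0 = np.asarray(init, float) if init is not None else _linearised_init(f, s)
    try:
        params, cov = optimize.curve_fit(
            rational_curve, f, s, p0=p0, method="lm", maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(f"rational fit did not converge: {exc}") from exc
    resid = s - rational_curve(f, *params)
    rss = float(np.sum(resid**2))
    tss = float(np.sum((s - s.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    thr = 1.0 / s
    thr_fit = 1.0 / rational_curve(f, *params)
    tss_t = float(np.sum((thr - thr.mean()) ** 2))
    r2_t = (
        1.0 - float(np.sum((thr - thr_fit) ** 2)) / tss_t
        if tss_t > 0 else 1.0
    )
    dof = f.size - params.size
    residual_sd = np.sqrt(rss / dof) if dof > 0 else np.nan
    return TCSCFit(params, cov, f, s, r2, r2_t, float(residual_sd), dof)


def _gradient(f: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Analytic gradient of the rational curve w.r.t. its coefficients;
    shape (n, 5)."""
    p1, p2, p3, p4, q1 = params
    denom = f + q1
    num = p1 * f**3 + p2 * f**2 + p3 * f + p4
    return np.column_stack(
        [f**3 / denom, f**2 / denom, f / denom, 1.0 / denom,
         -num / denom**2]
    )


def prediction_bounds(
    fit: TCSCFit, frequencies, level: float = 0.95
) -> pd.DataFrame:
    """Observation-level prediction bounds by the delta method:
    fit +/- t_(1-a/2, df) * sqrt(s^2 + g' Cov g)."""
    if fit.df <= 0:
        raise ValueError("no residual degrees of freedom for bounds")
    f = np.asarray(frequencies, dtype=float)
    g = _gradient(f, fit.params)
    var_curve = np.einsum("ij,jk,ik->i", g, fit.cov, g)
    se = np.sqrt(fit.residual_sd**2 + np.clip(var_curve, 0.0, None))
    tcrit = stats.t.ppf(0.5 + level / 2.0, fit.df)
    y = fit.predict(f)
    return pd.DataFrame(
        {
            "frequency_hz": f,
            "fit": y,
            "lower": y - tcrit * se,
            "upper": y + tcrit * se,
        }
    )


def curve_peak(
    params: Sequence[float],
    domain: tuple[float, float] = (1.0, 60.0),
    step: float = 0.01,
) -> tuple[float, float, bool]:
    """Global maximum of the rational curve on a closed domain.

    Dense-grid search at ``step`` resolution with bounded local refinement.
    Returns (f_peak, S_peak, at_edge); ``at_edge`` flags a maximum on the
    domain boundary.
    """
    lo, hi = domain
    grid = np.arange(lo, hi + step / 2.0, step)
    vals = rational_curve(grid, *params)
    if not np.all(np.isfinite(vals)):
        raise ValueError("curve not finite on the requested domain")
    i = int(np.argmax(vals))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
    f_peak, s_peak = float(grid[i]), float(vals[i])
    if a < b:
        res = optimize.minimize_scalar(
            lambda x: -rational_curve(x, *params),
            bounds=(a, b), method="bounded",
        )
        if -res.fun >= s_peak:
            f_peak, s_peak = float(res.x), float(-res.fun)
    at_edge = f_peak - lo < step or hi - f_peak < step
    return f_peak, s_peak, at_edge


def storey_qvalues(pvalues, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a fixed lambda tuning parameter.

    pi0 is estimated as #{p > lambda} / ((1 - lambda) m), clamped to
    (0, 1]; q(p_(i)) = min over j >= i of pi0 * m * p_(j) / j on the
    ascending order statistics.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = np.mean(p > lam) / (1.0 - lam)
    pi0 = float(np.clip(pi0, 1.0 / m, 1.0))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (fallback to Storey's estimator)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


@dataclass
class ComparisonResult:
    """Per-frequency rank-sum comparison of two sensitivity samples."""

    table: pd.DataFrame  # frequency_hz, n_psy, n_eeg, statistic, p, q,
    # sig_q005, sig_q001
    method: str = "storey"


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.all(np.concatenate([x, y]) == x[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def compare_curves(
    psy_by_freq: dict[float, Sequence[float]],
    eeg_by_freq: dict[float, Sequence[float]],
    lam: float = 0.5,
    method: str = "storey",
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum test per shared frequency with FDR
    q-values across frequencies (Storey by default, BH as fallback).

    Frequencies with fewer than 3 records in either sample are skipped.
    Significance flags echo q < 0.005 and q < 0.001 marks.
    """
    rows = []
    for f in sorted(set(psy_by_freq) & set(eeg_by_freq)):
        x = np.asarray(psy_by_freq[f], dtype=float)
        y = np.asarray(eeg_by_freq[f], dtype=float)
        if x.size < 3 or y.size < 3:
            continue
        u, p = _ranksum_p(x, y)
        rows.append(dict(frequency_hz=f, n_psy=x.size, n_eeg=y.size,
                         statistic=u, p=p))
    table = pd.DataFrame(rows)
    if not table.empty:
        if method == "storey":
            table["q"] = storey_qvalues(table["p"].to_numpy(), lam=lam)
        else:
            table["q"] = benjamini_hochberg(table["p"].to_numpy())
        table["sig_q005"] = table["q"] < 0.005
        table["sig_q001"] = table["q"] < 0.001
    return ComparisonResult(table, method)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with its t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need matched samples of length >= 3")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    rho, p = stats.pearsonr(x, y)
    return float(rho), float(p)
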