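"""Probit psychometric fitting and 50% visibility thresholds.

Detection probabilities (from subjective reports or from the z-score rule)
are modelled as a binomial GLM with a probit link and a linear predictor in
modulation depth: probit(p) = b0 + b1 * MD.  The visibility threshold is the
MD at p = 0.5, i.e. -b0 / b1.  Fits are gated as in the source analysis: a
negative slope, a non-positive threshold, or a residual deviance >= 1
invalidate the estimate (invalidity is a value, not an exception).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "PsychometricFit",
    "ThresholdRecord",
    "fit_probit",
    "threshold_from_fit",
    "detection_curves",
    "DEVIANCE_LIMIT",
]

#: Residual-deviance gate: only fits with deviance below one are kept.
DEVIANCE_LIMIT = 1.0

#: |slope| beyond which the fit is treated as separated/degenerate.
_SEPARATION_SLOPE = 1e8


@dataclass
class PsychometricFit:
    """Probit GLM fit of detection probability against modulation depth."""

    md: np.ndarray
    detected: np.ndarray
    trials: np.ndarray
    beta0: float
    beta1: float
    deviance: float
    converged: bool
    separated: bool
    source: str = "subjective"  # or "electrophysiological"
    frequency_hz: Optional[int] = None

    def predict(self, md) -> np.ndarray:
        from scipy.stats import norm

        return norm.cdf(self.beta0 + self.beta1 * np.asarray(md, float))


@dataclass
class ThresholdRecord:
    """50% visibility threshold extracted from a psychometric fit."""

    subject_id: Optional[str]
    source: str
    frequency_hz: Optional[int]
    threshold_md: float
    sensitivity: float
    valid: bool
    invalid_reason: Optional[str]  # negative_slope | negative_threshold |
    # high_deviance | separation
    deviance: float


def fit_probit(
    md,
    detected,
    trials,
    source: str = "subjective",
    frequency_hz: Optional[int] = None,
    use_log_md: bool = False,
) -> PsychometricFit:
    """Maximum-likelihood binomial probit GLM of detections against MD.

    ``detected`` and ``trials`` are per-MD counts.  Residual deviance is
    reported against the saturated model.  Perfect separation or
    non-convergence yields a flagged (separated) fit rather than an
    exception; downstream gating treats it as invalid.
    """
    md = np.asarray(md, dtype=float)
    detected = np.asarray(detected, dtype=float)
    trials = np.asarray(trials, dtype=float)
    if md.size < 3 or np.unique(md).size < 3:
        raise ValueError("need at least 3 distinct modulation depths")
    if np.any(detected > trials) or np.any(detected < 0):
        raise ValueError("detected counts must lie in [0, trials]")
    x = np.log(md) if use_log_md else md
    exog = sm.add_constant(x)
    endog = np.column_stack([detected, trials - detected])
    family = sm.families.Binomial(link=sm.families.links.Probit())
    beta0 = beta1 = np.nan
    deviance = np.inf
    converged = False
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(endog, exog, family=family).fit(maxiter=200)
        beta0, beta1 = (float(v) for v in res.params)
        deviance = float(res.deviance)
        converged = bool(res.converged)
        if (
            not np.isfinite([beta0, beta1]).all()
            or abs(beta1) > _SEPARATION_SLOPE
            or not converged
        ):
            separated = True
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        separated = True
    # all-or-nothing data cannot constrain a finite slope
    p_obs = np.divide(detected, trials, out=np.zeros_like(detected),
                      where=trials > 0)
    if np.all(p_obs == 1.0) or np.all(p_obs == 0.0):
        separated = True
    return PsychometricFit(
        md, detected, trials, beta0, beta1, deviance, converged,
        separated, source, frequency_hz,
    )


def threshold_from_fit(
    fit: PsychometricFit, subject_id: Optional[str] = None
) -> ThresholdRecord:
    """50% threshold -b0/b1 with the validity gates.

    Invalid when the fit is separated, the slope is non-positive, the
    threshold is non-positive, or the deviance is >= 1.
    """
    reason: Optional[str] = None
    threshold = np.nan
    if fit.separated:
        reason = "separation"
    elif fit.beta1 <= 0.0:
        reason = "negative_slope"
    else:
        threshold = -fit.beta0 / fit.beta1
        if threshold <= 0.0:
            reason = "negative_threshold"
        elif fit.deviance >= DEVIANCE_LIMIT:
            reason = "high_deviance"
    valid = reason is None
    sensitivity = 1.0 / threshold if valid else np.nan
    return ThresholdRecord(
        subject_id, fit.source, fit.frequency_hz,
        float(threshold) if valid else np.nan,
        float(sensitivity), valid, reason, fit.deviance,
    )


def detection_curves(
    trials: pd.DataFrame,
    response_column: str,
    rejected_column: Optional[str] = None,
) -> pd.DataFrame:
    """Detection probability per (subject, frequency, MD).

    ``trials`` needs columns subject_id, frequency_hz, md and the boolean
    ``response_column``; rows flagged in ``rejected_column`` (when present)
    are excluded from numerator and denominator.  Rows with a missing
    response (e.g. experiments without subjective reports) are dropped.
    """
    df = trials.copy()
    if rejected_column is not None and rejected_column in df.columns:
        df = df[~df[rejected_column].astype(bool)]
    df = df[df[response_column].notna()]
    if df.empty:
        return pd.DataFrame(
            columns=["subject_id", "frequency_hz", "md", "n", "detected",
                     "probability"]
        )
    grouped = (
        df.assign(_resp=df[response_column].astype(float))
        .groupby(["subject_id", "frequency_hz", "md"], as_index=False)
        .agg(n=("_resp", "size"), detected=("_resp", "sum"))
    )
    grouped["probability"] = grouped["detected"] / grouped["n"]
    return grouped
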