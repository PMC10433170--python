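"""Spectral analysis and SSVEP detection statistics.

Each 3-s epoch at 256 Hz is analysed with the FFT in three non-overlapping
1-s rectangular windows (1 Hz resolution, bins 1..128); the per-bin value is
the log10 of the mean amplitude over the three windows.  Baseline and
stimulation epochs of a condition are compared with Cohen's d on the pooled
standard deviation, the best responding harmonic (up to the 10th, below the
128 Hz Nyquist) is the bin maximising d, and per-epoch z-scores against the
baseline distribution at that bin with a cutoff of zero classify each trial
as having a detectable response or not.

A per-frequency quality-control check flags stimulation frequencies whose
subject-wise maxima of Cohen's d do not concentrate on the expected harmonic
bins (noise-like conditions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FREQ_BINS",
    "EpochSpectrumError",
    "epoch_spectrum",
    "cohens_d_spectrum",
    "best_harmonic",
    "best_channel",
    "zscore_epochs",
    "detect",
    "qc_frequency",
    "HarmonicSelection",
    "QCResult",
]

ANALYSIS_RATE = 256.0
WINDOW_SAMPLES = 256  # 1-s windows -> 1 Hz bins
N_WINDOWS = 3
EPOCH_SAMPLES = WINDOW_SAMPLES * N_WINDOWS
NYQUIST_HZ = 128
MAX_HARMONIC = 10

#: Frequencies (Hz) of the spectrum bins; value ``i`` is at FREQ_BINS[i].
FREQ_BINS = np.arange(1, NYQUIST_HZ + 1)


class EpochSpectrumError(ValueError):
    pass


def epoch_spectrum(epoch: np.ndarray) -> np.ndarray:
    """Log-amplitude spectrum of a 3-s epoch at 256 Hz.

    The epoch is split into three 256-sample rectangular windows; the value
    at integer frequency f in 1..128 Hz is log10 of the mean over windows of
    the FFT amplitude at that bin.  Returns an array of 128 values indexed
    bin f at position f - 1.
    """
    x = np.asarray(epoch, dtype=float).squeeze()
    if x.ndim != 1 or x.size != EPOCH_SAMPLES:
        raise EpochSpectrumError(
            f"expected a 1-D epoch of {EPOCH_SAMPLES} samples, got shape "
            f"{np.shape(epoch)}"
        )
    windows = x.reshape(N_WINDOWS, WINDOW_SAMPLES)
    amp = np.abs(np.fft.rfft(windows, axis=1))  # bins 0..128
    mean_amp = amp.mean(axis=0)[1:]  # drop DC -> bins 1..128
    with np.errstate(divide="ignore"):
        return np.log10(mean_amp)


def cohens_d_spectrum(
    stim_spectra: np.ndarray, base_spectra: np.ndarray
) -> np.ndarray:
    """Per-bin Cohen's d between stimulation and baseline log-spectra.

    d(f) = (mean_S - mean_B) / s_pooled with the classical pooled SD
    s^2 = ((n_S - 1) s_S^2 + (n_B - 1) s_B^2) / (n_S + n_B - 2).
    Bins with zero pooled SD get d = 0 with a warning.
    """
    s = np.atleast_2d(np.asarray(stim_spectra, float))
    b = np.atleast_2d(np.asarray(base_spectra, float))
    if s.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least two epochs per group")
    n_s, n_b = s.shape[0], b.shape[0]
    var_s = s.var(axis=0, ddof=1)
    var_b = b.var(axis=0, ddof=1)
    pooled = np.sqrt(
        ((n_s - 1) * var_s + (n_b - 1) * var_b) / (n_s + n_b - 2)
    )
    diff = s.mean(axis=0) - b.mean(axis=0)
    zero = pooled == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} spectrum bins have zero pooled SD; "
            "Cohen's d set to 0 there",
            RuntimeWarning,
        )
    d = np.zeros_like(diff)
    np.divide(diff, pooled, out=d, where=~zero)
    return d


@dataclass
class HarmonicSelection:
    """Best responding harmonic of one stimulation frequency."""

    frequency_hz: int
    harmonic: int
    bin_hz: int
    candidate_d: dict[int, float] = field(default_factory=dict)


def candidate_harmonics(frequency_hz: int,
                        max_harmonic: int = MAX_HARMONIC) -> list[int]:
    """Harmonic indices h with h * F below the 128 Hz Nyquist."""
    return [
        h for h in range(1, max_harmonic + 1)
        if h * frequency_hz < NYQUIST_HZ
    ]


def best_harmonic(
    d_spectrum: np.ndarray,
    frequency_hz: int,
    max_harmonic: int = MAX_HARMONIC,
) -> HarmonicSelection:
    """argmax over harmonics of Cohen's d at h * F; ties -> smaller h."""
    candidates = candidate_harmonics(frequency_hz, max_harmonic)
    if not candidates:
        raise ValueError(
            f"no harmonic of {frequency_hz} Hz lies below {NYQUIST_HZ} Hz"
        )
    d = np.asarray(d_spectrum, dtype=float)
    values = {h: float(d[h * frequency_hz - 1]) for h in candidates}
    best = max(candidates, key=lambda h: (values[h], -h))
    return HarmonicSelection(
        frequency_hz, best, best * frequency_hz, values
    )


def best_channel(
    d_by_channel: dict[str, float]
) -> tuple[str, pd.DataFrame]:
    """Channel with the largest Cohen's d at the selected bin.

    Ties resolve to the earlier channel in the input (canonical) order.
    Returns the winning label and a ranking table.
    """
    if not d_by_channel:
        raise ValueError("no channels supplied")
    labels = list(d_by_channel)
    ranking = pd.DataFrame(
        {"channel": labels, "cohens_d": [d_by_channel[c] for c in labels]}
    ).sort_values("cohens_d", ascending=False, kind="stable")
    return str(ranking.iloc[0]["channel"]), ranking.reset_index(drop=True)


def zscore_epochs(
    stim_spectra: np.ndarray,
    base_spectra: np.ndarray,
    bin_hz: int,
) -> np.ndarray:
    """Per-epoch z-scores of stimulation spectra against the baseline
    distribution at one bin: z_i = (x_Si - mean_B) / sd_B."""
    s = np.atleast_2d(np.asarray(stim_spectra, float))
    b = np.atleast_2d(np.asarray(base_spectra, float))
    idx = int(bin_hz) - 1
    if not 0 <= idx < s.shape[1]:
        raise ValueError(f"bin {bin_hz} Hz outside the spectrum")
    mu = b[:, idx].mean()
    sd = b[:, idx].std(ddof=1)
    if sd == 0.0:
        raise ValueError("baseline SD is zero at the requested bin")
    return (s[:, idx] - mu) / sd


def detect(z: np.ndarray) -> tuple[np.ndarray, float]:
    """Trial-wise detection: response 1 iff z > 0 (strict), plus the
    detection probability (mean response)."""
    z = np.asarray(z, dtype=float)
    responses = (z > 0.0).astype(int)
    return responses, float(responses.mean()) if z.size else 0.0


@dataclass
class QCResult:
    """Per-frequency quality control diagnostics."""

    frequency_hz: int
    include: bool
    alignment_fraction: float
    mean_best_d: float
    argmax_bins: list[int]


def qc_frequency(
    subject_d_spectra: Sequence[np.ndarray],
    frequency_hz: int,
    alignment_threshold: float = 0.25,
    d_threshold: float = 0.05,
    max_harmonic: int = MAX_HARMONIC,
) -> QCResult:
    """Check that subject-wise Cohen's d maxima align with harmonic bins.

    For each subject the global argmax bin of d over [3, 127] Hz is found;
    the frequency is kept when the fraction landing exactly on an expected
    harmonic bin is >= ``alignment_threshold`` AND the mean d at the best
    harmonic is >= ``d_threshold``.  A noise-only condition scatters its
    maxima uniformly and is excluded.
    """
    expected = {
        h * frequency_hz
        for h in candidate_harmonics(frequency_hz, max_harmonic)
    }
    argmax_bins: list[int] = []
    best_ds: list[float] = []
    for d in subject_d_spectra:
        d = np.asarray(d, dtype=float)
        search = d[2:127]  # bins 3..127 Hz
        argmax_bins.append(int(np.argmax(search)) + 3)
        sel = best_harmonic(d, frequency_hz, max_harmonic)
        best_ds.append(sel.candidate_d[sel.harmonic])
    frac = float(np.mean([b in expected for b in argmax_bins]))
    mean_d = float(np.mean(best_ds))
    include = frac >= alignment_threshold and mean_d >= d_threshold
    return QCResult(frequency_hz, include, frac, mean_d, argmax_bins)
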