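"""EEG signal conditioning and epoch hygiene.

The conditioning chain is: 50 Hz notch (IIR, Q = 30, zero-phase) ->
polyphase resampling to 256 Hz -> 2 Hz high-pass FIR (Hamming design,
1-2 Hz transition band, zero-phase).  Conditioned recordings are cut into
pairs of 3-s epochs around each stimulus onset (baseline before, stimulation
after), and trials whose broadband variance exceeds the condition mean plus
two standard deviations are rejected in a single pass.

An optional hook accepts an external ocular-artifact removal callable
(e.g. an ICA-based cleaner); none is bundled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Callable, Hashable, Optional, Sequence

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "EpochPair",
    "condition_signal",
    "common_average_reference",
    "segment_epochs",
    "reject_artifacts",
    "load_recording",
    "TARGET_RATE",
    "EPOCH_DURATION",
]

TARGET_RATE = 256.0  # Hz, analysis rate
EPOCH_DURATION = 3.0  # s per baseline/stimulation epoch


@dataclass
class Recording:
    """Multi-channel signal with event markers.

    ``data`` is (channels, samples) in microvolts; ``events`` is a list of
    (sample index, label) pairs, kept sorted by sample.
    """

    data: np.ndarray
    rate: float
    events: list[tuple[int, Hashable]] = field(default_factory=list)
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channels:
            self.channels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel names do not match data rows")
        self.events = sorted(self.events, key=lambda e: e[0])
        n = self.data.shape[1]
        for s, _ in self.events:
            if not 0 <= s < n:
                raise ValueError(f"event at sample {s} outside record")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochPair:
    """Baseline and stimulation segments of one trial."""

    trial_id: Hashable
    baseline: np.ndarray  # (channels, samples), microvolts
    stimulation: np.ndarray
    rate: float
    condition: Optional[object] = None
    subjective_report: Optional[bool] = None  # absent where not collected

    def __post_init__(self) -> None:
        self.baseline = np.atleast_2d(np.asarray(self.baseline, float))
        self.stimulation = np.atleast_2d(np.asarray(self.stimulation, float))
        if self.baseline.shape != self.stimulation.shape:
            raise ValueError("baseline and stimulation shapes differ")


def _highpass_fir(rate: float, cutoff: float = 2.0,
                  transition: float = 1.0) -> np.ndarray:
    """Hamming-window high-pass FIR with the given transition width."""
    numtaps = int(np.ceil(3.3 * rate / transition))
    numtaps += 1 - numtaps % 2  # force odd length
    return signal.firwin(
        numtaps, cutoff - transition / 2.0, window="hamming",
        pass_zero=False, fs=rate,
    )


def condition_signal(
    rec: Recording,
    target_rate: float = TARGET_RATE,
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
    highpass_hz: float = 2.0,
    ocular_removal: Optional[Callable[[np.ndarray, float], np.ndarray]] = None,
) -> Recording:
    """Notch, resample and high-pass a recording (all zero-phase).

    ``ocular_removal``, if given, is called with the resampled
    (channels, samples) array and the rate, and must return a cleaned array
    of the same shape; it stands in for component-based blink removal.
    Event indices are rescaled to the new rate.
    """
    if rec.rate < 512:
        raise ValueError(
            "conditioning expects an acquisition rate >= 512 Hz; "
            f"got {rec.rate} Hz"
        )
    b, a = signal.iirnotch(notch_hz, notch_q, fs=rec.rate)
    data = signal.filtfilt(b, a, rec.data, axis=1)

    frac = Fraction(int(round(target_rate)), int(round(rec.rate)))
    data = signal.resample_poly(data, frac.numerator, frac.denominator,
                                axis=1)

    if ocular_removal is not None:
        cleaned = ocular_removal(data, target_rate)
        if np.shape(cleaned) != data.shape:
            raise ValueError("ocular_removal must preserve the array shape")
        data = np.asarray(cleaned, dtype=float)

    taps = _highpass_fir(target_rate, highpass_hz)
    padlen = min(3 * len(taps), data.shape[1] - 1)
    data = signal.filtfilt(taps, [1.0], data, axis=1, padlen=padlen)

    scale = target_rate / rec.rate
    events = [(int(round(s * scale)), lab) for s, lab in rec.events]
    events = [(min(s, data.shape[1] - 1), lab) for s, lab in events]
    return Recording(data, target_rate, events, list(rec.channels))


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across channels from every channel."""
    if rec.data.shape[0] < 2:
        warnings.warn(
            "common average reference on a single channel is the identity",
            RuntimeWarning,
        )
        return replace(rec, data=rec.data.copy())
    car = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=car)


def segment_epochs(
    rec: Recording,
    onsets: Optional[Sequence[tuple[int, Hashable]]] = None,
    duration: float = EPOCH_DURATION,
) -> list[EpochPair]:
    """Cut [onset - d, onset) baseline and [onset, onset + d) stimulation
    windows around each marker; truncated trials are dropped with a log
    entry."""
    if onsets is None:
        onsets = rec.events
    w = round(duration * rec.rate)
    n = rec.n_samples
    pairs: list[EpochPair] = []
    for onset, label in onsets:
        if onset - w < 0 or onset + w > n:
            logger.info(
                "dropping trial %r: window [%d, %d) outside record of %d "
                "samples", label, onset - w, onset + w, n,
            )
            continue
        pairs.append(
            EpochPair(
                label,
                rec.data[:, onset - w:onset].copy(),
                rec.data[:, onset:onset + w].copy(),
                rec.rate,
            )
        )
    return pairs


def reject_artifacts(
    pairs_by_condition: dict[Hashable, Sequence[EpochPair]],
    channel: int = 0,
    sd_factor: float = 2.0,
) -> tuple[dict[Hashable, list[EpochPair]], dict[Hashable, np.ndarray]]:
    """Single-pass variance-based trial rejection per condition.

    For each condition the broadband variance of every trial's stimulation
    epoch (at ``channel``) is computed; trials with variance above
    mean + ``sd_factor`` * SD of the condition's variances are rejected.
    Returns the kept pairs and a boolean rejection mask per condition.
    """
    kept: dict[Hashable, list[EpochPair]] = {}
    masks: dict[Hashable, np.ndarray] = {}
    n_total = n_rejected = 0
    for cond, pairs in pairs_by_condition.items():
        if len(pairs) < 3:
            raise ValueError(
                f"condition {cond!r} has fewer than 3 trials; variance "
                "screening is not meaningful"
            )
        variances = np.array(
            [np.var(p.stimulation[channel]) for p in pairs]
        )
        thr = variances.mean() + sd_factor * variances.std(ddof=1)
        mask = variances > thr
        if mask.all():
            raise ValueError(
                f"all trials rejected for condition {cond!r}"
            )
        masks[cond] = mask
        kept[cond] = [p for p, rej in zip(pairs, mask) if not rej]
        n_total += len(pairs)
        n_rejected += int(mask.sum())
    logger.info(
        "artifact rejection: %d/%d trials rejected (%.1f%%)",
        n_rejected, n_total, 100.0 * n_rejected / max(n_total, 1),
    )
    return kept, masks


def load_recording(path, stim_channel: Optional[str] = None) -> Recording:
    """Read a BDF/EDF recording into a :class:`Recording`.

    Requires the optional ``mne`` dependency.  Events are taken from the
    file's annotations or from ``stim_channel`` when given.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading BDF/EDF files requires the optional 'mne' dependency"
        ) from exc
    path = str(path)
    if path.lower().endswith(".bdf"):
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if stim_channel is not None and stim_channel in raw.ch_names:
        events = mne.find_events(raw, stim_channel=stim_channel,
                                 verbose="error")
        raw = raw.drop_channels([stim_channel])
        ev = [(int(s), int(code)) for s, _, code in events]
    else:
        ann = mne.events_from_annotations(raw, verbose="error")[0]
        ev = [(int(s), int(code)) for s, _, code in ann]
    return Recording(
        raw.get_data() * 1e6,  # volts -> microvolts
        float(raw.info["sfreq"]),
        ev,
        list(raw.ch_names),
    )
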