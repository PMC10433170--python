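"""Stimulation conditions and photometric waveforms.

Square-wave luminance flicker is described by its temporal frequency ``F``
(Hz), its Michelson modulation depth ``MD`` in [0, 1], and the average
luminance level ``AvgLL``.  Four experiments sample (F, MD) cells around a
reference temporal contrast sensitivity curve (TCSC): some use absolute
modulation depths, others express MD as a multiple of the visibility
threshold 1/sensitivity at that frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .reference_tcsc import SensitivityCurve

__all__ = [
    "Condition",
    "Waveform",
    "FourierComponent",
    "michelson_md",
    "square_waveform",
    "square_fourier_components",
    "experiment_conditions",
    "conditions_to_csv",
    "conditions_from_csv",
    "EXPERIMENT_FREQUENCIES",
    "distinct_frequencies",
]

#: Stimulation frequencies per experiment (Hz).
EXPERIMENT_FREQUENCIES: dict[int, tuple[int, ...]] = {
    1: (8, 24, 32, 40, 48),
    2: (6, 24, 32, 40, 60),
    3: (7, 13, 19, 37, 48, 60),
    4: (4, 6, 8, 13, 19),
}

#: Threshold multipliers for the relative-MD experiments.
RELATIVE_MULTIPLIERS: dict[int, tuple[float, ...]] = {
    1: (0.6, 0.8, 1.0, 1.2, 1.4),
    3: (0.6, 0.8, 1.0, 1.2, 1.4),
}

#: Experiment 2 uses absolute modulation depths.
ABSOLUTE_MDS_EXP2: tuple[float, ...] = (0.002, 0.008, 0.014, 0.020, 0.026)

#: Experiment 4 multipliers depend on frequency: a lower ladder at 4 Hz.
EXP4_MULTIPLIERS_4HZ: tuple[float, ...] = (0.4, 0.8, 1.6, 3.2, 4.8, 6.4)
EXP4_MULTIPLIERS_OTHER: tuple[float, ...] = (0.8, 1.6, 3.2, 6.4, 9.6, 12.8)

#: Default repetitions of every condition.
DEFAULT_REPETITIONS = 10


@dataclass(frozen=True)
class Condition:
    """One (experiment, frequency, modulation depth) stimulation cell."""

    experiment_id: int
    frequency_hz: int
    md: float
    md_rule: str = "absolute"  # "absolute" | "relative"
    multiplier: Optional[float] = None
    repetitions: int = DEFAULT_REPETITIONS

    def __post_init__(self) -> None:
        if self.experiment_id not in (1, 2, 3, 4):
            raise ValueError(f"unknown experiment id {self.experiment_id}")
        if not 0.0 <= self.md <= 1.0:
            raise ValueError(f"MD must lie in [0, 1], got {self.md}")
        if self.frequency_hz < 1:
            raise ValueError("stimulation frequency must be >= 1 Hz")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.md_rule not in ("absolute", "relative"):
            raise ValueError(f"unknown md_rule {self.md_rule!r}")

    @property
    def label(self) -> str:
        return f"E{self.experiment_id}-F{self.frequency_hz}-MD{self.md:g}"


@dataclass
class Waveform:
    """Luminance time series of one square-wave flicker stimulus."""

    samples: np.ndarray  # lux
    rate: float  # samples/s
    duration: float  # s
    avg_ll: float  # mean luminance, lux
    frequency_hz: float
    md: float


@dataclass(frozen=True)
class FourierComponent:
    """One Fourier component of a light waveform, relative to its DC level."""

    m: int  # harmonic index, 1-based
    freq: float  # Hz
    amplitude: float  # C_m = |FFT component| / DC, dimensionless


def michelson_md(l_max: float, l_min: float) -> float:
    """Michelson contrast (Lmax - Lmin) / (Lmax + Lmin).

    Raises
    ------
    ValueError
        If a luminance is negative or ``l_max < l_min``.
    """
    if l_min < 0 or l_max <= 0:
        raise ValueError("luminances must be non-negative with l_max > 0")
    if l_max < l_min:
        raise ValueError("l_max must be >= l_min")
    return (l_max - l_min) / (l_max + l_min)


def square_waveform(
    frequency_hz: float,
    md: float,
    avg_ll: float = 1000.0,
    duration: float = 3.0,
    rate: float = 2048.0,
) -> Waveform:
    """Square-wave luminance flicker AvgLL * (1 + sgn(sin(2 pi F t)) * MD).

    The sign at exact zero crossings is taken as +1 (half-open duty
    convention), which affects at most two samples per cycle.
    """
    if not 0.0 <= md <= 1.0:
        raise ValueError("MD must lie in [0, 1]")
    if frequency_hz >= rate / 2:
        raise ValueError("stimulation frequency must be below Nyquist")
    n = round(duration * rate)
    t = np.arange(n) / rate
    s = np.sin(2.0 * np.pi * frequency_hz * t)
    sgn = np.where(s >= 0.0, 1.0, -1.0)
    samples = avg_ll * (1.0 + sgn * md)
    return Waveform(samples, rate, duration, avg_ll, frequency_hz, md)


def square_fourier_components(
    md: float, frequency_hz: float, f_cap: float = 60.0
) -> list[FourierComponent]:
    """Fourier components of an ideal square wave relative to its DC value.

    Only odd harmonics carry energy: C_m = (4 / pi) * MD / m.  Components
    are returned for odd m with m * F <= f_cap; even harmonics (C = 0) are
    omitted.
    """
    if not 0.0 <= md <= 1.0:
        raise ValueError("MD must lie in [0, 1]")
    if f_cap <= frequency_hz and not math.isclose(f_cap, frequency_hz):
        raise ValueError("f_cap must be >= the fundamental frequency")
    out = []
    m = 1
    while m * frequency_hz <= f_cap + 1e-12:
        out.append(
            FourierComponent(m, m * frequency_hz, (4.0 / np.pi) * md / m)
        )
        m += 2
    return out


def _relative_md(multiplier: float, curve: "SensitivityCurve", f: float) -> float:
    """MD as multiplier x visibility threshold, clamped to [0, 1]."""
    return min(1.0, multiplier * curve.threshold(f))


def experiment_conditions(
    experiment_id: int,
    reference_curve: Optional["SensitivityCurve"] = None,
    repetitions: int = DEFAULT_REPETITIONS,
) -> list[Condition]:
    """Build the stimulation-condition grid of one experiment.

    Experiments 1, 3 and 4 express modulation depths relative to a reference
    sensitivity curve and therefore require ``reference_curve``; experiment 2
    uses absolute MDs.
    """
    if experiment_id not in EXPERIMENT_FREQUENCIES:
        raise ValueError(f"unknown experiment id {experiment_id}")
    freqs = EXPERIMENT_FREQUENCIES[experiment_id]
    conditions: list[Condition] = []
    if experiment_id == 2:
        for f in freqs:
            for md in ABSOLUTE_MDS_EXP2:
                conditions.append(
                    Condition(2, f, md, "absolute", None, repetitions)
                )
        return conditions
    if reference_curve is None:
        raise ValueError(
            f"experiment {experiment_id} uses threshold-relative MDs; "
            "a reference sensitivity curve is required"
        )
    if experiment_id in (1, 3):
        for f in freqs:
            for mult in RELATIVE_MULTIPLIERS[experiment_id]:
                conditions.append(
                    Condition(
                        experiment_id,
                        f,
                        _relative_md(mult, reference_curve, f),
                        "relative",
                        mult,
                        repetitions,
                    )
                )
        return conditions
    # experiment 4: six multipliers, a lower ladder at 4 Hz
    for f in freqs:
        mults = EXP4_MULTIPLIERS_4HZ if f == 4 else EXP4_MULTIPLIERS_OTHER
        for mult in mults:
            conditions.append(
                Condition(
                    4, f, _relative_md(mult, reference_curve, f),
                    "relative", mult, repetitions,
                )
            )
    return conditions


def distinct_frequencies(
    experiment_ids: Sequence[int] = (1, 2, 3, 4)
) -> list[int]:
    """Sorted distinct stimulation frequencies across experiments."""
    freqs: set[int] = set()
    for e in experiment_ids:
        freqs.update(EXPERIMENT_FREQUENCIES[e])
    return sorted(freqs)


def conditions_to_csv(conditions: Sequence[Condition], path) -> None:
    pd.DataFrame(
        {
            "experiment_id": [c.experiment_id for c in conditions],
            "frequency_hz": [c.frequency_hz for c in conditions],
            "md": [c.md for c in conditions],
            "md_rule": [c.md_rule for c in conditions],
            "multiplier": [c.multiplier for c in conditions],
            "repetitions": [c.repetitions for c in conditions],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def conditions_from_csv(path) -> list[Condition]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        mult = None if pd.isna(row.multiplier) else float(row.multiplier)
        out.append(
            Condition(
                int(row.experiment_id),
                int(row.frequency_hz),
                float(row.md),
                str(row.md_rule),
                mult,
                int(row.repetitions),
            )
        )
    return out
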