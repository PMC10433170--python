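"""Reference temporal contrast sensitivity curves and the flicker
visibility measure (FVM).

A sensitivity curve maps temporal frequency (Hz) to contrast sensitivity,
the reciprocal of the Michelson-contrast visibility threshold.  Two forms
are supported: the cubic/linear rational polynomial

    TCSC(f) = scale * (p1 f^3 + p2 f^2 + p3 f + p4) / (f + q1)

and a tabulated curve interpolated linearly in log-log coordinates.

The FVM predicts whether a periodic light waveform is visible from its
Fourier components: each component's relative modulation C_m is normalised
by the visibility threshold T_m at its frequency and the contributions are
combined by Minkowski summation (default exponent 2).  FVM < 1 means not
visible, 1 just visible, > 1 visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .stimulus import FourierComponent

__all__ = [
    "SensitivityCurve",
    "FvmResult",
    "curve_sensitivity",
    "curve_threshold",
    "fvm",
    "default_psychophysical_curve",
    "default_electrophysiological_curve",
    "PSYCHOPHYSICAL_RATIONAL",
    "ELECTROPHYSIOLOGICAL_RATIONAL",
]

#: Rational-polynomial coefficients (p1, p2, p3, p4, q1) of the
#: psychophysical sensitivity fit, and the peak sensitivity the curve is
#: anchored to (the printed coefficients reproduce the peak location but
#: not its absolute level, so the default curve is rescaled to the peak).
PSYCHOPHYSICAL_RATIONAL = (-0.0008, -0.409, 40.68, 121.50, 10.75)
PSYCHOPHYSICAL_PEAK_SENSITIVITY = 309.0

#: Same for the electrophysiological sensitivity fit.
ELECTROPHYSIOLOGICAL_RATIONAL = (0.014, -1.69, 71.75, 155.90, 22.65)
ELECTROPHYSIOLOGICAL_PEAK_SENSITIVITY = 258.0

DEFAULT_DOMAIN = (1.0, 60.0)

_JUST_VISIBLE_TOL = 1e-9


def _rational(f, p1, p2, p3, p4, q1):
    f = np.asarray(f, dtype=float)
    return (p1 * f**3 + p2 * f**2 + p3 * f + p4) / (f + q1)


@dataclass
class SensitivityCurve:
    """Contrast sensitivity as a function of temporal frequency.

    Exactly one of ``coefficients`` (rational form) or ``table`` (tabulated
    form) is set.  ``scale`` multiplies the curve; queries outside
    ``domain`` raise rather than extrapolate silently.
    """

    label: str = "curve"
    coefficients: Optional[tuple[float, float, float, float, float]] = None
    table: Optional[tuple[np.ndarray, np.ndarray]] = None  # (freq, sens)
    domain: tuple[float, float] = DEFAULT_DOMAIN
    scale: float = 1.0

    def __post_init__(self) -> None:
        if (self.coefficients is None) == (self.table is None):
            raise ValueError(
                "exactly one of coefficients or table must be given"
            )
        if self.table is not None:
            f, s = (np.asarray(a, dtype=float) for a in self.table)
            if f.ndim != 1 or f.shape != s.shape or f.size < 2:
                raise ValueError("table needs matching 1-D freq/sens arrays")
            if np.any(np.diff(f) <= 0):
                order = np.argsort(f)
                f, s = f[order], s[order]
            if np.any(s <= 0) or np.any(f <= 0):
                raise ValueError("tabulated frequencies/sensitivities must be > 0")
            self.table = (f, s)
            self.domain = (float(f[0]), float(f[-1]))

    # -- factories ---------------------------------------------------------

    @classmethod
    def rational(
        cls,
        coefficients: Sequence[float],
        label: str = "rational",
        domain: tuple[float, float] = DEFAULT_DOMAIN,
        scale: float = 1.0,
    ) -> "SensitivityCurve":
        if len(coefficients) != 5:
            raise ValueError("rational form needs (p1, p2, p3, p4, q1)")
        return cls(label, tuple(float(c) for c in coefficients), None,
                   domain, scale)

    @classmethod
    def tabulated(
        cls, frequencies, sensitivities, label: str = "tabulated"
    ) -> "SensitivityCurve":
        return cls(label, None, (np.asarray(frequencies, float),
                                 np.asarray(sensitivities, float)))

    @classmethod
    def from_csv(cls, path, label: Optional[str] = None) -> "SensitivityCurve":
        df = pd.read_csv(path)
        return cls.tabulated(
            df["frequency_hz"].to_numpy(),
            df["sensitivity"].to_numpy(),
            label or str(path),
        )

    @classmethod
    def from_json(cls, path) -> "SensitivityCurve":
        with open(path) as fh:
            payload = json.load(fh)
        return cls.rational(
            [payload[k] for k in ("p1", "p2", "p3", "p4", "q1")],
            label=payload.get("label", "rational"),
            domain=tuple(payload.get("domain", DEFAULT_DOMAIN)),
            scale=float(payload.get("scale", 1.0)),
        )

    def to_json(self, path) -> None:
        if self.coefficients is None:
            raise ValueError("only rational curves serialise to JSON")
        p1, p2, p3, p4, q1 = self.coefficients
        with open(path, "w") as fh:
            json.dump(
                {"label": self.label, "p1": p1, "p2": p2, "p3": p3,
                 "p4": p4, "q1": q1, "scale": self.scale,
                 "domain": list(self.domain)},
                fh, indent=2,
            )

    # -- evaluation --------------------------------------------------------

    def _check_domain(self, f: np.ndarray) -> None:
        lo, hi = self.domain
        if np.any(f < lo - 1e-12) or np.any(f > hi + 1e-12):
            raise ValueError(
                f"frequency outside curve domain [{lo}, {hi}] Hz; "
                "no silent extrapolation"
            )

    def sensitivity(self, f) -> np.ndarray | float:
        """Contrast sensitivity at frequency ``f`` (Hz)."""
        arr = np.asarray(f, dtype=float)
        self._check_domain(arr)
        if self.coefficients is not None:
            out = self.scale * _rational(arr, *self.coefficients)
        else:
            ft, st = self.table
            out = self.scale * np.exp(
                np.interp(np.log(arr), np.log(ft), np.log(st))
            )
        return float(out) if np.isscalar(f) else out

    def threshold(self, f) -> np.ndarray | float:
        """Visibility threshold 1/sensitivity, clamped to <= 1 (an MD)."""
        s = np.asarray(self.sensitivity(f), dtype=float)
        if np.any(s <= 0):
            raise ValueError("nonpositive sensitivity has no threshold")
        out = np.minimum(1.0, 1.0 / s)
        return float(out) if np.isscalar(f) else out

    def peak(self, step: float = 0.01) -> tuple[float, float]:
        """(frequency, sensitivity) of the curve maximum on its domain."""
        lo, hi = self.domain
        grid = np.arange(lo, hi + step / 2, step)
        vals = np.asarray(self.sensitivity(grid))
        i = int(np.argmax(vals))
        a, b = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
        if a < b:
            res = minimize_scalar(
                lambda x: -float(self.sensitivity(x)),
                bounds=(a, b), method="bounded",
            )
            if -res.fun >= vals[i]:
                return float(res.x), float(-res.fun)
        return float(grid[i]), float(vals[i])


def curve_sensitivity(curve: SensitivityCurve, f) -> np.ndarray | float:
    """Functional alias for :meth:`SensitivityCurve.sensitivity`."""
    return curve.sensitivity(f)


def curve_threshold(curve: SensitivityCurve, f) -> np.ndarray | float:
    """Functional alias for :meth:`SensitivityCurve.threshold`."""
    return curve.threshold(f)


def default_psychophysical_curve() -> SensitivityCurve:
    """Psychophysical reference TCSC: printed rational shape, rescaled so
    the peak sensitivity equals 309."""
    raw = SensitivityCurve.rational(
        PSYCHOPHYSICAL_RATIONAL, label="psychophysical"
    )
    _, peak_val = raw.peak()
    raw.scale = PSYCHOPHYSICAL_PEAK_SENSITIVITY / peak_val
    return raw


def default_electrophysiological_curve() -> SensitivityCurve:
    """Electrophysiological reference TCSC, peak anchored to 258."""
    raw = SensitivityCurve.rational(
        ELECTROPHYSIOLOGICAL_RATIONAL, label="electrophysiological"
    )
    _, peak_val = raw.peak()
    raw.scale = ELECTROPHYSIOLOGICAL_PEAK_SENSITIVITY / peak_val
    return raw


@dataclass
class FvmResult:
    """Outcome of the flicker visibility measure."""

    value: float
    verdict: str  # "not_visible" | "just_visible" | "visible"
    contributions: list[tuple[float, float]] = field(default_factory=list)
    # (component frequency, (C_m / T_m)^exponent)


def fvm(
    components: Iterable[FourierComponent],
    curve: SensitivityCurve,
    exponent: float = 2.0,
) -> FvmResult:
    """Flicker visibility measure of a waveform's Fourier components.

    value = ( sum_m (C_m / T_m)^exponent )^(1/exponent), with T_m the
    visibility threshold at the component's frequency.  Components above
    the curve's domain are treated as invisible (T = inf, contribution 0);
    components below the domain raise.  An empty component list yields 0.
    """
    lo, hi = curve.domain
    total = 0.0
    contributions: list[tuple[float, float]] = []
    for comp in components:
        if comp.freq > hi + 1e-12:
            contributions.append((comp.freq, 0.0))
            continue
        if comp.freq < lo - 1e-12:
            raise ValueError(
                f"component at {comp.freq} Hz below curve domain {lo} Hz"
            )
        t_m = float(curve.threshold(comp.freq))
        c = (comp.amplitude / t_m) ** exponent
        contributions.append((comp.freq, c))
        total += c
    value = total ** (1.0 / exponent) if total > 0 else 0.0
    if abs(value - 1.0) <= _JUST_VISIBLE_TOL:
        verdict = "just_visible"
    elif value < 1.0:
        verdict = "not_visible"
    else:
        verdict = "visible"
    return FvmResult(value, verdict, contributions)
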