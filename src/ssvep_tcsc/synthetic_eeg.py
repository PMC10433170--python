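"""Synthetic multi-subject SSVEP dataset with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: ongoing EEG with a 1/f amplitude spectrum and an alpha bump,
steady-state responses at the stimulation frequency and its harmonics whose
total amplitude grows linearly with log contrast above an electrophysiological
threshold, and a probit psychophysical observer producing yes/no reports.
Every subject carries its own thresholds, so estimator output can be checked
against ground truth.

Two generation modes exist: ``epochs`` synthesises 3-s baseline/stimulation
pairs directly at the 256 Hz analysis rate (fast; the default for simulation
studies), and ``continuous`` synthesises a full 2048 Hz recording with event
markers so the complete conditioning chain can be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .preprocess import EpochPair, Recording
from .reference_tcsc import SensitivityCurve, default_psychophysical_curve
from .stimulus import Condition, experiment_conditions

__all__ = [
    "SubjectProfile",
    "DatasetConfig",
    "Dataset",
    "draw_profile",
    "synth_background",
    "ssvep_amplitude",
    "synth_trial",
    "generate_subject_recording",
    "generate_dataset",
    "STUDY_COHORT_SIZES",
]

#: Cohort sizes of the four flicker experiments (total 62 participants).
STUDY_COHORT_SIZES = {1: 10, 2: 12, 3: 24, 4: 16}

#: Harmonics are generated below this frequency (the analysis Nyquist).
HARMONIC_CAP_HZ = 128.0

#: Offset of the log-contrast amplitude law: response amplitude becomes
#: positive at MD = 10**(-C0) * theta_eeg, slightly below threshold.
LOG_CONTRAST_OFFSET = 0.05

#: Ratio theta_eeg / theta_psy as a function of frequency: the
#: electrophysiological threshold sits above the psychophysical one at low
#: frequencies and below it at 60 Hz (sensitivity curves cross near 50 Hz).
_KAPPA_FREQ = np.array([1.0, 45.0, 50.0, 60.0, 128.0])
_KAPPA_VAL = np.array([1.2, 1.2, 1.0, 0.8, 0.8])


def eeg_threshold_ratio(f) -> np.ndarray | float:
    """Frequency-dependent ratio of electrophysiological to psychophysical
    visibility thresholds."""
    out = np.interp(np.asarray(f, dtype=float), _KAPPA_FREQ, _KAPPA_VAL)
    return float(out) if np.isscalar(f) else out


@dataclass
class SubjectProfile:
    """Ground-truth observer model for one synthetic subject."""

    subject_id: str
    reference_curve: SensitivityCurve
    psy_threshold_scale: float = 1.0  # multiplies the reference threshold
    eeg_threshold_scale: float = 1.0  # extra multiplier on theta_eeg
    rel_slope: float = 0.15  # psychometric SD as a fraction of threshold
    guess_rate: float = 0.02
    lapse_rate: float = 0.02
    gain: float = 1.0  # microvolts of SSVEP per log10-contrast unit
    alpha_freq: float = 10.0  # Hz
    alpha_amp: float = 1.0  # relative height of the alpha bump
    noise_exponent: float = 1.0  # 1/f^alpha amplitude spectrum
    background_rms: float = 10.0  # microvolts
    channel_gains: dict[str, float] = field(
        default_factory=lambda: {"Pz": 1.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.guess_rate <= 0.1 and 0 <= self.lapse_rate <= 0.1):
            raise ValueError("guess/lapse rates must lie in [0, 0.1]")
        if self.gain <= 0 or self.psy_threshold_scale <= 0:
            raise ValueError("gains and threshold scales must be positive")

    def psy_threshold(self, f) -> float:
        """Subject's psychophysical visibility threshold at frequency f."""
        return min(1.0, self.psy_threshold_scale
                   * float(self.reference_curve.threshold(f)))

    def eeg_threshold(self, f) -> float:
        """Subject's electrophysiological visibility threshold at f."""
        return min(
            1.0,
            self.eeg_threshold_scale * eeg_threshold_ratio(f)
            * self.psy_threshold(f),
        )

    def detection_probability(self, f: float, md: float) -> float:
        """Probability the probit observer reports seeing the flicker."""
        theta = self.psy_threshold(f)
        sigma = self.rel_slope * theta
        p = norm.cdf((md - theta) / sigma)
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * p


def draw_profile(
    subject_id: str,
    rng: np.random.Generator,
    reference_curve: Optional[SensitivityCurve] = None,
    **overrides,
) -> SubjectProfile:
    """Sample a subject profile with realistic inter-individual spread.

    Thresholds jitter log-normally (~15% SD psychophysical, an extra ~10%
    electrophysiological), the alpha peak is drawn from N(10, 1) Hz, and
    the SSVEP gain varies ~20% around its default.
    """
    if reference_curve is None:
        reference_curve = default_psychophysical_curve()
    defaults = dict(
        psy_threshold_scale=float(10.0 ** rng.normal(0.0, 0.06)),
        eeg_threshold_scale=float(10.0 ** rng.normal(0.0, 0.04)),
        alpha_freq=float(np.clip(rng.normal(10.0, 1.0), 7.5, 13.0)),
        alpha_amp=float(np.clip(rng.normal(1.0, 0.3), 0.0, 2.0)),
        gain=float(DEFAULT_GAIN_UV * 10.0 ** rng.normal(0.0, 0.08)),
        noise_exponent=float(np.clip(rng.normal(1.0, 0.1), 0.7, 1.3)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    defaults.update(overrides)
    return SubjectProfile(subject_id, reference_curve, **defaults)


#: Default SSVEP gain (microvolts per log10-contrast unit).  Chosen so that
#: the response amplitude reached at the electrophysiological threshold is
#: comparable to the background spectral amplitude in a 1-s analysis window
#: at gamma-band frequencies -- the near-threshold regime the detection
#: statistics are designed for.
DEFAULT_GAIN_UV = 6.0


def synth_background(
    duration: float,
    rate: float,
    profile: SubjectProfile,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random-phase background EEG: 1/f^a amplitude spectrum plus a Gaussian
    alpha bump, zero mean, RMS set by the profile."""
    n = round(duration * rate)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.zeros_like(freqs)
    above = freqs >= 1.0
    shape[above] = freqs[above] ** (-profile.noise_exponent)
    bump = profile.alpha_amp * np.exp(
        -0.5 * ((freqs - profile.alpha_freq) / 1.5) ** 2
    )
    shape *= 1.0 + bump
    coeff = shape * (
        rng.standard_normal(freqs.size)
        + 1j * rng.standard_normal(freqs.size)
    ) / np.sqrt(2.0)
    x = np.fft.irfft(coeff, n=n)
    x -= x.mean()
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x *= profile.background_rms / rms
    return x


def _target_harmonic(frequency_hz: float, harmonics: Sequence[int]) -> int:
    """Harmonic that carries the largest weight.

    Below 20 Hz the response is dominated by the even harmonic closest to
    40 Hz (ties resolved to the smaller harmonic); at and above 20 Hz the
    fundamental dominates.
    """
    if frequency_hz >= 20.0:
        return 1
    even = [h for h in harmonics if h % 2 == 0]
    if not even:
        return 1
    return min(even, key=lambda h: (abs(h * frequency_hz - 40.0), h))


def ssvep_amplitude(
    profile: SubjectProfile, frequency_hz: float, md: float
) -> list[tuple[int, float, float]]:
    """Per-harmonic SSVEP amplitudes (harmonic, frequency, microvolts).

    The total amplitude follows A = gain * max(0, log10(MD / theta_eeg) + c0)
    with c0 = 0.05, distributed over harmonics h*F < 128 Hz with the largest
    weight on the dominant harmonic (see :func:`_target_harmonic`).
    """
    if not 0.0 <= md <= 1.0:
        raise ValueError("MD must lie in [0, 1]")
    harmonics = [
        h for h in range(1, 11) if h * frequency_hz < HARMONIC_CAP_HZ
    ]
    if md <= 0.0:
        return [(h, h * frequency_hz, 0.0) for h in harmonics]
    theta = profile.eeg_threshold(frequency_hz)
    total = profile.gain * max(
        0.0, np.log10(md / theta) + LOG_CONTRAST_OFFSET
    )
    target = _target_harmonic(frequency_hz, harmonics)
    raw = np.array([1.0 / (1.0 + abs(h - target)) ** 2 for h in harmonics])
    weights = raw / raw.sum()
    return [
        (h, h * frequency_hz, total * w)
        for h, w in zip(harmonics, weights)
    ]


def synth_trial(
    profile: SubjectProfile,
    condition: Condition,
    seed: Optional[int] = None,
    rate: float = 256.0,
    duration: float = 3.0,
    trial_id: Hashable = 0,
) -> EpochPair:
    """One trial: background-only baseline, background + SSVEP stimulation,
    and a Bernoulli subjective report from the probit observer."""
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    channels = list(profile.channel_gains)
    t = np.arange(round(duration * rate)) / rate
    amps = ssvep_amplitude(profile, condition.frequency_hz, condition.md)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(amps))
    ssvep = np.zeros_like(t)
    for (h, f, a), phi in zip(amps, phases):
        if a > 0.0 and f < rate / 2.0:
            ssvep += a * np.sin(2.0 * np.pi * f * t + phi)
    baseline = np.empty((len(channels), t.size))
    stimulation = np.empty_like(baseline)
    for i, ch in enumerate(channels):
        baseline[i] = synth_background(duration, rate, profile, rng)
        stimulation[i] = (
            synth_background(duration, rate, profile, rng)
            + profile.channel_gains[ch] * ssvep
        )
    p_yes = profile.detection_probability(condition.frequency_hz,
                                          condition.md)
    report = bool(rng.uniform() < p_yes)
    return EpochPair(trial_id, baseline, stimulation, rate, condition, report)


def generate_subject_recording(
    profile: SubjectProfile,
    conditions: Sequence[Condition],
    rng: np.random.Generator,
    rate: float = 2048.0,
    lead_s: float = 4.0,
    iti_s: float = 1.0,
) -> tuple[Recording, pd.DataFrame]:
    """Continuous recording for one subject: an uninterrupted background with
    SSVEP bursts added in each 3-s stimulation window, plus event markers.

    Trials (all conditions x repetitions) are presented in randomised order.
    Returns the recording and its trial table.
    """
    trial_conditions = [
        c for c in conditions for _ in range(c.repetitions)
    ]
    order = rng.permutation(len(trial_conditions))
    trial_conditions = [trial_conditions[i] for i in order]

    step = 2 * 3.0 + iti_s  # baseline + stimulation + inter-trial interval
    total_s = lead_s + step * len(trial_conditions) + lead_s
    n = round(total_s * rate)
    channels = list(profile.channel_gains)
    data = np.empty((len(channels), n))
    for i in range(len(channels)):
        data[i] = synth_background(total_s, rate, profile, rng)

    rows = []
    events: list[tuple[int, Hashable]] = []
    w = round(3.0 * rate)
    for k, cond in enumerate(trial_conditions):
        onset = round((lead_s + step * k + 3.0) * rate)
        t = np.arange(w) / rate
        amps = ssvep_amplitude(profile, cond.frequency_hz, cond.md)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=len(amps))
        ssvep = np.zeros(w)
        for (h, f, a), phi in zip(amps, phases):
            if a > 0.0 and f < rate / 2.0:
                ssvep += a * np.sin(2.0 * np.pi * f * t + phi)
        for i, ch in enumerate(channels):
            data[i, onset:onset + w] += profile.channel_gains[ch] * ssvep
        p_yes = profile.detection_probability(cond.frequency_hz, cond.md)
        report = bool(rng.uniform() < p_yes)
        trial_id = f"{profile.subject_id}-t{k:04d}"
        events.append((onset, trial_id))
        rows.append(
            dict(
                subject_id=profile.subject_id,
                experiment_id=cond.experiment_id,
                trial_id=trial_id,
                frequency_hz=cond.frequency_hz,
                md=cond.md,
                md_rule=cond.md_rule,
                multiplier=cond.multiplier,
                subjective_report=report,
            )
        )
    rec = Recording(data, rate, events, channels)
    return rec, pd.DataFrame(rows)


@dataclass
class DatasetConfig:
    """What to simulate: experiments, cohort sizes and generation mode."""

    experiments: tuple[int, ...] = (2, 3)
    cohort_sizes: dict[int, int] = field(
        default_factory=lambda: dict(STUDY_COHORT_SIZES)
    )
    repetitions: int = 10
    rate: float = 256.0
    mode: str = "epochs"  # "epochs" (direct 256 Hz) | "continuous" (2048 Hz)
    reference_curve: Optional[SensitivityCurve] = None
    profile_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("epochs", "continuous"):
            raise ValueError("mode must be 'epochs' or 'continuous'")


@dataclass
class Dataset:
    """Synthetic cohort: trial table, epoch store and ground truth."""

    trials: pd.DataFrame
    epochs: dict[Hashable, EpochPair]
    profiles: dict[str, SubjectProfile]
    recordings: dict[str, Recording]
    ground_truth: dict

    def ground_truth_frame(self) -> pd.DataFrame:
        rows = []
        for sid, per_f in self.ground_truth["subjects"].items():
            for f, d in per_f.items():
                rows.append(dict(subject_id=sid, frequency_hz=f, **d))
        return pd.DataFrame(rows)


def generate_dataset(
    config: DatasetConfig, master_seed: int = 0
) -> Dataset:
    """Simulate a cohort per experiment, reproducibly from ``master_seed``.

    The seed hierarchy is master -> experiment -> subject -> trial, so any
    trial can be regenerated in isolation from the recorded per-trial seed.
    """
    curve = config.reference_curve or default_psychophysical_curve()
    master = np.random.SeedSequence(master_seed)
    exp_seeds = master.spawn(len(config.experiments))

    all_rows: list[pd.DataFrame | dict] = []
    epochs: dict[Hashable, EpochPair] = {}
    profiles: dict[str, SubjectProfile] = {}
    recordings: dict[str, Recording] = {}
    truth: dict = {"master_seed": int(master_seed), "subjects": {}}

    for exp, ss in zip(config.experiments, exp_seeds):
        conditions = experiment_conditions(
            exp, reference_curve=curve, repetitions=config.repetitions
        )
        n_subj = config.cohort_sizes[exp]
        subj_seeds = ss.spawn(n_subj)
        for j, sseq in enumerate(subj_seeds):
            rng = np.random.default_rng(sseq)
            sid = f"E{exp}S{j:02d}"
            profile = draw_profile(
                sid, rng, reference_curve=curve,
                **config.profile_overrides,
            )
            profiles[sid] = profile
            truth["subjects"][sid] = {
                int(c.frequency_hz): dict(
                    theta_psy=profile.psy_threshold(c.frequency_hz),
                    theta_eeg=profile.eeg_threshold(c.frequency_hz),
                )
                for c in conditions
            }
            if config.mode == "continuous":
                rec, table = generate_subject_recording(
                    profile, conditions, rng, rate=config.rate
                    if config.rate >= 512 else 2048.0,
                )
                recordings[sid] = rec
                all_rows.append(table)
                continue
            trial_conditions = [
                c for c in conditions for _ in range(c.repetitions)
            ]
            order = rng.permutation(len(trial_conditions))
            rows = []
            for k, idx in enumerate(order):
                cond = trial_conditions[idx]
                trial_seed = int(rng.integers(0, 2**31 - 1))
                trial_id = f"{sid}-t{k:04d}"
                pair = synth_trial(
                    profile, cond, seed=trial_seed, rate=config.rate,
                    trial_id=trial_id,
                )
                if exp == 1:  # no subjective reports were collected
                    pair.subjective_report = None
                epochs[trial_id] = pair
                rows.append(
                    dict(
                        subject_id=sid,
                        experiment_id=exp,
                        trial_id=trial_id,
                        frequency_hz=cond.frequency_hz,
                        md=cond.md,
                        md_rule=cond.md_rule,
                        multiplier=cond.multiplier,
                        subjective_report=pair.subjective_report,
                        seed=trial_seed,
                    )
                )
            all_rows.append(pd.DataFrame(rows))

    for frame in all_rows:
        frame["subjective_report"] = frame["subjective_report"].astype(
            "boolean"
        )
    trials = pd.concat(
        [r for r in all_rows if isinstance(r, pd.DataFrame)],
        ignore_index=True,
    )
    return Dataset(trials, epochs, profiles, recordings, truth)
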