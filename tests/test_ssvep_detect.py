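import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssvep_tcsc.ssvep_detect import (
    EPOCH_SAMPLES,
    FREQ_BINS,
    best_channel,
    best_harmonic,
    cohens_d_spectrum,
    detect,
    epoch_spectrum,
    qc_frequency,
    zscore_epochs,
)


def _brute_force_dft_bin(window: np.ndarray, f: int) -> float:
    """Independent oracle: direct DFT sum at one integer-Hz bin."""
    n = window.size
    k = np.arange(n)
    return abs(np.sum(window * np.exp(-2j * np.pi * f * k / n)))


class TestEpochSpectrum:
    def test_one_hertz_resolution_128_bins(self):
        assert FREQ_BINS.size == 128
        assert np.all(np.diff(FREQ_BINS) == 1)

    def test_pure_tone_dominates_its_bin(self):
        t = np.arange(EPOCH_SAMPLES) / 256.0
        spec = epoch_spectrum(np.sin(2 * np.pi * 10 * t))
        assert int(np.argmax(spec)) + 1 == 10

    def test_matches_brute_force_dft(self, rng):
        x = rng.standard_normal(EPOCH_SAMPLES)
        spec = epoch_spectrum(x)
        windows = x.reshape(3, 256)
        for f in rng.choice(np.arange(1, 129), size=5, replace=False):
            oracle = np.log10(
                np.mean([_brute_force_dft_bin(w, int(f)) for w in windows])
            )
            assert abs(spec[int(f) - 1] - oracle) < 1e-9

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            epoch_spectrum(np.zeros(500))


class TestCohensD:
    def test_identical_groups_zero(self, rng):
        x = rng.standard_normal((4, 128))
        d = cohens_d_spectrum(x, x)
        assert np.allclose(d, 0.0)

    def test_hand_computed_pooled_sd(self):
        stim = np.array([[1.5], [1.6], [1.7]])
        base = np.array([[1.0], [1.2], [1.1]])
        d = cohens_d_spectrum(np.tile(stim, 128), np.tile(base, 128))
        s2 = ((2 * np.var([1.5, 1.6, 1.7], ddof=1)
               + 2 * np.var([1.0, 1.2, 1.1], ddof=1)) / 4)
        expected = (np.mean([1.5, 1.6, 1.7]) - np.mean([1.0, 1.2, 1.1])) \
            / np.sqrt(s2)
        assert d[0] == pytest.approx(expected, rel=1e-12)

    def test_degenerate_sd_warns_and_zeroes(self):
        stim = np.zeros((2, 128))
        base = np.ones((2, 128))
        with pytest.warns(RuntimeWarning):
            d = cohens_d_spectrum(stim, base)
        assert np.all(d == 0.0)

    @settings(max_examples=25, derandomize=True)
    @given(shift=st.floats(-5.0, 5.0))
    def test_location_shift_invariance(self, shift):
        rng = np.random.default_rng(0)
        stim = rng.standard_normal((5, 128))
        base = rng.standard_normal((6, 128))
        d0 = cohens_d_spectrum(stim, base)
        d1 = cohens_d_spectrum(stim + shift, base + shift)
        np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestBestHarmonic:
    def test_candidate_sets(self):
        d = np.zeros(128)
        assert set(best_harmonic(d, 40).candidate_d) == {1, 2, 3}
        assert set(best_harmonic(d, 60).candidate_d) == {1, 2}

    def test_ties_prefer_smaller_harmonic(self):
        d = np.zeros(128)
        sel = best_harmonic(d, 24)
        assert sel.harmonic == 1 and sel.bin_hz == 24

    def test_picks_energetic_harmonic(self):
        d = np.zeros(128)
        d[4 * 8 - 1] = 2.0  # energy on the 4th harmonic of 8 Hz
        sel = best_harmonic(d, 8)
        assert sel.harmonic == 4 and sel.bin_hz == 32

    def test_frequency_above_nyquist_errors(self):
        with pytest.raises(ValueError):
            best_harmonic(np.zeros(128), 130)


class TestBestChannel:
    def test_dominant_channel_selected(self):
        label, ranking = best_channel({"Oz": 0.4, "Pz": 0.9, "Cz": 0.1})
        assert label == "Pz"
        assert list(ranking["channel"]) == ["Pz", "Oz", "Cz"]

    def test_ties_resolve_to_canonical_order(self):
        label, _ = best_channel({"Pz": 0.5, "Oz": 0.5})
        assert label == "Pz"

    def test_synthetic_multichannel_pz_dominant(self, ref_curve):
        """With spatially scaled SSVEP copies, the Pz-dominant gain map
        makes Pz win the per-channel Cohen's d ranking."""
        from ssvep_tcsc.ssvep_detect import epoch_spectrum as spec
        from ssvep_tcsc.stimulus import Condition
        from ssvep_tcsc.synthetic_eeg import SubjectProfile, synth_trial

        profile = SubjectProfile(
            "s", ref_curve,
            channel_gains={"Pz": 1.0, "Oz": 0.6, "Cz": 0.2},
        )
        cond = Condition(2, 24, 0.026, "absolute")
        stim = {ch: [] for ch in profile.channel_gains}
        base = {ch: [] for ch in profile.channel_gains}
        for s in range(8):
            p = synth_trial(profile, cond, seed=s)
            for i, ch in enumerate(profile.channel_gains):
                stim[ch].append(spec(p.stimulation[i]))
                base[ch].append(spec(p.baseline[i]))
        d_at_bin = {
            ch: cohens_d_spectrum(np.array(stim[ch]),
                                  np.array(base[ch]))[24 - 1]
            for ch in stim
        }
        label, _ = best_channel(d_at_bin)
        assert label == "Pz"


class TestZScore:
    def test_trivial_values(self):
        base = np.zeros((4, 128))
        base[:, 9] = [1.0, 1.2, 0.8, 1.0]
        mu = base[:, 9].mean()
        sd = base[:, 9].std(ddof=1)
        stim = np.zeros((2, 128))
        stim[0, 9] = mu
        stim[1, 9] = mu + sd
        z = zscore_epochs(stim, base, 10)
        np.testing.assert_allclose(z, [0.0, 1.0], atol=1e-12)

    def test_batch_matches_loop(self, rng):
        stim = rng.standard_normal((7, 128))
        base = rng.standard_normal((9, 128))
        z = zscore_epochs(stim, base, 42)
        mu, sd = base[:, 41].mean(), base[:, 41].std(ddof=1)
        for i in range(7):
            assert z[i] == pytest.approx((stim[i, 41] - mu) / sd)

    def test_zero_baseline_sd_errors(self):
        with pytest.raises(ValueError):
            zscore_epochs(np.ones((2, 128)), np.ones((3, 128)), 5)

    def test_mean_z_equals_d_times_sd_ratio(self, rng):
        """Algebraic identity: mean over stimulation epochs of z equals
        Cohen's d scaled by pooled-to-baseline SD ratio."""
        stim = rng.standard_normal((6, 128)) + 0.3
        base = rng.standard_normal((6, 128))
        z = zscore_epochs(stim, base, 17)
        d = cohens_d_spectrum(stim, base)[16]
        n_s = n_b = 6
        pooled = np.sqrt(
            ((n_s - 1) * stim[:, 16].var(ddof=1)
             + (n_b - 1) * base[:, 16].var(ddof=1)) / (n_s + n_b - 2)
        )
        assert z.mean() == pytest.approx(
            d * pooled / base[:, 16].std(ddof=1), rel=1e-9
        )


class TestDetect:
    def test_strict_zero_cutoff(self):
        responses, prob = detect(np.array([-0.5, 0.0, 1e-12, 2.0]))
        assert responses.tolist() == [0, 0, 1, 1]
        assert prob == 0.5

    def test_null_rate_near_half(self, rng):
        """Under the null (no signal) the z > 0 rule fires at chance."""
        hits = 0
        total = 0
        for _ in range(250):
            stim = rng.standard_normal((10, 128))
            base = rng.standard_normal((10, 128))
            z = zscore_epochs(stim, base, 24)
            hits += int((z > 0).sum())
            total += z.size
        assert 0.45 <= hits / total <= 0.55

    def test_monotone_in_signal_amplitude(self):
        """Detection probability rises with injected SSVEP amplitude."""
        rng = np.random.default_rng(42)
        t = np.arange(EPOCH_SAMPLES) / 256.0
        probs = []
        for amp in (0.0, 1.0, 3.0, 9.0):
            hits = total = 0
            for _ in range(60):
                sig = amp * np.sin(2 * np.pi * 24 * t)
                stim = np.array([
                    epoch_spectrum(rng.standard_normal(EPOCH_SAMPLES) * 5
                                   + sig)
                    for _ in range(10)
                ])
                base = np.array([
                    epoch_spectrum(rng.standard_normal(EPOCH_SAMPLES) * 5)
                    for _ in range(10)
                ])
                z = zscore_epochs(stim, base, 24)
                hits += int((z > 0).sum())
                total += z.size
            probs.append(hits / total)
        assert all(b >= a - 0.05 for a, b in zip(probs, probs[1:]))
        assert probs[-1] > probs[0]


class TestQcFrequency:
    def test_strong_ssvep_included(self, rng):
        spectra = []
        for _ in range(8):
            d = rng.normal(0.0, 0.02, size=128)
            d[24 - 1] = 1.0
            spectra.append(d)
        qc = qc_frequency(spectra, 24)
        assert qc.include
        assert qc.alignment_fraction == 1.0

    def test_noise_only_excluded(self):
        rng = np.random.default_rng(0)
        spectra = [rng.normal(0.0, 0.05, size=128) for _ in range(12)]
        qc = qc_frequency(spectra, 7)
        assert not qc.include

    def test_threshold_boundary_is_inclusive(self):
        """Alignment fraction exactly at the threshold keeps the
        frequency (>= rule)."""
        spectra = []
        for i in range(4):
            d = np.zeros(128)
            d[24 - 1] = 0.5
            if i > 0:  # 3 of 4 subjects peak off-harmonic
                d[50 - 1] = 1.0
            spectra.append(d)
        qc = qc_frequency(spectra, 24, alignment_threshold=0.25)
        assert qc.alignment_fraction == pytest.approx(0.25)
        assert qc.include
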