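import numpy as np
import pytest
from scipy.signal import spectrogram

from gabashift.eeg import (
    WaveletSpec,
    frontal_gamma_summary,
    induced_vs_evoked,
    morlet_power,
    reject_artifacts,
)
from gabashift.synthetic_data import EpochSet, simulate_eeg


def make_epochs(data, labels=None, sfreq=250.0, tmin=-0.4, channels=("E23", "E24")):
    if labels is None:
        labels = np.array(["low"] * data.shape[0])
    return EpochSet(data=data, sfreq=sfreq, tmin=tmin, channels=list(channels), labels=labels)


class TestRejection:
    def test_flat_epochs_kept(self):
        ep = make_epochs(np.zeros((5, 2, 575)))
        assert reject_artifacts(ep).all()

    def test_range_threshold(self):
        data = np.zeros((3, 2, 575))
        data[1, 0, 100] = 250.0  # 250 uV range on one channel
        ep = make_epochs(data)
        kept = reject_artifacts(ep)
        assert not kept[1] and kept[0] and kept[2]

    @pytest.mark.parametrize("step,expected", [(61.0, False), (59.0, True)])
    def test_gradient_boundary(self, step, expected):
        data = np.zeros((1, 2, 575))
        data[0, 0, 200:] = step  # single-sample jump; range stays <= 200
        ep = make_epochs(data)
        assert reject_artifacts(ep)[0] is np.True_ if expected else not reject_artifacts(ep)[0]

    def test_rejection_monotone_in_thresholds(self, rng):
        data = rng.normal(0, 40, size=(50, 2, 575))
        ep = make_epochs(data)
        kept = [
            reject_artifacts(ep, range_limit_uv=r, gradient_limit_uv=g).sum()
            for r, g in [(300, 90), (200, 60), (150, 45), (100, 30)]
        ]
        assert all(a >= b for a, b in zip(kept, kept[1:]))


class TestMorlet:
    def test_zero_signal_zero_power(self):
        ep = make_epochs(np.zeros((3, 2, 575)))
        tf = morlet_power(ep, baseline_correct=False)
        assert np.allclose(tf.power, 0.0)

    def test_pure_sinusoid_peaks_at_42hz_subband(self):
        spec = WaveletSpec()
        t = -0.4 + np.arange(575) / 250.0
        sig = np.cos(2 * np.pi * 42.0 * t)
        ep = make_epochs(np.tile(sig, (2, 2, 1)))
        tf = morlet_power(ep, spec, baseline_correct=False)
        mid = (tf.times > 0.0) & (tf.times < 1.0)
        band = tf.power[0, 0][:, mid].mean(axis=1)
        peak_f = tf.frequencies[int(np.argmax(band))]
        step = np.diff(tf.frequencies)[0]
        assert abs(peak_f - 42.0) <= step
        # unit-amplitude normalization: peak power ~ 1
        assert band.max() == pytest.approx(1.0, rel=0.05)

    def test_frequency_independent_sinusoid_response(self):
        spec = WaveletSpec()
        t = -0.4 + np.arange(575) / 250.0
        peaks = []
        for f0 in (20.0, 45.0, 70.0):
            sig = np.cos(2 * np.pi * f0 * t)
            ep = make_epochs(np.tile(sig, (1, 2, 1)))
            tf = morlet_power(ep, spec, baseline_correct=False)
            fi = int(np.argmin(np.abs(tf.frequencies - f0)))
            mid = (tf.times > 0.2) & (tf.times < 1.0)
            peaks.append(tf.power[0, 0, fi][mid].mean())
        assert np.ptp(peaks) / np.mean(peaks) < 0.2

    def test_localization_matches_stft_oracle(self):
        ep = simulate_eeg(n_trials=4, seed=5, noise_sd=0.0)
        spec = WaveletSpec()
        tf = morlet_power(ep, spec, baseline_correct=False)
        flat = tf.power[0, 0]
        fi, ti = np.unravel_index(np.argmax(flat), flat.shape)
        f_spec, t_spec, S = spectrogram(ep.data[0, 0], fs=250.0, nperseg=128, noverlap=112)
        sfi, sti = np.unravel_index(np.argmax(S), S.shape)
        step = np.diff(tf.frequencies)[0]
        assert abs(tf.frequencies[fi] - f_spec[sfi]) <= step + np.diff(f_spec)[0]
        sigma_t = spec.sigma_t(tf.frequencies[fi])
        assert abs(tf.times[ti] - (t_spec[sti] - 0.4)) <= sigma_t + (t_spec[1] - t_spec[0])

    def test_white_noise_power_scales_with_variance(self, rng):
        totals = []
        variances = (1.0, 4.0, 9.0)
        base = rng.standard_normal((20, 1, 575))
        for v in variances:
            ep = make_epochs(np.sqrt(v) * base, channels=("E23",))
            tf = morlet_power(ep, baseline_correct=False)
            totals.append(tf.power.mean())
        ratios = np.asarray(totals) / np.asarray(variances)
        assert np.ptp(ratios) / ratios.mean() < 1e-9  # exactly linear in variance

    def test_epoch_too_short_for_lowest_band(self):
        ep = make_epochs(np.zeros((2, 2, 40)))
        with pytest.raises(ValueError):
            morlet_power(ep)


class TestInducedVsEvoked:
    def test_phase_locked_bursts_equal(self):
        t = -0.4 + np.arange(575) / 250.0
        env = ((t >= 0.5) & (t <= 1.5)).astype(float)
        sig = env * np.cos(2 * np.pi * 42.0 * t)
        ep = make_epochs(np.tile(sig, (10, 2, 1)))
        ind, ev = induced_vs_evoked(ep)
        assert np.allclose(ind.power, ev.power, atol=1e-10)

    def test_random_phase_suppresses_evoked(self):
        ep = simulate_eeg(n_trials_per_condition=(100, 100), seed=3)
        ind, ev = induced_vs_evoked(ep)
        fi = int(np.argmin(np.abs(ind.frequencies - 42.0)))
        delay = (ind.times >= 0.5) & (ind.times <= 1.5)
        li = ind.conditions.index("low")
        ratio = abs(ev.power[li, 0, fi][delay].mean()) / ind.power[li, 0, fi][delay].mean()
        assert ratio < 0.1

    def test_dc_offset_removed_by_baseline_correction(self):
        ep = make_epochs(np.full((4, 2, 575), 25.0))
        ind, ev = induced_vs_evoked(ep)
        assert np.allclose(ind.power, 0.0, atol=1e-12)
        assert np.allclose(ev.power, 0.0, atol=1e-12)


class TestFrontalSummary:
    def test_null_contrast_when_conditions_equal(self):
        ep = simulate_eeg(
            n_trials=120, seed=9, gamma_amplitude_by_condition={"low": 1.5, "high": 1.5}
        )
        tf = morlet_power(ep)
        with pytest.warns(UserWarning):
            s = frontal_gamma_summary(tf)
        assert abs(s["contrast"]) < 0.3 * s["low"]

    def test_stronger_high_condition_gives_positive_contrast(self):
        hits = 0
        for seed in range(10):
            ep = simulate_eeg(
                n_trials=60, seed=seed, gamma_amplitude_by_condition={"low": 1.0, "high": 2.0}
            )
            tf = morlet_power(ep)
            with pytest.warns(UserWarning):
                s = frontal_gamma_summary(tf)
            hits += s["contrast"] > 0
        assert hits >= 9

    def test_missing_electrode_rejected(self):
        ep = simulate_eeg(n_trials=10, seed=0)
        tf = morlet_power(ep)
        with pytest.raises(ValueError):
            frontal_gamma_summary(tf, electrodes=("E99", "E24"))
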