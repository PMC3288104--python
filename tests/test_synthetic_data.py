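import numpy as np
import pytest

from gabashift.input_function import METABOLITE_SAMPLE_TIMES
from gabashift.kinetics import KineticParams, model_tac, vt
from gabashift.synthetic_data import (
    default_ground_truth,
    default_input_fit,
    params_for_vt,
    simulate_eeg,
    simulate_plasma,
    simulate_subject_pair,
    simulate_tac,
    total_plasma_at_frames,
)


class TestPlasma:
    def test_metabolite_sample_times(self):
        _, mets, _, _ = simulate_plasma()
        assert np.allclose(mets.time_min, METABOLITE_SAMPLE_TIMES)

    def test_no_metabolism_degenerate(self):
        _, mets, _, _ = simulate_plasma(parent_params=(0.0, 0.1, 1.0))
        assert np.allclose(mets.parent_fraction, 1.0)

    def test_single_exponential_tail_auc(self):
        # closed form A/lambda = 10/0.1 = 100 units*min from the peak
        _, _, parent_fit, _ = simulate_plasma(tail_params=((10.0, 0.1), (0.0, 1.0), (0.0, 1.0)))
        assert np.sum(parent_fit.amplitudes / parent_fit.rates) == pytest.approx(100.0)

    def test_invalid_parent_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate_plasma(parent_params=(0.9, 0.1, 0.4))  # fraction 1.3 at t=0

    def test_dense_early_sampling(self):
        plasma, _, _, _ = simulate_plasma()
        assert (plasma.time_min <= 2.0).sum() >= 20
        assert 30 <= len(plasma) <= 40

    def test_metabolite_correction_roundtrip(self):
        from gabashift.input_function import compute_input, fit_parent_fraction

        plasma, mets, parent_fit, _ = simulate_plasma()
        pf = fit_parent_fraction(mets.time_min, mets.parent_fraction)
        parent = compute_input(plasma.time_min, plasma.total_activity_kbq_ml, pf)
        assert np.allclose(parent, parent_fit(plasma.time_min.to_numpy()), rtol=1e-6)


class TestTac:
    def test_noiseless_equals_model(self, schedule, input_fit):
        p = KineticParams(0.4, 0.4, 0.3, 0.1)
        tac = simulate_tac(p, input_fit, schedule, blood_volume_fraction=0.0, noise_scale=0.0)
        assert np.allclose(tac.values, model_tac(p, input_fit, schedule))

    def test_blood_term_added(self, schedule, input_fit):
        p = KineticParams(0.4, 0.4, 0.3, 0.1)
        tac0 = simulate_tac(p, input_fit, schedule, 0.0, 0.0)
        tac5 = simulate_tac(p, input_fit, schedule, 0.05, 0.0)
        blood = 0.05 * total_plasma_at_frames(input_fit, schedule)
        assert np.allclose(tac5.values - tac0.values, blood)

    def test_seeded_determinism(self, schedule, input_fit):
        p = KineticParams(0.4, 0.4, 0.3, 0.1)
        a = simulate_tac(p, input_fit, schedule, 0.05, 0.1, seed=99)
        b = simulate_tac(p, input_fit, schedule, 0.05, 0.1, seed=99)
        assert np.array_equal(a.values, b.values)

    def test_noise_sd_scales_inversely_with_duration(self, schedule, input_fit):
        """Empirical frame SD across replicates follows sqrt(pred / duration)."""
        p = KineticParams(0.4, 0.4, 0.3, 0.1)
        noiseless = simulate_tac(p, input_fit, schedule, 0.0, 0.0).values
        reps = np.stack(
            [
                simulate_tac(p, input_fit, schedule, 0.0, 0.1, seed=i).values
                for i in range(200)
            ]
        )
        sd = reps.std(axis=0)
        # normalized SD should be flat across frames despite 40x duration range
        norm = sd / np.sqrt(noiseless / schedule.frame_duration)
        assert norm.std() / norm.mean() < 0.15


class TestSubjectPair:
    def test_null_shift_identity(self):
        truth = default_ground_truth(affinity_shift=1.0)
        pair = simulate_subject_pair(truth)
        for r in pair.params_baseline:
            assert vt(pair.params_post[r]) == pytest.approx(vt(pair.params_baseline[r]))

    def test_shift_arithmetic(self):
        # VT_post = vnd + s*(VT_base - vnd): 1 + 1.3*6 = 8.8
        p = params_for_vt(7.0, 0.4, 1.0)
        truth = default_ground_truth(affinity_shift=1.3, vnd_true=1.0)
        pair = simulate_subject_pair(truth)
        from gabashift.synthetic_data import shifted_params

        assert vt(shifted_params(p, 1.3)) == pytest.approx(8.8)
        for r, pb in pair.params_baseline.items():
            expected = 1.0 + 1.3 * (vt(pb) - 1.0)
            assert vt(pair.params_post[r]) == pytest.approx(expected, rel=1e-12)

    def test_k1_k2_untouched(self):
        pair = simulate_subject_pair(default_ground_truth(affinity_shift=1.27))
        for r in pair.params_baseline:
            assert pair.params_post[r].K1 == pair.params_baseline[r].K1
            assert pair.params_post[r].k2 == pair.params_baseline[r].k2

    def test_baseline_vt_magnitudes_study_plausible(self):
        pair = simulate_subject_pair(default_ground_truth())
        vts = np.array([vt(p) for p in pair.params_baseline.values()])
        assert vts.min() >= 5.0 and vts.max() <= 7.5

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            simulate_subject_pair(default_ground_truth(vnd_true=6.0))

    def test_seeded_determinism(self):
        t = default_ground_truth(noise_scale=0.1, seed=5)
        a = simulate_subject_pair(t)
        b = simulate_subject_pair(t)
        for r in a.tacs_baseline:
            assert np.array_equal(a.tacs_baseline[r].values, b.tacs_baseline[r].values)
            assert np.array_equal(a.tacs_post[r].values, b.tacs_post[r].values)


class TestEeg:
    def test_condition_ratio_70_30(self):
        ep = simulate_eeg(n_trials=200, seed=0)
        assert (ep.labels == "low").sum() == 140
        assert (ep.labels == "high").sum() == 60

    def test_epoch_geometry(self):
        ep = simulate_eeg(n_trials=10, seed=0)
        assert ep.sfreq == 250.0
        assert ep.times[0] == pytest.approx(-0.4)
        assert ep.times[-1] == pytest.approx(1.9, abs=0.005)

    def test_burst_confined_to_delay_window(self):
        quiet = simulate_eeg(n_trials=20, seed=1, noise_sd=0.0)
        t = quiet.times
        outside = (t < 0.5) | (t > 1.5)
        assert np.allclose(quiet.data[..., outside], 0.0)
        assert np.max(np.abs(quiet.data)) > 0

    def test_zero_amplitude_gives_no_delay_excess(self):
        ep = simulate_eeg(
            n_trials=60, seed=2, gamma_amplitude_by_condition={"low": 0.0, "high": 0.0}
        )
        from gabashift.eeg import WaveletSpec, morlet_power

        tf = morlet_power(ep, WaveletSpec())
        fi = int(np.argmin(np.abs(tf.frequencies - 42.0)))
        delay = (tf.times >= 0.5) & (tf.times <= 1.5)
        induced_raw = morlet_power(ep, WaveletSpec(), baseline_correct=False)
        base = (tf.times >= -0.3) & (tf.times <= -0.1)
        p_delay = induced_raw.power[:, :, fi, delay].mean()
        p_base = induced_raw.power[:, :, fi, base].mean()
        assert p_delay == pytest.approx(p_base, rel=0.3)

    def test_seeded_determinism(self):
        a = simulate_eeg(n_trials=10, seed=11)
        b = simulate_eeg(n_trials=10, seed=11)
        assert np.array_equal(a.data, b.data)
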