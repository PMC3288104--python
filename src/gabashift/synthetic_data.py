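"""Synthetic study data with known ground truth.

Generates the three raw-data streams the analysis consumes:

* arterial plasma sampling tables (total activity + metabolite parent
  fractions) built from a linear-rise / tri-exponential-tail parent curve,
* baseline / post-drug scan pairs of regional time-activity curves whose
  noiseless distribution volumes obey a regionally uniform multiplicative
  affinity shift of the specific compartment,
* EEG epochs of pink noise plus condition-scaled, phase-randomized 42 Hz
  bursts confined to the post-cue delay window.

Everything is seeded; identical seeds give bit-identical output.  Default
magnitudes follow the high-dose (0.25 mg/kg tiagabine) study arm: regional
baseline VT between roughly 5.1 and 7.2 mL/g, nondisplaceable volume near
1 mL/g, a 5% regional blood volume, and frame noise whose standard
deviation scales as sqrt(prediction / frame duration), the counting-
statistics stand-in that motivates frame-duration weighting in the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .input_function import InputFunctionFit, ParentFractionFit, METABOLITE_SAMPLE_TIMES
from .kinetics import KineticParams, TimeActivityCurve, vt
from .schedule import FrameSchedule, make_frame_schedule

__all__ = [
    "GroundTruth",
    "ScanPair",
    "make_frame_schedule",
    "default_input_fit",
    "default_ground_truth",
    "simulate_plasma",
    "simulate_tac",
    "simulate_subject_pair",
    "simulate_eeg",
    "EpochSet",
    "STUDY_ROIS",
]

# the ten component ROIs used for the Lassen analysis
STUDY_ROIS = ("DLPFC", "OFC", "MPFC", "ACC", "PC", "OC", "AMY", "HIP", "ENT", "PHG")

# baseline regional VT targets (mL/g), high-dose-arm magnitudes
_BASELINE_VT = {
    "DLPFC": 6.7, "OFC": 6.7, "MPFC": 7.1, "ACC": 7.2, "PC": 6.6,
    "OC": 7.0, "AMY": 5.2, "HIP": 5.1, "ENT": 5.1, "PHG": 5.4,
}
# baseline regional K1 (mL g-1 min-1)
_BASELINE_K1 = {
    "DLPFC": 0.407, "OFC": 0.394, "MPFC": 0.419, "ACC": 0.408, "PC": 0.412,
    "OC": 0.408, "AMY": 0.295, "HIP": 0.287, "ENT": 0.264, "PHG": 0.293,
}
_DEFAULT_K4 = 0.1  # min-1, dissociation rate used to place k3 given a VT target


@dataclass(frozen=True)
class GroundTruth:
    """Known kinetic truth for one simulated subject.

    ``params_baseline`` maps region -> KineticParams with K1/k2 equal to
    ``vnd_true`` in every region (regionally uniform nondisplaceable
    volume); ``affinity_shift`` s scales the specific distribution volume
    between the two scans so that, before noise,
    VT_post = vnd_true + s * (VT_base - vnd_true).
    """

    params_baseline: dict
    affinity_shift: float
    vnd_true: float
    blood_volume_fraction: float = 0.05
    noise_scale: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.affinity_shift < 0:
            raise ValueError("affinity shift must be >= 0")
        for region, p in self.params_baseline.items():
            if not np.isclose(p.K1 / p.k2, self.vnd_true, rtol=1e-9):
                raise ValueError(
                    f"region {region}: K1/k2 must equal vnd_true for a uniform "
                    "nondisplaceable volume"
                )


@dataclass
class ScanPair:
    """Baseline and post-drug scans for one subject, with the generating truth."""

    truth: GroundTruth
    input_fit: InputFunctionFit
    params_baseline: dict
    params_post: dict
    tacs_baseline: dict
    tacs_post: dict

    def vt_true(self, condition: str) -> dict:
        params = self.params_baseline if condition == "baseline" else self.params_post
        return {r: vt(p) for r, p in params.items()}


def params_for_vt(vt_target: float, k1: float, vnd: float, k4: float = _DEFAULT_K4) -> KineticParams:
    """Construct 2TC parameters hitting a VT target with K1/k2 = vnd."""
    if vt_target < vnd:
        raise ValueError("VT target below the nondisplaceable volume")
    k2 = k1 / vnd
    k3 = k4 * (vt_target / vnd - 1.0)
    return KineticParams(K1=k1, k2=k2, k3=k3, k4=k4 if k3 > 0 else _DEFAULT_K4)


def default_ground_truth(
    affinity_shift: float = 1.27,
    vnd_true: float = 1.0,
    noise_scale: float = 0.0,
    seed: int = 0,
    blood_volume_fraction: float = 0.05,
) -> GroundTruth:
    """Study-conformant truth: ten ROIs at high-dose-arm baseline magnitudes."""
    params = {
        r: params_for_vt(_BASELINE_VT[r], _BASELINE_K1[r], vnd_true) for r in STUDY_ROIS
    }
    return GroundTruth(
        params_baseline=params,
        affinity_shift=affinity_shift,
        vnd_true=vnd_true,
        blood_volume_fraction=blood_volume_fraction,
        noise_scale=noise_scale,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# plasma


def default_input_fit(
    peak_time: float = 1.0,
    amplitudes=(8.0, 3.0, 1.0),
    rates=(2.0, 0.3, 0.03),
) -> InputFunctionFit:
    """Canonical parent input: linear rise over [0, peak], tri-exponential tail.

    Amplitudes in kBq/mL referenced to the peak; rates in 1/min.  The peak
    near 1 min mimics a 30 s bolus injection.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    rates = np.asarray(rates, dtype=float)
    peak_value = float(amplitudes.sum())
    pre_t = np.array([0.0, peak_time])
    pre_v = np.array([0.0, peak_value])
    auc = 0.5 * peak_time * peak_value + float(np.sum(amplitudes / rates))
    return InputFunctionFit(
        peak_time=peak_time,
        pre_times=pre_t,
        pre_values=pre_v,
        amplitudes=amplitudes,
        rates=rates,
        auc=auc,
    )


def default_plasma_sample_times(peak_time: float = 1.0) -> np.ndarray:
    """~35 sample times (min): every 6 s for 2 min, then sparser to 90 min."""
    early = np.arange(0.0, 2.0 + 1e-9, 0.1)  # 21 samples
    late = np.array([2.5, 3.0, 4.0, 5.0, 7.5, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0, 75.0, 90.0])
    return np.concatenate([early, late])


def simulate_plasma(
    peak_time: float = 1.0,
    tail_params=((8.0, 2.0), (3.0, 0.3), (1.0, 0.03)),
    parent_params=(0.55, 0.15, 0.40),
    sample_times=None,
    seed: int = 0,
    noise_sd_frac: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, InputFunctionFit, ParentFractionFit]:
    """Simulate arterial plasma sampling and metabolite measurements.

    The *total* plasma activity rises linearly from 0 to the peak and then
    follows the tri-exponential tail; the unmetabolized parent fraction
    follows a*exp(-b*t) + c sampled at the seven metabolite time points.
    Returns (plasma table, metabolite table, true parent InputFunctionFit,
    true ParentFractionFit).  Convention: the linear-rise/tri-exponential
    curve describes the *parent* concentration and the tabulated totals are
    parent / fraction, so metabolite correction (total x interpolated
    fraction) recovers the parent curve exactly at the sample times.
    """
    amps = np.asarray([a for a, _ in tail_params], dtype=float)
    rates = np.asarray([lam for _, lam in tail_params], dtype=float)
    if np.any(rates <= 0):
        raise ValueError("tail rates must be positive")
    a, b, c = parent_params
    pf_true = ParentFractionFit(a=a, b=b, c_const=c)
    grid = np.linspace(0.0, 90.0, 901)
    raw = a * np.exp(-b * grid) + c
    if np.any((raw < 0) | (raw > 1)):
        raise ValueError("parent fraction leaves [0, 1] on [0, 90] min")
    if sample_times is None:
        sample_times = default_plasma_sample_times(peak_time)
    sample_times = np.asarray(sample_times, dtype=float)

    parent_fit = default_input_fit(peak_time, amps, rates)
    parent = parent_fit(sample_times)
    frac = pf_true(sample_times)
    total = np.where(frac > 0, parent / frac, 0.0)
    rng = np.random.default_rng(seed)
    if noise_sd_frac > 0:
        total = total * (1.0 + noise_sd_frac * rng.standard_normal(total.size))
        total = np.clip(total, 0.0, None)
    plasma = pd.DataFrame({"time_min": sample_times, "total_activity_kbq_ml": total})
    met_t = np.asarray(METABOLITE_SAMPLE_TIMES, dtype=float)
    met = pd.DataFrame({"time_min": met_t, "parent_fraction": pf_true(met_t)})
    return plasma, met, parent_fit, pf_true


# ---------------------------------------------------------------------------
# TACs


def _frame_average(func, schedule: FrameSchedule, n: int = 64) -> np.ndarray:
    """Interval average of a callable over each frame (composite midpoint rule)."""
    out = np.empty(schedule.n_frames)
    for i, (t0, d) in enumerate(zip(schedule.frame_start, schedule.frame_duration)):
        tt = t0 + (np.arange(n) + 0.5) / n * d
        out[i] = float(np.mean(func(tt)))
    return out


def total_plasma_at_frames(
    input_fit: InputFunctionFit,
    schedule: FrameSchedule,
    parent_fraction: ParentFractionFit | None = None,
) -> np.ndarray:
    """Frame-averaged total plasma activity (parent / parent fraction)."""
    if parent_fraction is None:
        return _frame_average(input_fit, schedule)
    return _frame_average(lambda t: input_fit(t) / np.clip(parent_fraction(t), 1e-9, 1.0), schedule)


def simulate_tac(
    truth: KineticParams,
    input_fit: InputFunctionFit,
    schedule: FrameSchedule,
    blood_volume_fraction: float = 0.05,
    noise_scale: float = 0.0,
    seed: int = 0,
    region: str = "ROI",
    parent_fraction: ParentFractionFit | None = None,
) -> TimeActivityCurve:
    """Forward-simulate one regional TAC.

    frame value = frame-averaged 2TC prediction
                  + blood_volume_fraction * frame-averaged total plasma
                  + N(0, (noise_scale * sqrt(prediction / duration))^2).

    Noise variance proportional to prediction / frame duration is the
    Gaussian stand-in for counting statistics that justifies weighting the
    fit by frame duration.  ``noise_scale = 0`` gives the exact model TAC.
    """
    from .kinetics import model_tac  # local import; kinetics does not depend on us

    pred = model_tac(truth, input_fit, schedule)
    blood = blood_volume_fraction * total_plasma_at_frames(input_fit, schedule, parent_fraction)
    values = pred + blood
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        sd = noise_scale * np.sqrt(np.clip(values, 0.0, None) / schedule.frame_duration)
        values = values + sd * rng.standard_normal(values.size)
    return TimeActivityCurve(region=region, schedule=schedule, values=values, blood_corrected=False)


def shifted_params(p: KineticParams, s: float) -> KineticParams:
    """Post-drug parameters: k4 scaled down by the affinity shift s (k3/k4 -> s*k3/k4)."""
    if p.k3 == 0:
        return p
    return KineticParams(K1=p.K1, k2=p.k2, k3=p.k3, k4=p.k4 / s)


def simulate_subject_pair(
    truth: GroundTruth,
    regions=STUDY_ROIS,
    input_fit: InputFunctionFit | None = None,
    schedule: FrameSchedule | None = None,
    parent_fraction: ParentFractionFit | None = None,
) -> ScanPair:
    """Simulate a baseline / post-drug scan pair with a known affinity shift.

    The post-scan parameters scale k3/k4 by s (implemented as a decrease in
    the dissociation rate k4, the affinity interpretation) with K1 and k2
    untouched, so that before noise VT_post = vnd + s*(VT_base - vnd)
    exactly in every region.
    """
    s = truth.affinity_shift
    if s <= 0:
        raise ValueError("affinity shift must be positive")
    params_base = {r: truth.params_baseline[r] for r in regions}
    vts = np.array([vt(p) for p in params_base.values()])
    specific = np.array([p.k3 > 0 for p in params_base.values()])
    # regions with specific binding must sit strictly above vnd; pure
    # nondisplaceable regions (k3 = 0) coincide with it by construction
    if np.any(vts[specific] <= truth.vnd_true) or np.any(vts < truth.vnd_true - 1e-12):
        raise ValueError("vnd_true must be below every baseline VT (Lassen geometry undefined)")
    params_post = {r: shifted_params(p, s) for r, p in params_base.items()}
    if input_fit is None:
        input_fit = default_input_fit()
    if schedule is None:
        schedule = make_frame_schedule()
    # independent per-region, per-condition noise streams derived from the seed
    ss = np.random.SeedSequence(truth.seed)
    seeds = ss.generate_state(2 * len(params_base))
    tacs_base, tacs_post = {}, {}
    for i, r in enumerate(params_base):
        tacs_base[r] = simulate_tac(
            params_base[r], input_fit, schedule, truth.blood_volume_fraction,
            truth.noise_scale, int(seeds[2 * i]), region=r, parent_fraction=parent_fraction,
        )
        tacs_post[r] = simulate_tac(
            params_post[r], input_fit, schedule, truth.blood_volume_fraction,
            truth.noise_scale, int(seeds[2 * i + 1]), region=r, parent_fraction=parent_fraction,
        )
    return ScanPair(
        truth=truth,
        input_fit=input_fit,
        params_baseline=params_base,
        params_post=params_post,
        tacs_baseline=tacs_base,
        tacs_post=tacs_post,
    )


# ---------------------------------------------------------------------------
# EEG


@dataclass
class EpochSet:
    """EEG epochs: trials x channels x samples, with condition labels."""

    data: np.ndarray
    sfreq: float
    tmin: float
    channels: list
    labels: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.labels.shape[0] != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel list length mismatch")

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.sfreq


def _pink_noise(rng, n_samples: int, sd: float) -> np.ndarray:
    """1/f (pink) noise with the requested standard deviation."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n_samples)
    return x * (sd / np.std(x))


def simulate_eeg(
    n_trials_per_condition=None,
    gamma_freq: float = 42.0,
    gamma_amplitude_by_condition=None,
    seed: int = 0,
    n_trials: int = 300,
    channels=("E23", "E24"),
    sfreq: float = 250.0,
    tmin: float = -0.4,
    tmax: float = 1.9,
    noise_sd: float = 10.0,
    burst_window=(0.5, 1.5),
) -> EpochSet:
    """Simulate cued-task EEG epochs with induced gamma bursts.

    Each trial is pink noise plus a Hann-windowed sinusoidal burst at
    ``gamma_freq`` confined to the delay window (default 500-1500 ms
    post-cue) with an independent uniform random phase per trial, so the
    burst is induced (phase-varying) rather than evoked (phase-locked).
    70% of trials are labeled low-control and 30% high-control; the burst
    amplitude depends on the condition (µV; default high = 2 x low).
    """
    if gamma_amplitude_by_condition is None:
        gamma_amplitude_by_condition = {"low": 1.0, "high": 2.0}
    rng = np.random.default_rng(seed)
    if n_trials_per_condition is not None:
        n_low, n_high = n_trials_per_condition
    else:
        n_low = int(round(0.7 * n_trials))
        n_high = n_trials - n_low
    labels = np.array(["low"] * n_low + ["high"] * n_high)
    n_samples = int(round((tmax - tmin) * sfreq)) + 1
    times = tmin + np.arange(n_samples) / sfreq
    w0, w1 = burst_window
    in_burst = (times >= w0) & (times <= w1)
    envelope = np.zeros(n_samples)
    phase_t = (times[in_burst] - w0) / (w1 - w0)
    envelope[in_burst] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase_t))  # Hann
    data = np.empty((labels.size, len(channels), n_samples))
    for i, lab in enumerate(labels):
        amp = gamma_amplitude_by_condition[lab]
        for ch in range(len(channels)):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            burst = amp * envelope * np.cos(2.0 * np.pi * gamma_freq * times + phase)
            data[i, ch] = _pink_noise(rng, n_samples, noise_sd) + burst
    return EpochSet(data=data, sfreq=sfreq, tmin=tmin, channels=list(channels), labels=labels)


# ---------------------------------------------------------------------------
# tidy-table output


def tacs_to_frame(pairs: dict, schedule: FrameSchedule) -> pd.DataFrame:
    """Flatten {subject: ScanPair} into a tidy TAC table."""
    rows = []
    for subject, pair in pairs.items():
        for condition, tacs in (("baseline", pair.tacs_baseline), ("post", pair.tacs_post)):
            for region, tac in tacs.items():
                for t0, d, v in zip(schedule.frame_start, schedule.frame_duration, tac.values):
                    rows.append(
                        {
                            "subject": subject,
                            "condition": condition,
                            "region": region,
                            "frame_start_min": t0,
                            "frame_duration_min": d,
                            "activity": v,
                        }
                    )
    return pd.DataFrame(rows)


def write_epochs(epochs: EpochSet, out_dir) -> None:
    """Write epochs as one CSV matrix per trial plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i in range(epochs.data.shape[0]):
        np.savetxt(out / f"trial_{i:04d}.csv", epochs.data[i], delimiter=",")
    sidecar = {
        "sfreq": epochs.sfreq,
        "tmin": epochs.tmin,
        "channels": epochs.channels,
        "labels": epochs.labels.tolist(),
    }
    (out / "epochs.json").write_text(json.dumps(sidecar, indent=1))


def read_epochs(in_dir) -> EpochSet:
    src = Path(in_dir)
    sidecar = json.loads((src / "epochs.json").read_text())
    trials = sorted(src.glob("trial_*.csv"))
    data = np.stack([np.loadtxt(f, delimiter=",") for f in trials])
    return EpochSet(
        data=data,
        sfreq=sidecar["sfreq"],
        tmin=sidecar["tmin"],
        channels=sidecar["channels"],
        labels=np.asarray(sidecar["labels"]),
    )
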