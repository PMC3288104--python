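"""Induced gamma-band power from cued-task EEG epochs.

Epochs (−400 to +1900 ms around the cue, 250 Hz) are screened with
amplitude-range and sample-to-sample gradient criteria, transformed with
complex Morlet wavelets (parameter ω0 = 7; 20 sub-bands spanning
14–80 Hz), averaged as *induced* power (mean over trials of per-trial
power, so activity need not be phase-locked to the cue), and baseline
corrected by subtracting mean power in the −300 to −100 ms pre-cue
interval.  The frontal summary averages the 42 Hz sub-band over two
frontal electrodes in the 500–1500 ms delay window and contrasts the
high- against the low-cognitive-control condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .synthetic_data import EpochSet

__all__ = [
    "WaveletSpec",
    "TFPower",
    "reject_artifacts",
    "morlet_power",
    "induced_vs_evoked",
    "frontal_gamma_summary",
]


@dataclass(frozen=True)
class WaveletSpec:
    """Morlet transform configuration.

    ``morlet_parameter`` is ω0, the carrier-to-envelope frequency ratio of
    the wavelet mo(x) ∝ exp(−x²/2)·exp(iω0 x).  The kernel amplitude is
    normalized so a unit-amplitude sinusoid yields peak power 1 at every
    analysis frequency.  ``frequencies`` defaults to 20 linearly spaced
    sub-bands spanning 14–80 Hz; ``baseline`` is the pre-cue correction
    window in seconds.
    """

    morlet_parameter: float = 7.0
    frequencies: np.ndarray = field(default_factory=lambda: np.linspace(14.0, 80.0, 20))
    baseline: tuple = (-0.3, -0.1)

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.baseline[0] >= self.baseline[1] or self.baseline[1] > 0:
            raise ValueError("baseline window must precede the cue")

    def sigma_t(self, freq: float) -> float:
        """Temporal SD (s) of the wavelet envelope at an analysis frequency."""
        return self.morlet_parameter / (2.0 * np.pi * freq)


@dataclass
class TFPower:
    """Time-frequency power, condition × channel × frequency × time."""

    power: np.ndarray
    conditions: list
    channels: list
    frequencies: np.ndarray
    times: np.ndarray
    baseline_corrected: bool


def reject_artifacts(epochs: EpochSet, range_limit_uv: float = 200.0, gradient_limit_uv: float = 60.0) -> np.ndarray:
    """Boolean keep-mask over trials.

    A trial is rejected when any channel's within-epoch amplitude range
    exceeds ``range_limit_uv`` or any consecutive-sample step exceeds
    ``gradient_limit_uv`` (both strict: a range of exactly 200 µV or a
    step of exactly 60 µV is kept).
    """
    data = epochs.data
    ranges = data.max(axis=2) - data.min(axis=2)  # trials x channels
    grads = np.abs(np.diff(data, axis=2)).max(axis=2)
    bad = (ranges > range_limit_uv).any(axis=1) | (grads > gradient_limit_uv).any(axis=1)
    return ~bad


def _morlet_kernel(freq: float, sfreq: float, omega0: float) -> np.ndarray:
    """Complex Morlet kernel, amplitude-normalized for unit-sinusoid response.

    Support is ±5 temporal SDs.  The Gaussian envelope is divided by its
    discrete sum and doubled so that convolving with cos(2πft) yields a
    complex signal of magnitude ≈ 1 (power 1) at every frequency.
    """
    sigma = omega0 / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    envelope = np.exp(-0.5 * (t / sigma) ** 2)
    kernel = envelope * np.exp(2j * np.pi * freq * t)
    return 2.0 * kernel / envelope.sum()


def _transform(data: np.ndarray, sfreq: float, spec: WaveletSpec) -> np.ndarray:
    """Complex wavelet coefficients, (..., freq, time), via FFT convolution.

    The per-epoch mean (DC offset) is removed first: the truncated wavelet
    has non-zero partial sums at the epoch edges, so an offset would
    otherwise bleed into edge power.
    """
    data = data - data.mean(axis=-1, keepdims=True)
    n = data.shape[-1]
    lowest = spec.frequencies[0]
    support = 2 * int(np.ceil(5.0 * spec.sigma_t(lowest) * sfreq)) + 1
    if support > n:
        raise ValueError(
            f"epoch ({n} samples) shorter than wavelet support ({support} samples) "
            f"at {lowest:g} Hz"
        )
    out = np.empty(data.shape[:-1] + (spec.frequencies.size, n), dtype=complex)
    for i, f in enumerate(spec.frequencies):
        k = _morlet_kernel(f, sfreq, spec.morlet_parameter)
        out[..., i, :] = fftconvolve(data, k[(np.newaxis,) * (data.ndim - 1) + (slice(None),)], mode="same", axes=-1)
    return out


def _baseline_indices(times: np.ndarray, window: tuple) -> np.ndarray:
    idx = (times >= window[0]) & (times <= window[1])
    if not idx.any():
        raise ValueError("baseline window outside the epoch")
    return idx


def morlet_power(epochs: EpochSet, spec: WaveletSpec | None = None, baseline_correct: bool = True, mode: str = "subtract") -> TFPower:
    """Trial-averaged induced time-frequency power per condition and channel.

    Per-trial power |W|² is averaged over trials within each condition
    (induced power); baseline correction subtracts (or, with
    ``mode='ratio'``, divides by) the mean power in the pre-cue baseline
    window per channel and frequency.
    """
    spec = spec or WaveletSpec()
    conditions = sorted(set(epochs.labels.tolist()))
    times = epochs.times
    power = np.empty((len(conditions), len(epochs.channels), spec.frequencies.size, times.size))
    for ci, cond in enumerate(conditions):
        sel = epochs.data[epochs.labels == cond]
        w = _transform(sel, epochs.sfreq, spec)
        power[ci] = np.mean(np.abs(w) ** 2, axis=0)
    if baseline_correct:
        bl = _baseline_indices(times, spec.baseline)
        base = power[..., bl].mean(axis=-1, keepdims=True)
        if mode == "subtract":
            power = power - base
        elif mode == "ratio":
            power = power / base
        else:
            raise ValueError(f"unknown baseline mode {mode!r}")
    return TFPower(
        power=power,
        conditions=conditions,
        channels=list(epochs.channels),
        frequencies=spec.frequencies,
        times=times,
        baseline_corrected=baseline_correct,
    )


def induced_vs_evoked(epochs: EpochSet, spec: WaveletSpec | None = None) -> tuple[TFPower, TFPower]:
    """Induced (trial-mean of per-trial power) vs evoked (power of the mean signal).

    Phase-locked activity survives trial averaging and appears in both;
    activity with random per-trial phase cancels in the average and
    appears only in the induced estimate.  Both are baseline corrected by
    subtraction.
    """
    spec = spec or WaveletSpec()
    if epochs.data.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    induced = morlet_power(epochs, spec)
    conditions = induced.conditions
    times = epochs.times
    power = np.empty_like(induced.power)
    for ci, cond in enumerate(conditions):
        mean_sig = epochs.data[epochs.labels == cond].mean(axis=0)
        w = _transform(mean_sig, epochs.sfreq, spec)
        power[ci] = np.abs(w) ** 2
    bl = _baseline_indices(times, spec.baseline)
    power = power - power[..., bl].mean(axis=-1, keepdims=True)
    evoked = TFPower(
        power=power,
        conditions=conditions,
        channels=list(epochs.channels),
        frequencies=spec.frequencies,
        times=times,
        baseline_corrected=True,
    )
    return induced, evoked


def frontal_gamma_summary(
    tf: TFPower,
    electrodes=("E23", "E24"),
    band_center: float = 42.0,
    window: tuple = (0.5, 1.5),
) -> dict:
    """Delay-period frontal gamma summary and high−low contrast.

    Averages baseline-corrected power over the two frontal electrodes, the
    sub-band nearest ``band_center`` and the delay window.  Returns
    ``{condition: value, ..., 'contrast': high − low,
    'band_frequency': f}``; if ``band_center`` is not an exact sub-band
    center the nearest one is used with a warning.
    """
    missing = [e for e in electrodes if e not in tf.channels]
    if missing:
        raise ValueError(f"electrodes not present: {missing}")
    fi = int(np.argmin(np.abs(tf.frequencies - band_center)))
    if abs(tf.frequencies[fi] - band_center) > 1e-9:
        warnings.warn(
            f"band center {band_center:g} Hz not a sub-band center; "
            f"using nearest sub-band {tf.frequencies[fi]:.2f} Hz",
            stacklevel=2,
        )
    ti = (tf.times >= window[0]) & (tf.times <= window[1])
    ei = [tf.channels.index(e) for e in electrodes]
    out = {"band_frequency": float(tf.frequencies[fi])}
    for ci, cond in enumerate(tf.conditions):
        out[cond] = float(tf.power[ci][ei][:, fi, :][:, ti].mean())
    if "high" in out and "low" in out:
        out["contrast"] = out["high"] - out["low"]
    return out
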