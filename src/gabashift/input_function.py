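"""Arterial input function: metabolite correction, curve fitting, clearance, free fraction.

The metabolite-corrected input function is the plasma concentration of
unchanged radiotracer over time.  It is assembled from (i) total-activity
counts of arterial samples, (ii) the unmetabolized parent fraction measured
at a sparse set of times and interpolated with an exponential-plus-constant
fit, and (iii) a tri-exponential fit to the parent curve from the time of
peak plasma activity onward.  The fitted input drives the kinetic model;
its area under the curve gives tracer clearance, and an ultrafiltration
assay gives the plasma free fraction fP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ParentFractionFit",
    "InputFunctionFit",
    "FreeFractionAssay",
    "FitError",
    "fit_parent_fraction",
    "compute_input",
    "fit_input_function",
    "clearance",
    "free_fraction",
]

# standard metabolite sampling times (min) for the study protocol
METABOLITE_SAMPLE_TIMES = (2.0, 5.0, 15.0, 30.0, 45.0, 75.0, 90.0)


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best residual seen."""

    def __init__(self, message: str, best_residual: float = np.inf):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass(frozen=True)
class ParentFractionFit:
    """Unmetabolized parent fraction model f(t) = a*exp(-b*t) + c_const."""

    a: float
    b: float
    c_const: float
    residual_norm: float = 0.0

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        frac = self.a * np.exp(-self.b * t) + self.c_const
        return np.clip(frac, 0.0, 1.0)


@dataclass(frozen=True)
class InputFunctionFit:
    """Metabolite-corrected plasma parent curve.

    Before the peak the measured samples are linearly interpolated; at and
    after the peak the curve follows a sum of three exponentials
    sum_i A_i * exp(-lambda_i * (t - peak_time)).

    Attributes
    ----------
    peak_time : float
        Time of peak plasma parent activity (min).
    pre_times, pre_values : ndarray
        Measured samples up to and including the peak, used for
        interpolation on [0, peak_time].
    amplitudes : ndarray, shape (3,)
        Tail amplitudes A_i (activity / mL), referenced to t = peak_time.
    rates : ndarray, shape (3,)
        Tail rates lambda_i (1/min), all > 0.
    auc : float
        Area under the full curve: pre-peak trapezoid + analytic tail
        integral sum(A_i / lambda_i).
    """

    peak_time: float
    pre_times: np.ndarray
    pre_values: np.ndarray
    amplitudes: np.ndarray
    rates: np.ndarray
    auc: float
    residual_norm: float = 0.0

    def tail(self, t):
        """Tri-exponential tail evaluated at absolute time t >= peak_time."""
        dt = np.asarray(t, dtype=float) - self.peak_time
        return np.exp(-np.outer(dt, self.rates)) @ self.amplitudes

    def __call__(self, t):
        """Evaluate the parent input at time t (min); 0 before first sample."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        out = np.empty_like(t)
        pre = t < self.peak_time
        out[pre] = np.interp(t[pre], self.pre_times, self.pre_values, left=0.0)
        out[~pre] = self.tail(t[~pre])
        return float(out[0]) if scalar else out


@dataclass(frozen=True)
class FreeFractionAssay:
    """Ultrafiltration triplicates for the plasma free fraction measurement.

    Each column pairs total activity with ultrafiltrate activity for one
    aliquot; the saline triplicate measures filter retention of free tracer.
    """

    plasma_total: np.ndarray
    plasma_ultrafiltrate: np.ndarray
    saline_total: np.ndarray
    saline_ultrafiltrate: np.ndarray

    def __post_init__(self):
        for name in ("plasma_total", "plasma_ultrafiltrate", "saline_total", "saline_ultrafiltrate"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.plasma_total <= 0) or np.any(self.saline_total <= 0):
            raise ValueError("all counts must be positive")
        if np.any(self.plasma_ultrafiltrate > self.plasma_total) or np.any(
            self.saline_ultrafiltrate > self.saline_total
        ):
            raise ValueError("ultrafiltrate activity cannot exceed total activity")


def _separable_exp_fit(t, y, rate_seeds, n_terms, constant_term):
    """Fit y ~ sum_i A_i exp(-r_i t) (+ c) with rates nonlinear, amplitudes linear.

    Variable-projection scheme: for trial log-rates the amplitudes (and the
    optional constant) are solved by linear least squares, so the nonlinear
    search runs only over the rates.  Multi-start over `rate_seeds`; best
    residual wins, ties broken by the smallest rate-vector norm.
    Returns (amplitudes, rates, constant, residual_norm).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)

    def design(rates):
        cols = [np.exp(-r * t) for r in rates]
        if constant_term:
            cols.append(np.ones_like(t))
        return np.column_stack(cols)

    def solve_linear(rates):
        X = design(rates)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return coef, X @ coef - y

    def resid(log_rates):
        _, r = solve_linear(np.exp(log_rates))
        return r

    best = None
    for seed in rate_seeds:
        try:
            sol = least_squares(
                resid, np.log(np.asarray(seed, dtype=float)), method="lm",
                xtol=1e-14, ftol=1e-14, max_nfev=2000,
            )
        except Exception:
            continue
        rates = np.exp(sol.x)
        coef, r = solve_linear(rates)
        norm = float(np.linalg.norm(r))
        key = (norm, float(np.linalg.norm(rates)))
        if best is None or key < best[0]:
            best = (key, coef, rates)
    if best is None:
        raise FitError("all multi-start exponential fits failed")
    key, coef, rates = best
    if constant_term:
        return coef[:-1], rates, float(coef[-1]), key[0]
    return coef, rates, 0.0, key[0]


def fit_parent_fraction(times, fractions) -> ParentFractionFit:
    """Fit measured parent fractions to f(t) = a*exp(-b*t) + c_const.

    Parameters are found by multi-start separable least squares (the decay
    rate b is the only nonlinear parameter).  Predictions are clamped to
    [0, 1] at evaluation time.
    """
    times = np.asarray(times, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if times.size < 4:
        raise ValueError("need at least 4 parent-fraction measurements")
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("parent fractions must lie in [0, 1]")
    amps, rates, const, norm = _separable_exp_fit(
        times, fractions, rate_seeds=[[0.01], [0.05], [0.2], [1.0]], n_terms=1,
        constant_term=True,
    )
    return ParentFractionFit(a=float(amps[0]), b=float(rates[0]), c_const=const, residual_norm=norm)


def compute_input(times, total_activity, pf: ParentFractionFit):
    """Metabolite-correct total plasma counts: parent = total x parent fraction."""
    times = np.asarray(times, dtype=float)
    total = np.asarray(total_activity, dtype=float)
    return total * pf(times)


def fit_input_function(times, parent_activity) -> InputFunctionFit:
    """Fit the metabolite-corrected input to a tri-exponential tail from the peak.

    The peak is located as the sample-time maximum (earliest sample wins a
    tie).  Samples before the peak are kept for linear interpolation; the
    post-peak samples are fitted to sum_i A_i exp(-lambda_i (t - peak)) with
    positivity enforced on the rates (amplitudes are left free).  The AUC is
    the pre-peak trapezoid plus the closed-form tail integral.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(parent_activity, dtype=float)
    order = np.argsort(times, kind="stable")
    times, y = times[order], y[order]
    ipeak = int(np.argmax(y))  # argmax returns the earliest maximum
    t_peak = times[ipeak]
    tail_t = times[ipeak:] - t_peak
    tail_y = y[ipeak:]
    if tail_t.size < 8:
        raise ValueError("need at least 8 samples from the peak onward")
    seeds = [[2.0, 0.3, 0.03], [1.0, 0.1, 0.01], [5.0, 0.5, 0.05]]
    amps, rates, _, norm = _separable_exp_fit(
        tail_t, tail_y, rate_seeds=seeds, n_terms=3, constant_term=False
    )
    if np.any(rates <= 0):
        raise FitError("fitted tail rate is non-positive", norm)
    pre_times = times[: ipeak + 1]
    pre_values = y[: ipeak + 1]
    pre_auc = float(np.trapezoid(pre_values, pre_times)) if pre_times.size > 1 else 0.0
    tail_auc = float(np.sum(amps / rates))
    return InputFunctionFit(
        peak_time=float(t_peak),
        pre_times=pre_times,
        pre_values=pre_values,
        amplitudes=np.asarray(amps, dtype=float),
        rates=np.asarray(rates, dtype=float),
        auc=pre_auc + tail_auc,
        residual_norm=norm,
    )


def clearance(injected_dose: float, fit: InputFunctionFit) -> float:
    """Tracer clearance = injected dose / AUC of the input function.

    Units follow the inputs (e.g. kBq dose with kBq min/mL AUC gives
    mL/min); conversion to L/h is a reporting concern (see
    :func:`clearance_l_per_h`).
    """
    if fit.auc <= 0:
        raise ValueError("input-function AUC must be positive")
    return injected_dose / fit.auc


def clearance_l_per_h(injected_dose_kbq: float, fit: InputFunctionFit) -> float:
    """Clearance in L/h from a dose in kBq and an input fit in kBq min/mL."""
    return clearance(injected_dose_kbq, fit) * 60.0 / 1000.0


def free_fraction(assay: FreeFractionAssay) -> dict:
    """Plasma free fraction fP from ultrafiltration triplicates.

    The raw value is the mean plasma ultrafiltrate/total ratio.  The
    corrected value divides by the mean saline ratio to account for filter
    retention of free tracer, and is clamped to [0, 1].  Returns a dict with
    keys ``fp`` (corrected), ``fp_raw`` and ``saline_ratio``.
    """
    plasma_ratio = float(np.mean(assay.plasma_ultrafiltrate / assay.plasma_total))
    saline_ratio = float(np.mean(assay.saline_ultrafiltrate / assay.saline_total))
    if saline_ratio == 0:
        raise ValueError("saline ultrafiltrate ratio is zero; retention correction undefined")
    fp = min(max(plasma_ratio / saline_ratio, 0.0), 1.0)
    return {"fp": fp, "fp_raw": plasma_ratio, "saline_ratio": saline_ratio}
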