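"""Two-tissue-compartment (2TC) kinetic modeling of regional PET data.

The reversible 2TC model describes tracer exchange between arterial plasma
and two tissue compartments (nondisplaceable and specifically bound) with
rate constants K1 (mL g-1 min-1, delivery), k2 (min-1, efflux), k3 (min-1,
binding) and k4 (min-1, dissociation).  The tissue impulse response is a
sum of two exponentials with eigenvalues

    alpha_{1,2} = ((k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4 k2 k4)) / 2,

and the tissue curve is its convolution with the metabolite-corrected
plasma input.  The total distribution volume is VT = K1/k2 (1 + k3/k4);
binding potentials follow as BP_P = VT - VND and BP_ND = VT/VND - 1, with
VND the nondisplaceable distribution volume (pons VT in this study design).

The convolution is evaluated in closed form: exponential x exponential on
the fitted tri-exponential tail of the input, exponential x linear-segment
on the interpolated pre-peak samples.  Frame values are interval averages
(integral over the frame divided by its duration), matching how emission
counts are acquired, and fits are weighted by frame duration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .input_function import InputFunctionFit
from .schedule import FrameSchedule

__all__ = [
    "KineticParams",
    "TimeActivityCurve",
    "FitResult",
    "OutcomeMeasures",
    "blood_correct",
    "model_tac",
    "fit_2tc",
    "vt",
    "outcomes",
]

# Gauss-Legendre nodes/weights on [0, 1] used for frame averaging
_GL_X, _GL_W = np.polynomial.legendre.leggauss(8)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


@dataclass(frozen=True)
class KineticParams:
    """2TC rate constants; K1 in mL g-1 min-1, k2..k4 in min-1."""

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0

    def __post_init__(self):
        if self.K1 <= 0 or self.k2 <= 0:
            raise ValueError("K1 and k2 must be positive")
        if self.k3 < 0 or self.k4 < 0:
            raise ValueError("k3 and k4 must be non-negative")
        if self.k3 > 0 and self.k4 == 0:
            raise ValueError("k3 > 0 requires k4 > 0 (irreversible binding unsupported)")

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.k3, self.k4], dtype=float)


@dataclass
class TimeActivityCurve:
    """Per-frame regional activity concentration on a frame schedule."""

    region: str
    schedule: FrameSchedule
    values: np.ndarray
    blood_corrected: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.schedule.n_frames,):
            raise ValueError("one activity value per frame required")


@dataclass(frozen=True)
class FitResult:
    params: KineticParams
    vt: float
    weighted_residual_norm: float
    converged: bool
    covariance: np.ndarray | None = None


@dataclass(frozen=True)
class OutcomeMeasures:
    vt: float
    vnd: float
    bp_p: float
    bp_nd: float
    fp: float | None = None


def vt(params: KineticParams) -> float:
    """Total distribution volume VT = K1/k2 (1 + k3/k4); K1/k2 when k3 = 0."""
    if params.k3 == 0:
        return params.K1 / params.k2
    if params.k4 == 0:
        raise ValueError("VT undefined for k3 > 0 with k4 = 0")
    return params.K1 / params.k2 * (1.0 + params.k3 / params.k4)


def outcomes(vt_roi: float, vt_pons: float, fp: float | None = None) -> OutcomeMeasures:
    """Binding potentials from a regional VT and the pons VT (VND)."""
    if vt_pons <= 0:
        raise ValueError("VND (pons VT) must be positive")
    return OutcomeMeasures(
        vt=vt_roi,
        vnd=vt_pons,
        bp_p=vt_roi - vt_pons,
        bp_nd=vt_roi / vt_pons - 1.0,
        fp=fp,
    )


def blood_correct(tac: TimeActivityCurve, total_plasma_at_frames, blood_volume_fraction: float = 0.05) -> TimeActivityCurve:
    """Remove the intravascular contribution from a regional TAC.

    tissue = total regional activity - fraction x total plasma activity,
    frame by frame, assuming the given blood volume fraction (default 5%).
    """
    if tac.blood_corrected:
        raise ValueError("TAC is already blood-corrected")
    plasma = np.asarray(total_plasma_at_frames, dtype=float)
    if plasma.shape != tac.values.shape:
        raise ValueError("plasma and TAC frame counts differ")
    return TimeActivityCurve(
        region=tac.region,
        schedule=tac.schedule,
        values=tac.values - blood_volume_fraction * plasma,
        blood_corrected=True,
    )


# ---------------------------------------------------------------------------
# forward model


class _ModelContext:
    """Precomputed quadrature grid and input-segment data for one (input, schedule)."""

    def __init__(self, input_fit: InputFunctionFit, schedule: FrameSchedule):
        self.input_fit = input_fit
        self.schedule = schedule
        # quadrature nodes: 8-point Gauss-Legendre within each frame
        starts = schedule.frame_start[:, None]
        durs = schedule.frame_duration[:, None]
        self.nodes = (starts + durs * _GL_X[None, :]).ravel()
        self.n_frames = schedule.n_frames
        # pre-peak piecewise-linear segments (t0, t1, c0, c1): value = c0 + c1*t
        pts_t = np.asarray(input_fit.pre_times, dtype=float)
        pts_v = np.asarray(input_fit.pre_values, dtype=float)
        if pts_t.size == 0 or pts_t[0] > 0:
            pts_t = np.concatenate([[min(0.0, pts_t[0] if pts_t.size else 0.0)], pts_t])
            pts_v = np.concatenate([[pts_v[0] if pts_v.size else 0.0], pts_v])
        t0, t1 = pts_t[:-1], pts_t[1:]
        keep = t1 > t0
        t0, t1 = t0[keep], t1[keep]
        v0, v1 = pts_v[:-1][keep], pts_v[1:][keep]
        c1 = (v1 - v0) / (t1 - t0)
        c0 = v0 - c1 * t0
        self.seg = (t0, t1, c0, c1)
        self.t_peak = float(input_fit.peak_time)
        self.amps = np.asarray(input_fit.amplitudes, dtype=float)
        self.lams = np.asarray(input_fit.rates, dtype=float)

    def conv_exp(self, alpha: float) -> np.ndarray:
        """f(alpha, t) = int_0^t exp(-alpha (t - tau)) Cp(tau) dtau at the nodes."""
        t = self.nodes
        out = np.zeros_like(t)
        t0, t1, c0, c1 = self.seg
        # pre-peak linear segments, closed form
        for a, b, p0, p1 in zip(t0, t1, c0, c1):
            m = t > a
            if not np.any(m):
                continue
            tm = t[m]
            u = np.minimum(tm, b)
            if abs(alpha) > 1e-12:
                # G(tau) = e^{alpha tau} ((p0 + p1 tau)/alpha - p1/alpha^2)
                def G(tau):
                    return np.exp(alpha * (tau - tm)) * ((p0 + p1 * tau) / alpha - p1 / alpha**2)

                out[m] += G(u) - G(a)
            else:
                out[m] += (p0 * u + 0.5 * p1 * u**2) - (p0 * a + 0.5 * p1 * a**2)
        # tri-exponential tail, closed form
        post = t >= self.t_peak
        if np.any(post):
            dt = t[post] - self.t_peak
            acc = np.zeros_like(dt)
            for A, lam in zip(self.amps, self.lams):
                if abs(alpha - lam) > 1e-9 * max(abs(alpha), abs(lam), 1e-12):
                    acc += A * (np.exp(-lam * dt) - np.exp(-alpha * dt)) / (alpha - lam)
                else:
                    acc += A * dt * np.exp(-alpha * dt)
            out[post] += acc
        return out

    def predict_frames(self, K1: float, k2: float, k3: float, k4: float) -> np.ndarray:
        """Frame-averaged 2TC prediction for the given rate constants."""
        s = k2 + k3 + k4
        disc = s * s - 4.0 * k2 * k4
        disc = max(disc, 0.0)
        root = np.sqrt(disc)
        a1 = 0.5 * (s - root)
        a2 = 0.5 * (s + root)
        if root > 1e-8 * max(a2, 1e-12):
            b1 = K1 * (k3 + k4 - a1) / (a2 - a1)
            b2 = K1 * (a2 - k3 - k4) / (a2 - a1)
            c_nodes = b1 * self.conv_exp(a1) + b2 * self.conv_exp(a2)
        else:
            # repeated-eigenvalue analytic limit:
            # C = K1 [ f(alpha) - (k3 + k4 - alpha) f'(alpha) ], f' by central difference
            a = 0.5 * (a1 + a2)
            d = max(1e-6 * max(a, 1.0), 1e-9)
            fprime = (self.conv_exp(a + d) - self.conv_exp(a - d)) / (2.0 * d)
            c_nodes = K1 * (self.conv_exp(a) - (k3 + k4 - a) * fprime)
        return c_nodes.reshape(self.n_frames, len(_GL_W)) @ _GL_W


def model_tac(params: KineticParams, input_fit: InputFunctionFit, schedule: FrameSchedule) -> np.ndarray:
    """Frame-averaged tissue activity predicted by the 2TC model.

    The tissue impulse response is convolved with the input function in
    closed form and averaged over each frame interval.  The repeated-
    eigenvalue case (discriminant = 0) is handled by the analytic limit.
    """
    ctx = _ModelContext(input_fit, schedule)
    return ctx.predict_frames(params.K1, params.k2, params.k3, params.k4)


# ---------------------------------------------------------------------------
# fitting

# multi-start seeds: K1 in {0.2, 0.5} crossed with uniform k-patterns {0.05, 0.2}
_START_PATTERNS = [
    (0.2, 0.05, 0.05, 0.05),
    (0.2, 0.2, 0.2, 0.2),
    (0.5, 0.05, 0.05, 0.05),
    (0.5, 0.2, 0.2, 0.2),
]
_LOWER = np.array([1e-6, 1e-6, 1e-6, 1e-6])
_UPPER = np.array([2.0, 1.0, 1.0, 1.0])


def fit_2tc(
    tac: TimeActivityCurve,
    input_fit: InputFunctionFit,
    init: KineticParams | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> FitResult:
    """Frame-duration-weighted nonlinear least-squares fit of the 2TC model.

    Minimizes sum_i duration_i (obs_i - pred_i)^2 by Levenberg-Marquardt.
    Multi-start over four initializations within wide positivity bounds
    (numerical safety only), then an unconstrained LM refit from the best
    bounded solution gives the final answer.  VT is recomputed from the
    fitted parameters.
    """
    if not tac.blood_corrected:
        raise ValueError("fit_2tc requires a blood-corrected TAC")
    if tac.schedule.n_frames < 8:
        raise ValueError("need at least 8 frames")
    ctx = _ModelContext(input_fit, tac.schedule)
    obs = tac.values
    sqw = np.sqrt(tac.schedule.frame_duration)

    def resid(p):
        K1, k2, k3, k4 = p
        if K1 <= 0 or k2 <= 0 or k3 < 0 or k4 < 0:
            return np.full_like(obs, 1e6)
        return sqw * (ctx.predict_frames(K1, k2, k3, k4) - obs)

    lo, hi = bounds if bounds is not None else (_LOWER, _UPPER)
    starts = [init.as_array()] if init is not None else [np.array(p) for p in _START_PATTERNS]
    best = None
    n_ok = 0
    for x0 in starts:
        try:
            sol = least_squares(
                resid, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400,
            )
        except Exception:
            continue
        n_ok += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or n_ok == 0:
        raise RuntimeError("2TC fit failed to converge from any initialization")
    # final unconstrained refit (the model itself is fitted without constraints;
    # the bounds above only steer the multi-start search)
    final = best
    try:
        refit = least_squares(resid, best.x, method="lm", xtol=1e-12, ftol=1e-12, max_nfev=400)
        if refit.cost <= best.cost and np.all(refit.x[:2] > 0) and np.all(refit.x[2:] >= 0):
            final = refit
    except Exception:
        pass
    K1, k2, k3, k4 = final.x
    params = KineticParams(K1=K1, k2=k2, k3=max(k3, 0.0), k4=max(k4, 0.0))
    cov = None
    try:
        J = final.jac
        JTJ = J.T @ J
        dof = max(obs.size - 4, 1)
        cov = np.linalg.inv(JTJ) * 2.0 * final.cost / dof
    except np.linalg.LinAlgError:
        pass
    return FitResult(
        params=params,
        vt=vt(params),
        weighted_residual_norm=float(np.sqrt(2.0 * final.cost)),
        converged=bool(final.success),
        covariance=cov,
    )
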