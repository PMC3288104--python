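"""Lassen-plot (graphical occupancy) analysis of paired distribution volumes.

When only VT — not BP — can be measured, the fractional change in binding
potential between two conditions is the slope of the ordinary least-squares
regression of (VT_baseline − VT_post) on VT_baseline across regions; the
x-intercept estimates the nondisplaceable volume VND.  Under the assumption
that an increase in extracellular GABA shifts the benzodiazepine-site
affinity by the same factor in every region, the affinity shift is
1 − slope: a slope of −0.27 corresponds to a 27% affinity increase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LassenFit",
    "LASSEN_ROIS",
    "lassen_fit",
    "affinity_shift_from_slope",
    "group_shift_summary",
]

# the ten component ROIs entering the study-conformant regression
LASSEN_ROIS = ("DLPFC", "OFC", "MPFC", "ACC", "PC", "OC", "AMY", "HIP", "ENT", "PHG")


@dataclass(frozen=True)
class LassenFit:
    """Per-subject regression summary.

    slope = ΔBP (fractional binding change); x_intercept = VND estimate;
    affinity_shift = 1 − slope.  ``x_intercept`` is NaN with
    ``x_intercept_defined`` False when the slope is (numerically) zero.
    """

    slope: float
    intercept: float
    x_intercept: float
    delta_bp: float
    affinity_shift: float
    r_squared: float
    n_regions: int
    x_intercept_defined: bool = True


def affinity_shift_from_slope(slope: float) -> float:
    """Affinity shift = 1 − ΔBP, with ΔBP the Lassen-plot slope."""
    return 1.0 - slope


def lassen_fit(vt_baseline, vt_post, method: str = "ols") -> LassenFit:
    """Regress (VT_baseline − VT_post) on VT_baseline across regions.

    ``method='ols'`` (default) is ordinary least squares, matching the
    study analysis.  ``method='odr'`` offers orthogonal-distance regression
    for users who want both axes' measurement error acknowledged; it is not
    the study method.
    """
    x = np.asarray(vt_baseline, dtype=float)
    y = x - np.asarray(vt_post, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("baseline and post VT lists must be paired 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 regions")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in baseline VT; regression undefined")
    if method == "ols":
        res = stats.linregress(x, y)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    elif method == "odr":
        from scipy import odr

        data = odr.Data(x, y)
        out = odr.ODR(data, odr.unilinear, beta0=[0.0, 0.0]).run()
        slope, intercept = float(out.beta[0]), float(out.beta[1])
        ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    else:
        raise ValueError(f"unknown method {method!r}")
    defined = abs(slope) > 1e-12
    x_int = -intercept / slope if defined else np.nan
    return LassenFit(
        slope=slope,
        intercept=intercept,
        x_intercept=x_int,
        delta_bp=slope,
        affinity_shift=affinity_shift_from_slope(slope),
        r_squared=r2,
        n_regions=int(x.size),
        x_intercept_defined=defined,
    )


def group_shift_summary(fits) -> dict:
    """Unweighted mean ± SD of slope, x-intercept and affinity shift across subjects.

    With a single subject the SD is reported as NaN (sample SD undefined).
    Undefined x-intercepts (slope = 0) are excluded from the x-intercept
    summary and counted in ``n_x_intercept``.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to summarize")

    def mean_sd(vals):
        vals = np.asarray(vals, dtype=float)
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
        return float(np.mean(vals)), sd

    slopes = [f.slope for f in fits]
    shifts = [f.affinity_shift for f in fits]
    xints = [f.x_intercept for f in fits if f.x_intercept_defined]
    out = {
        "n_subjects": len(fits),
        "slope_mean": mean_sd(slopes)[0],
        "slope_sd": mean_sd(slopes)[1],
        "shift_mean": mean_sd(shifts)[0],
        "shift_sd": mean_sd(shifts)[1],
        "n_x_intercept": len(xints),
    }
    if xints:
        out["x_intercept_mean"], out["x_intercept_sd"] = mean_sd(xints)
    else:
        out["x_intercept_mean"] = out["x_intercept_sd"] = np.nan
    return out
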