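"""Single-agent dose-response fitting and IC50 estimation.

Viability (% of vehicle-treated control) as a function of drug
concentration is modelled with the four-parameter logistic (4PL)

    v(d) = bottom + (top - bottom) / (1 + (d / ec50) ** hill)

fitted by bounded least squares with a multi-start over hill slopes.
Two potency summaries are reported: the relative EC50 (the curve
midpoint) and the absolute IC50, the concentration at which the fitted
curve crosses 50% of control viability.  Viability relative to control
makes the absolute IC50 the primary summary; if the curve floor sits
above 50% the IC50 is flagged as not reached.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

from .errors import InputError

__all__ = ["DoseResponseCurve", "four_pl", "fit_4pl", "ic50"]

#: hill-slope starting points for the multi-start fit
HILL_STARTS = (0.5, 1.0, 2.0, 4.0)


def four_pl(d, top: float, bottom: float, hill: float, ec50: float):
    """Evaluate the descending four-parameter logistic at dose(s) ``d``."""
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore"):
        out = bottom + (top - bottom) / (1.0 + (d / ec50) ** hill)
    return out if out.ndim else float(out)


@dataclass
class DoseResponseCurve:
    """A fitted single-agent curve.

    ``ic50`` is the absolute IC50 (crossing of 50% control viability),
    NaN when flagged ``ic50_not_reached``; ``ec50`` is the fitted curve
    midpoint (relative EC50).
    """

    doses: np.ndarray
    viability: np.ndarray
    top: float
    bottom: float
    hill: float
    ec50: float
    sse: float
    converged: bool
    fitted: bool = True
    ic50_value: float = float("nan")
    ic50_not_reached: bool = False
    ic50_interpolated: float = float("nan")

    def predict(self, d):
        return four_pl(d, self.top, self.bottom, self.hill, self.ec50)

    def to_json(self) -> str:
        payload = {
            "top": float(self.top),
            "bottom": float(self.bottom),
            "hill": float(self.hill),
            "ec50": float(self.ec50),
            "ic50": None if self.ic50_not_reached else float(self.ic50_value),
            "ic50_not_reached": bool(self.ic50_not_reached),
            "ic50_interpolated": None
            if np.isnan(self.ic50_interpolated)
            else float(self.ic50_interpolated),
            "sse": float(self.sse),
            "converged": bool(self.converged),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _interp_ic50(doses: np.ndarray, viability: np.ndarray) -> float:
    """Monotone-spline (PCHIP) crossing of 50% viability on log-dose;
    NaN when the observed curve never crosses 50."""
    order = np.argsort(doses)
    d, v = doses[order], viability[order]
    if v.min() > 50.0 or v.max() < 50.0:
        return float("nan")
    spline = PchipInterpolator(np.log10(d), v)
    grid = np.logspace(np.log10(d[0]), np.log10(d[-1]), 512)
    vv = spline(np.log10(grid))
    idx = np.nonzero(np.diff(np.sign(vv - 50.0)))[0]
    if len(idx) == 0:
        return float("nan")
    i = idx[0]
    # linear interpolation in log-dose between bracketing grid points
    x0, x1 = np.log10(grid[i]), np.log10(grid[i + 1])
    y0, y1 = vv[i], vv[i + 1]
    return float(10 ** (x0 + (50.0 - y0) * (x1 - x0) / (y1 - y0)))


def fit_4pl(doses, viability) -> DoseResponseCurve:
    """Fit the 4PL by bounded least squares with multi-start.

    Requires >= 4 distinct positive doses.  ``top`` is bounded in
    [80, 120] (viability is relative to control), ``bottom`` in
    [0, 100], ``ec50`` within [min dose / 10, max dose * 10].  The best
    of the hill-slope starts (0.5, 1, 2, 4) by SSE is kept.  If no start
    converges the curve is flagged and the IC50 falls back to monotone
    interpolation of the raw data.
    """
    doses = np.asarray(doses, dtype=float).ravel()
    viability = np.asarray(viability, dtype=float).ravel()
    if doses.shape != viability.shape:
        raise InputError("doses and viability must have equal length")
    if len(np.unique(doses)) < 4:
        raise InputError("need at least 4 distinct doses")
    if np.any(doses <= 0):
        raise InputError("doses must be positive (dose 0 is the control, not a point)")
    if not np.all(np.isfinite(viability)):
        raise InputError("viability must be finite")

    d_lo, d_hi = doses.min() / 10.0, doses.max() * 10.0
    lower = np.array([80.0, 0.0, 0.05, d_lo])
    upper = np.array([120.0, 100.0, 20.0, d_hi])

    def residuals(theta):
        top, bottom, hill, ec50 = theta
        return four_pl(doses, top, bottom, hill, ec50) - viability

    best = None
    v_hi = float(np.clip(viability.max(), 80.0, 120.0))
    v_lo = float(np.clip(viability.min(), 0.0, 100.0))
    ec50_0 = float(np.clip(np.exp(np.mean(np.log(doses))), d_lo, d_hi))
    for hill0 in HILL_STARTS:
        x0 = np.array([v_hi, v_lo, hill0, ec50_0])
        try:
            res = least_squares(residuals, x0, bounds=(lower, upper), method="trf")
        except Exception:
            continue
        if not res.success:
            continue
        sse = float(res.fun @ res.fun)
        if best is None or sse < best[0]:
            best = (sse, res.x)

    if best is None:
        curve = DoseResponseCurve(
            doses=doses,
            viability=viability,
            top=float("nan"),
            bottom=float("nan"),
            hill=float("nan"),
            ec50=float("nan"),
            sse=float("nan"),
            converged=False,
            fitted=False,
        )
        curve.ic50_interpolated = _interp_ic50(doses, viability)
        curve.ic50_value = curve.ic50_interpolated
        curve.ic50_not_reached = bool(np.isnan(curve.ic50_value))
        return curve

    sse, (top, bottom, hill, ec50) = best
    if top <= bottom:  # degenerate flat fit (e.g. constant viability)
        curve = DoseResponseCurve(
            doses=doses,
            viability=viability,
            top=float(top),
            bottom=float(bottom),
            hill=float(hill),
            ec50=float(ec50),
            sse=sse,
            converged=False,
            fitted=False,
        )
        curve.ic50_not_reached = True
        return curve
    curve = DoseResponseCurve(
        doses=doses,
        viability=viability,
        top=float(top),
        bottom=float(bottom),
        hill=float(hill),
        ec50=float(ec50),
        sse=sse,
        converged=True,
    )
    curve.ic50_value = ic50(curve)
    curve.ic50_not_reached = bool(np.isnan(curve.ic50_value))
    curve.ic50_interpolated = _interp_ic50(doses, viability)
    return curve


def ic50(curve: DoseResponseCurve) -> float:
    """Absolute IC50: dose where the fitted curve crosses 50% viability.

    Solving ``bottom + (top - bottom) / (1 + (d/ec50)^hill) = 50`` gives
    ``d = ec50 * ((top - 50) / (50 - bottom)) ** (1 / hill)``.  Returns
    NaN (not reached) when 50% lies outside (bottom, top) or the
    crossing falls beyond 10x the largest measured dose.
    """
    if not curve.fitted:
        raise InputError("curve was not successfully fitted")
    top, bottom, hill, ec50_ = curve.top, curve.bottom, curve.hill, curve.ec50
    if not (bottom < 50.0 < top):
        return float("nan")
    d = ec50_ * ((top - 50.0) / (50.0 - bottom)) ** (1.0 / hill)
    if d > 10.0 * curve.doses.max():
        return float("nan")
    return float(d)
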