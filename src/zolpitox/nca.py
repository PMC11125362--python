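"""Non-compartmental analysis of a single concentration-time profile.

Exposure metrics computed without assuming a structural model: Cmax/Tmax,
AUC by the linear-up/log-down trapezoidal rule, the terminal slope lambda_z
from a best-adjusted-R^2 log-linear regression over trailing post-peak
points (Cmax excluded), and the derived quantities

    half_life = ln(2) / lambda_z
    AUC_inf   = AUC_last + C_last / lambda_z
    CL/F      = 1000 * dose / AUC_inf      (dose mg, AUC ng*h/mL -> L/h)
    Vd/F      = (CL/F) / lambda_z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["NCAResult", "auc_linuplogdown", "fit_lambda_z", "nca_params"]

_MIN_LAMBDA_POINTS = 3


@dataclass(frozen=True)
class NCAResult:
    """NCA metrics for one profile; terminal-phase fields are NaN when
    lambda_z is not estimable."""

    cmax: float
    tmax: float
    auc_last: float
    auc_inf: float
    lambda_z: float
    n_lambda_points: int
    adj_r2: float
    half_life: float
    cl_f: float
    vd_f: float

    @property
    def lambda_z_estimable(self) -> bool:
        return not math.isnan(self.lambda_z)


def auc_linuplogdown(times, concs) -> float:
    """AUC over the observed span by the linear-up/log-down rule.

    Rising (or flat, or zero-touching) intervals use the linear trapezoid
    ``(c1 + c2)/2 * dt``; strictly declining intervals with both ends
    positive use the log trapezoid ``(c1 - c2) * dt / ln(c1/c2)``.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValueError("times and concs must be matching 1-D arrays")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    log_ok = (c2 < c1) & (c2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_seg = (c1 - c2) * dt / np.log(np.where(log_ok, c1 / np.where(c2 > 0, c2, 1.0), 1.0))
    lin_seg = 0.5 * (c1 + c2) * dt
    return float(np.sum(np.where(log_ok, log_seg, lin_seg)))


def fit_lambda_z(times, concs) -> tuple[float, int, float]:
    """Terminal slope of log-concentration vs time.

    Considers trailing subsets of >= 3 positive observations strictly after
    Tmax (Cmax itself excluded) and keeps the subset with the highest
    adjusted R^2; ties within 1e-4 prefer more points.  Returns
    ``(lambda_z, n_points, adj_r2)`` or ``(nan, 0, nan)`` when no subset
    qualifies or the best slope is nonnegative.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    i_max = int(np.argmax(c))
    mask = (np.arange(t.size) > i_max) & (c > 0)
    tt, cc = t[mask], np.log(c[mask])
    m = tt.size
    if m < _MIN_LAMBDA_POINTS:
        return math.nan, 0, math.nan
    best = None
    for k in range(_MIN_LAMBDA_POINTS, m + 1):
        x, y = tt[-k:], cc[-k:]
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        if best is None or adj > best[0] + 1e-4:
            best = (adj, k, slope)
    adj, k, slope = best
    if slope >= 0:
        return math.nan, 0, math.nan
    return float(-slope), int(k), float(adj)


def nca_params(times, concs, dose: float) -> NCAResult:
    """Full NCA of one profile (times h, concs ng/mL, dose mg)."""
    if dose <= 0:
        raise ValueError(f"dose must be > 0, got {dose}")
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    i_max = int(np.argmax(c))
    cmax = float(c[i_max])
    tmax = float(t[i_max])
    auc_last = auc_linuplogdown(t, c)
    lz, n_pts, adj_r2 = fit_lambda_z(t, c)
    if math.isnan(lz):
        return NCAResult(
            cmax=cmax, tmax=tmax, auc_last=auc_last, auc_inf=math.nan,
            lambda_z=math.nan, n_lambda_points=0, adj_r2=math.nan,
            half_life=math.nan, cl_f=math.nan, vd_f=math.nan,
        )
    pos = np.nonzero(c > 0)[0]
    c_last = float(c[pos[-1]]) if pos.size else 0.0
    auc_inf = auc_last + c_last / lz
    cl_f = 1000.0 * dose / auc_inf
    return NCAResult(
        cmax=cmax, tmax=tmax, auc_last=auc_last, auc_inf=auc_inf,
        lambda_z=lz, n_lambda_points=n_pts, adj_r2=adj_r2,
        half_life=math.log(2) / lz, cl_f=cl_f, vd_f=cl_f / lz,
    )
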