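"""Closed-form one-compartment oral-absorption model with lag time.

The structural model is a single well-mixed central compartment fed by a
depot at first-order rate ``ka`` and cleared at first-order rate
``ke = cl / v``, with absorption delayed by a lag ``tlag`` after each dose.
For a single oral dose ``D`` (mg) given at time 0 the plasma concentration
(ng/mL) at time ``t`` is the biexponential

    C(t) = 1000 * D*ka / (v*(ka - ke)) * (exp(-ke*tau) - exp(-ka*tau)),

with ``tau = t - tlag`` and ``C = 0`` for ``t <= tlag``.  The factor 1000
converts mg/L to ng/mL.  Multiple doses superpose linearly, each with its
own lag-shifted clock.

Everything in this module is deterministic; the population layer adds
between-subject variability on top of these curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "StructuralParams",
    "DoseEvent",
    "DoseRegimen",
    "TimeGrid",
    "conc_single_dose",
    "conc_profile",
    "typical_tmax_cmax",
    "ode_oracle",
]

# relative |ka - ke| below which the degenerate (ka == ke) limit form is used
_KA_KE_TOL = 1e-8


@dataclass(frozen=True)
class StructuralParams:
    """Fixed-effect PK constants of one subject's concentration curve.

    Parameters
    ----------
    ka : float
        Absorption rate constant (1/h).
    v : float
        Apparent volume of distribution Vd/F (L).
    cl : float
        Apparent clearance CL/F (L/h).
    tlag : float
        Absorption lag time (h); concentration is zero before it.
    """

    ka: float
    v: float
    cl: float
    tlag: float = 0.0

    def __post_init__(self) -> None:
        if not (self.ka > 0 and np.isfinite(self.ka)):
            raise ValueError(f"ka must be positive and finite, got {self.ka}")
        if not (self.v > 0 and np.isfinite(self.v)):
            raise ValueError(f"v must be positive and finite, got {self.v}")
        if not (self.cl > 0 and np.isfinite(self.cl)):
            raise ValueError(f"cl must be positive and finite, got {self.cl}")
        if not (self.tlag >= 0 and np.isfinite(self.tlag)):
            raise ValueError(f"tlag must be nonnegative, got {self.tlag}")

    @property
    def ke(self) -> float:
        """Elimination rate constant CL/V (1/h)."""
        return self.cl / self.v


@dataclass(frozen=True)
class DoseEvent:
    """A single oral dose: ``amount`` mg administered at ``time`` h."""

    time: float
    amount: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.amount <= 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")


@dataclass(frozen=True)
class DoseRegimen:
    """An ordered, nonempty sequence of dose events."""

    events: tuple[DoseEvent, ...]

    def __init__(self, events: Sequence[DoseEvent]):
        events = tuple(events)
        if not events:
            raise ValueError("regimen must contain at least one dose event")
        times = [e.time for e in events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose times must be nondecreasing")
        object.__setattr__(self, "events", events)

    @classmethod
    def single(cls, amount: float, time: float = 0.0) -> "DoseRegimen":
        return cls([DoseEvent(time=time, amount=amount)])

    @property
    def total_dose(self) -> float:
        return sum(e.amount for e in self.events)


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing sampling times (h), starting at >= 0."""

    times: np.ndarray = field(repr=False)

    def __init__(self, times: Sequence[float]):
        arr = np.asarray(times, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("time grid must be a nonempty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise ValueError("time grid must be finite")
        if arr[0] < 0:
            raise ValueError("time grid must start at >= 0")
        if not np.all(np.diff(arr) > 0):
            raise ValueError("time grid must be strictly increasing")
        arr.setflags(write=False)
        object.__setattr__(self, "times", arr)

    def __len__(self) -> int:
        return self.times.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


def _conc_kernel(ka, v, cl, tlag, dose, t):
    """Broadcastable concentration kernel for a dose at time 0.

    All arguments may be arrays; shapes broadcast.  Returns ng/mL.
    """
    ka = np.asarray(ka, dtype=float)
    v = np.asarray(v, dtype=float)
    cl = np.asarray(cl, dtype=float)
    tlag = np.asarray(tlag, dtype=float)
    dose = np.asarray(dose, dtype=float)
    t = np.asarray(t, dtype=float)

    ke = cl / v
    tau = t - tlag
    active = tau > 0
    tau = np.where(active, tau, 0.0)

    degenerate = np.abs(ka - ke) < _KA_KE_TOL * ke
    # regular biexponential; guard the denominator where degenerate
    denom = np.where(degenerate, 1.0, ka - ke)
    regular = dose * ka / (v * denom) * (np.exp(-ke * tau) - np.exp(-ka * tau))
    # ka -> ke limit: C = D/v * ke * tau * exp(-ke*tau)
    limit = dose / v * ke * tau * np.exp(-ke * tau)
    c = np.where(degenerate, limit, regular)
    return 1000.0 * np.where(active, c, 0.0)


def _conc_grad_kernel(ka, v, cl, tlag, dose, t):
    """Concentration and its partials w.r.t. (ka, v, cl) for a dose at t=0.

    Broadcastable like :func:`_conc_kernel`.  Used by the estimation layer
    for analytic inner-problem derivatives; the near-degenerate ``ka == ke``
    direction is regularized rather than given its exact limit (individual
    draws essentially never land on it).
    """
    ka = np.asarray(ka, dtype=float)
    v = np.asarray(v, dtype=float)
    cl = np.asarray(cl, dtype=float)
    t = np.asarray(t, dtype=float)
    ke = cl / v
    tau = t - np.asarray(tlag, dtype=float)
    active = tau > 0
    tau = np.where(active, tau, 0.0)
    d = ka - ke
    d = np.where(np.abs(d) < 1e-10 * ke, 1e-10 * ke, d)
    K = 1000.0 * np.asarray(dose, dtype=float) / v
    e1 = np.exp(-ke * tau)
    e2 = np.exp(-ka * tau)
    diff = e1 - e2
    c = K * ka / d * diff
    dka = -K * ke / d**2 * diff + K * ka / d * tau * e2
    dke = K * ka * (diff / d**2 - tau * e1 / d)
    dcl = dke / v
    dv = -c / v - ke / v * dke
    zero = np.zeros(np.broadcast_shapes(c.shape, active.shape))
    return (
        np.where(active, c, zero),
        np.where(active, dka, zero),
        np.where(active, dv, zero),
        np.where(active, dcl, zero),
    )


def conc_single_dose(p: StructuralParams, dose: float, t) -> np.ndarray | float:
    """Concentration (ng/mL) after a single dose (mg) at time 0.

    ``t`` may be a scalar or array of times (h).  Zero before the lag time;
    the ``ka == ke`` degeneracy is handled by an explicit limit branch.
    """
    if dose <= 0:
        raise ValueError(f"dose must be > 0, got {dose}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    out = _conc_kernel(p.ka, p.v, p.cl, p.tlag, dose, t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def conc_profile(p: StructuralParams, regimen: DoseRegimen, grid: TimeGrid) -> np.ndarray:
    """Concentration profile (ng/mL) over ``grid`` by linear superposition."""
    t = grid.times
    total = np.zeros_like(t)
    for ev in regimen.events:
        total += _conc_kernel(p.ka, p.v, p.cl, p.tlag, ev.amount, np.maximum(t - ev.time, 0.0)) * (
            t >= ev.time
        )
    return total


def typical_tmax_cmax(p: StructuralParams, dose: float) -> tuple[float, float]:
    """Closed-form peak time and peak concentration for a single dose at t=0.

    ``tmax = tlag + ln(ka/ke)/(ka - ke)``; in the ``ka == ke`` limit
    ``tmax = tlag + 1/ke``.
    """
    ke = p.ke
    if abs(p.ka - ke) < _KA_KE_TOL * ke:
        tmax = p.tlag + 1.0 / ke
    else:
        tmax = p.tlag + np.log(p.ka / ke) / (p.ka - ke)
    cmax = conc_single_dose(p, dose, tmax)
    return float(tmax), float(cmax)


def ode_oracle(
    p: StructuralParams,
    regimen: DoseRegimen,
    grid: TimeGrid,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    max_step: float = 0.25,
) -> np.ndarray:
    """Concentration profile by direct numerical integration of the ODE system.

    Integrates ``dA_depot/dt = -ka*A_depot`` and
    ``dA_central/dt = ka*A_depot - ke*A_central`` with each dose entering the
    depot as a bolus at its event time plus the absorption lag.  Serves as an
    independent cross-check of the closed-form superposition evaluator; the
    two must agree to better than 1e-6 relative.
    """
    ka, ke, v = p.ka, p.ke, p.v
    t_grid = grid.times
    bolus = sorted((ev.time + p.tlag, ev.amount) for ev in regimen.events)

    def rhs(_t, y):
        return [-ka * y[0], ka * y[0] - ke * y[1]]

    # integrate piecewise from t=0 between bolus instants, evaluating at grid times
    out = np.zeros_like(t_grid)
    state = np.zeros(2)
    t_now = 0.0
    t_end = float(t_grid[-1])
    amounts: dict[float, float] = {}
    for bt, amt in bolus:
        amounts[bt] = amounts.get(bt, 0.0) + amt
        if bt <= t_now:
            state[0] += amt
    breakpoints = [bt for bt in amounts if t_now < bt <= t_end] + [t_end]
    for t_next in sorted(set(breakpoints)):
        if t_next > t_now:
            sel = (t_grid > t_now) & (t_grid <= t_next)
            t_eval = t_grid[sel]
            pad = t_eval.size == 0 or t_eval[-1] < t_next
            sol = solve_ivp(
                rhs,
                (t_now, t_next),
                state,
                t_eval=np.concatenate([t_eval, [t_next]]) if pad else t_eval,
                rtol=rtol,
                atol=atol,
                max_step=max_step,  # bounds dense-output interpolation error in the tail
                method="DOP853",
            )
            if not sol.success:
                raise RuntimeError(f"ODE integration failed: {sol.message}")
            if t_eval.size:
                out[sel] = sol.y[1][: t_eval.size]
            state = sol.y[:, -1].copy()
            t_now = t_next
        if t_next in amounts:
            state[0] += amounts[t_next]
    return 1000.0 * out / v
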