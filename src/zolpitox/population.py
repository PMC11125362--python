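"""Population layer: typical values, correlated lognormal IIV, residual error.

Individual parameters follow ``P_i = theta * exp(eta_i)`` with
``eta ~ N(0, Omega)`` on the log scale; Omega carries variances for
(Ka, Vd, CL) with a single Vd–CL correlation and an independent Ka.
Observations carry proportional residual error ``DV = IPRED * (1 + eps)``
with ``eps ~ N(0, sigma^2)``.

The default parameter set describes immediate-release oral zolpidem in
healthy adults: typical Ka 5.41 1/h, Vd/F 61.7 L, CL/F 16.9 L/h, lag
0.394 h; IIV coefficients of variation 158.91 / 22.10 / 32.60 % on
Ka / Vd / CL with corr(eta_Vd, eta_CL) = 0.853; proportional error SD
0.284.  The lag time carries no interindividual variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

from .structural import StructuralParams

__all__ = [
    "PopulationParams",
    "IndividualParams",
    "omega_from_cv",
    "sample_individuals",
    "apply_residual_error",
    "reference_params",
    "load_population_config",
    "REFERENCE_CV",
]

CVConvention = Literal["exact-lognormal", "sd-equals-cv"]

# typical values and variability of the default zolpidem model
REFERENCE_THETA = StructuralParams(ka=5.41, v=61.7, cl=16.9, tlag=0.394)
REFERENCE_CV = dict(cv_ka=158.91, cv_v=22.10, cv_cl=32.60, rho_v_cl=0.853)
REFERENCE_SIGMA_PROP = 0.284


def omega_from_cv(
    cv_ka: float,
    cv_v: float,
    cv_cl: float,
    rho_v_cl: float,
    convention: CVConvention = "exact-lognormal",
) -> np.ndarray:
    """Build the 3x3 log-scale IIV covariance from CV percentages.

    Under ``exact-lognormal`` (default) the log-variance is
    ``omega^2 = ln(1 + (CV/100)^2)``, the exact relation for a lognormal
    variate; under ``sd-equals-cv`` it is ``(CV/100)^2``, the common
    reporting shortcut where CV% is taken as 100*sqrt(omega^2).  The two
    differ negligibly for small CVs but materially above ~50%.

    The Vd–CL off-diagonal is ``rho * omega_v * omega_cl``; Ka is
    independent of the pair.
    """
    cvs = np.array([cv_ka, cv_v, cv_cl], dtype=float) / 100.0
    if np.any(cvs < 0):
        raise ValueError("CV percentages must be nonnegative")
    if not -1.0 <= rho_v_cl <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {rho_v_cl}")
    if convention == "exact-lognormal":
        w2 = np.log1p(cvs**2)
    elif convention == "sd-equals-cv":
        w2 = cvs**2
    else:
        raise ValueError(f"unknown CV convention: {convention!r}")
    omega = np.diag(w2)
    omega[1, 2] = omega[2, 1] = rho_v_cl * np.sqrt(w2[1] * w2[2])
    return omega


@dataclass(frozen=True)
class PopulationParams:
    """Typical values plus between-subject and residual variability.

    ``omega`` is the 3x3 covariance of (eta_Ka, eta_Vd, eta_CL) on the log
    scale; ``sigma_prop`` the proportional residual SD.
    """

    theta: StructuralParams
    omega: np.ndarray = field(repr=False)
    sigma_prop: float

    def __init__(self, theta: StructuralParams, omega, sigma_prop: float):
        omega = np.array(omega, dtype=float)
        if omega.shape != (3, 3):
            raise ValueError(f"omega must be 3x3, got shape {omega.shape}")
        if not np.allclose(omega, omega.T, atol=1e-12):
            raise ValueError("omega must be symmetric")
        eigmin = np.linalg.eigvalsh(omega).min()
        if eigmin < -1e-10:
            raise ValueError(f"omega must be positive semidefinite (min eig {eigmin:.3g})")
        if sigma_prop < 0:
            raise ValueError(f"sigma_prop must be >= 0, got {sigma_prop}")
        omega.setflags(write=False)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "sigma_prop", float(sigma_prop))

    def cholesky(self) -> np.ndarray:
        """Lower-triangular square root of omega (PSD-safe)."""
        try:
            return np.linalg.cholesky(self.omega)
        except np.linalg.LinAlgError:
            # PSD but singular: eigen square root, lower-triangularized via QR
            w, q = np.linalg.eigh(self.omega)
            w = np.clip(w, 0.0, None)
            root = q @ np.diag(np.sqrt(w))
            return root


@dataclass(frozen=True)
class IndividualParams:
    """One subject's realized parameters ``P_i = theta * exp(eta_i)``."""

    subject: int
    eta: np.ndarray = field(repr=False)
    params: StructuralParams

    @classmethod
    def from_eta(cls, subject: int, eta: np.ndarray, theta: StructuralParams) -> "IndividualParams":
        eta = np.asarray(eta, dtype=float)
        if eta.shape != (3,) or not np.all(np.isfinite(eta)):
            raise ValueError("eta must be a finite 3-vector")
        p = StructuralParams(
            ka=theta.ka * float(np.exp(eta[0])),
            v=theta.v * float(np.exp(eta[1])),
            cl=theta.cl * float(np.exp(eta[2])),
            tlag=theta.tlag,
        )
        return cls(subject=subject, eta=eta, params=p)


def reference_params(
    convention: CVConvention = "exact-lognormal",
    sigma_prop: float = REFERENCE_SIGMA_PROP,
) -> PopulationParams:
    """The default zolpidem population parameter set (see module docstring)."""
    omega = omega_from_cv(convention=convention, **REFERENCE_CV)
    return PopulationParams(theta=REFERENCE_THETA, omega=omega, sigma_prop=sigma_prop)


def sample_individuals(
    pop: PopulationParams, n: int, seed: int | np.random.Generator
) -> list[IndividualParams]:
    """Draw ``n`` subjects with ``eta ~ N(0, omega)``, realized multiplicatively.

    Draws are made subject-by-subject in a fixed order (subjects outer,
    eta components inner) from numpy's default PCG64 generator, so a given
    seed always yields the same cohort.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal((n, 3))
    etas = z @ pop.cholesky().T
    return [IndividualParams.from_eta(i, etas[i], pop.theta) for i in range(n)]


def apply_residual_error(
    ipred: np.ndarray, sigma_prop: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Multiply predictions by ``(1 + eps)`` with ``eps ~ N(0, sigma^2)`` i.i.d.

    Zero predictions stay exactly zero (the error is multiplicative).
    Raw output may be negative in the Gaussian tail; callers that need
    physical concentrations truncate (see the study generator).
    """
    if sigma_prop < 0:
        raise ValueError(f"sigma_prop must be >= 0, got {sigma_prop}")
    ipred = np.asarray(ipred, dtype=float)
    if np.any(ipred < 0):
        raise ValueError("ipred must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.standard_normal(ipred.shape) * sigma_prop
    return ipred * (1.0 + eps)


def load_population_config(path: str | Path) -> PopulationParams:
    """Read population parameters from a plain-text key-value (YAML) file.

    Recognized keys: ``ka, v, cl, tlag`` (typical values), ``cv_ka, cv_v,
    cv_cl, rho_v_cl`` (IIV), ``sigma_prop`` (residual SD) and
    ``cv_convention``.  Missing keys fall back to the zolpidem defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"population config must be a key-value mapping: {path}")
    known = {
        "ka", "v", "cl", "tlag",
        "cv_ka", "cv_v", "cv_cl", "rho_v_cl",
        "sigma_prop", "cv_convention",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    theta = replace(
        REFERENCE_THETA,
        **{k: float(raw[k]) for k in ("ka", "v", "cl", "tlag") if k in raw},
    )
    cv = dict(REFERENCE_CV)
    cv.update({k: float(raw[k]) for k in ("cv_ka", "cv_v", "cv_cl", "rho_v_cl") if k in raw})
    convention = raw.get("cv_convention", "exact-lognormal")
    omega = omega_from_cv(convention=convention, **cv)
    sigma = float(raw.get("sigma_prop", REFERENCE_SIGMA_PROP))
    return PopulationParams(theta=theta, omega=omega, sigma_prop=sigma)
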