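"""FOCE-I nonlinear mixed-effects estimation, LRT, bootstrap, CWRES, VPC.

The marginal likelihood of each subject's data is approximated by the
first-order conditional method with interaction (FOCE-I): the random-effect
vector ``eta_i`` is set to the mode of the penalized conditional objective

    g_i(eta) = sum_j [ (dv_ij - f_ij(eta))^2 / var_ij + ln var_ij ]
               + eta' Omega^{-1} eta,      var_ij = sigma^2 f_ij(eta)^2,

the model is linearized about that mode with gradient ``G_i = df/deta``,
and the subject's contribution to the objective function value is

    OFV_i = ln det V_i + e_i' V_i^{-1} e_i,
    V_i = G_i Omega G_i' + diag(sigma^2 f_i(eta_hat)^2),
    e_i = dv_i - f_i(eta_hat) + G_i eta_hat,

the extended-least-squares form without the ``n ln(2pi)`` constant, so the
usual chi-squared drop criterion (Delta OFV > 3.84 for one added
parameter) applies directly.  The residual variance is evaluated at the
conditional (not population) prediction — the "interaction".

The outer problem optimizes log typical values, a log-Cholesky factor of
Omega (independent Ka, correlated Vd-CL block) and log sigma, so all
positivity/PSD constraints are unconstrained.  Standard errors come from
the inverse numerical Hessian of OFV/2 with a delta-method transform to
the reporting scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import minimize
from scipy.stats import chi2

from .dataset import PKDataset
from .population import PopulationParams, sample_individuals, apply_residual_error
from .structural import StructuralParams, _conc_kernel, _conc_grad_kernel

__all__ = [
    "ModelConfig",
    "FitResult",
    "BootstrapResult",
    "VPCResult",
    "foce_i_objective",
    "fit",
    "lrt",
    "covariate_sex_test",
    "bootstrap",
    "cwres_and_gof",
    "vpc",
]

_FLOOR = 1e-6  # ng/mL; keeps the proportional-error likelihood defined at f ~ 0
_ETA_FD_STEP = 1e-4


@dataclass(frozen=True)
class ModelConfig:
    """Structural/estimation switches for a fit.

    ``estimate_lag=False`` drops the absorption lag (the nested reduction
    used in the lag LRT); ``sex_covariate_on`` adds a multiplicative
    ``exp(beta * I(female))`` factor on ``"cl"`` or ``"v"``.
    """

    estimate_lag: bool = True
    sex_covariate_on: str | None = None

    def __post_init__(self) -> None:
        if self.sex_covariate_on not in (None, "cl", "v"):
            raise ValueError("sex_covariate_on must be None, 'cl' or 'v'")


class _Prep:
    """Padded per-subject arrays extracted once from a PKDataset."""

    def __init__(self, data: PKDataset, config: ModelConfig):
        ids = data.subject_ids
        self.ids = ids
        self.n = len(ids)
        obs_t, obs_dv, dose_t, dose_a = [], [], [], []
        for sid in ids:
            grp = data.subject(sid)
            obs = grp[(grp["evid"] == 0) & (grp["mdv"] == 0)]
            doses = grp[grp["evid"] == 1]
            obs_t.append(obs["time"].to_numpy(float))
            obs_dv.append(obs["dv"].to_numpy(float))
            dose_t.append(doses["time"].to_numpy(float))
            dose_a.append(doses["amt"].to_numpy(float))
        jmax = max(len(t) for t in obs_t)
        emax = max(len(t) for t in dose_t)
        if min(len(t) for t in obs_t) < 1:
            raise ValueError("every subject needs at least one usable observation")
        self.t = np.zeros((self.n, jmax))
        self.dv = np.zeros((self.n, jmax))
        self.mask = np.zeros((self.n, jmax), dtype=bool)
        self.dose_t = np.zeros((self.n, emax))
        self.dose_a = np.zeros((self.n, emax))
        for i in range(self.n):
            j = len(obs_t[i])
            self.t[i, :j] = obs_t[i]
            self.dv[i, :j] = obs_dv[i]
            self.mask[i, :j] = True
            e = len(dose_t[i])
            self.dose_t[i, :e] = dose_t[i]
            self.dose_a[i, :e] = dose_a[i]
        self.n_obs = int(self.mask.sum())
        self.sex = None
        if config.sex_covariate_on is not None:
            if data.covariates is None or "sex" not in data.covariates.columns:
                raise ValueError("sex covariate requested but dataset has no sex labels")
            labels = data.covariates.loc[ids, "sex"]
            if labels.nunique() < 2:
                raise ValueError("sex covariate not testable: all subjects share one label")
            self.sex = (labels.to_numpy() == "F").astype(float)

    def predict(self, theta: StructuralParams, eta: np.ndarray, beta: float, on: str | None):
        """Concentration matrix f(eta), shape (n, jmax)."""
        ka = theta.ka * np.exp(eta[:, 0])
        v = theta.v * np.exp(eta[:, 1])
        cl = theta.cl * np.exp(eta[:, 2])
        if on == "cl":
            cl = cl * np.exp(beta * self.sex)
        elif on == "v":
            v = v * np.exp(beta * self.sex)
        f = np.zeros_like(self.t)
        for e in range(self.dose_t.shape[1]):
            amt = self.dose_a[:, e][:, None]
            dt = self.t - self.dose_t[:, e][:, None]
            live = (amt > 0) & (dt >= 0)
            f += np.where(
                live,
                _conc_kernel(ka[:, None], v[:, None], cl[:, None], theta.tlag, amt, np.maximum(dt, 0.0)),
                0.0,
            )
        return f

    def predict_grad(self, theta: StructuralParams, eta: np.ndarray, beta: float, on: str | None):
        """Concentration matrix and its Jacobian w.r.t. eta, shapes (n, jmax)
        and (n, jmax, 3).  Chain rule: d f / d eta_k = P_k * d f / d P_k."""
        ka = theta.ka * np.exp(eta[:, 0])
        v = theta.v * np.exp(eta[:, 1])
        cl = theta.cl * np.exp(eta[:, 2])
        if on == "cl":
            cl = cl * np.exp(beta * self.sex)
        elif on == "v":
            v = v * np.exp(beta * self.sex)
        f = np.zeros_like(self.t)
        J = np.zeros(self.t.shape + (3,))
        kac, vc, clc = ka[:, None], v[:, None], cl[:, None]
        for e in range(self.dose_t.shape[1]):
            amt = self.dose_a[:, e][:, None]
            dt = self.t - self.dose_t[:, e][:, None]
            live = (amt > 0) & (dt >= 0)
            c, dka, dv, dcl = _conc_grad_kernel(kac, vc, clc, theta.tlag, amt, np.maximum(dt, 0.0))
            f += np.where(live, c, 0.0)
            J[:, :, 0] += np.where(live, kac * dka, 0.0)
            J[:, :, 1] += np.where(live, vc * dv, 0.0)
            J[:, :, 2] += np.where(live, clc * dcl, 0.0)
        return f, J


def _inner_objective(prep, f, eta, sigma2, omega_inv):
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        fc = np.maximum(f, _FLOOR)
        var = sigma2 * fc**2
        r = np.where(prep.mask, prep.dv - f, 0.0)
        terms = np.where(prep.mask, r**2 / var + np.log(var), 0.0)
        g = terms.sum(axis=1) + np.einsum("nk,kl,nl->n", eta, omega_inv, eta)
    return np.where(np.isfinite(g), g, np.inf)


def _solve_etas(prep, theta, beta, on, sigma2, omega_inv, eta0, tol=2e-6, max_iter=25):
    """Batched damped Gauss-Newton for the conditional eta modes."""
    eta = eta0.copy()

    def f_of(e):
        return prep.predict(theta, e, beta, on)

    g = _inner_objective(prep, f_of(eta), eta, sigma2, omega_inv)
    for _ in range(max_iter):
        f, J = prep.predict_grad(theta, eta, beta, on)
        fc = np.maximum(f, _FLOOR)
        var = sigma2 * fc**2
        r = prep.dv - f
        floored = f < _FLOOR
        dgdf = np.where(
            floored,
            -2 * r / var,
            -2 * r / var - 2 * r**2 / (sigma2 * fc**3) + 2.0 / fc,
        )
        dgdf = np.where(prep.mask, dgdf, 0.0)
        grad = np.einsum("njk,nj->nk", J, dgdf) + 2 * eta @ omega_inv
        w = np.where(prep.mask, 1.0 / var, 0.0)
        H = 2 * np.einsum("nja,nj,njb->nab", J, w, J) + 2 * omega_inv[None]
        H = H + 1e-8 * np.eye(3)[None]
        try:
            step = -np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = -grad
        # trust region: |eta| beyond ~6 SDs is never the mode, and huge
        # trial steps overflow exp() before backtracking can reject them
        step = np.clip(step, -4.0, 4.0)
        # the Newton step approximates the remaining eta error
        if np.max(np.abs(grad)) < tol or np.max(np.abs(step)) < 1e-7:
            break
        # per-subject backtracking
        alpha = np.ones(prep.n)
        improved = np.zeros(prep.n, dtype=bool)
        eta_new = eta.copy()
        g_new = g.copy()
        for _bt in range(15):
            trial = eta + alpha[:, None] * step
            g_trial = _inner_objective(prep, f_of(trial), trial, sigma2, omega_inv)
            better = (g_trial < g_new) & ~improved
            eta_new[better] = trial[better]
            g_new[better] = g_trial[better]
            improved |= g_trial <= g + 1e-12
            if improved.all():
                break
            alpha = np.where(improved, alpha, alpha * 0.5)
        if np.max(g - g_new) < 1e-7:  # stagnation: only polishing left
            eta, g = eta_new, g_new
            break
        eta, g = eta_new, g_new
    return eta


def _foce_ofv(prep, theta, omega, sigma, beta=0.0, on=None, eta0=None):
    """FOCE-I objective and conditional etas for fixed population parameters."""
    sigma2 = sigma**2
    omega_reg = omega + 1e-10 * np.eye(3)
    omega_inv = np.linalg.inv(omega_reg)
    if eta0 is None:
        eta0 = np.zeros((prep.n, 3))
    eta = _solve_etas(prep, theta, beta, on, sigma2, omega_inv, eta0)
    f, J = prep.predict_grad(theta, eta, beta, on)
    fc = np.maximum(f, _FLOOR)
    var = sigma2 * fc**2
    ofv = 0.0
    per_subject = np.empty(prep.n)
    for i in range(prep.n):
        m = prep.mask[i]
        G = J[i][m]
        V = G @ omega_reg @ G.T + np.diag(var[i][m])
        e = (prep.dv[i] - f[i])[m] + G @ eta[i]
        sign, logdet = np.linalg.slogdet(V)
        if sign <= 0:
            per_subject[i] = np.inf
        else:
            per_subject[i] = logdet + float(e @ np.linalg.solve(V, e))
        ofv += per_subject[i]
    return float(ofv), eta, per_subject


def foce_i_objective(
    data: PKDataset,
    pop: PopulationParams,
    config: ModelConfig = ModelConfig(),
    beta_sex: float = 0.0,
    eta_init: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Evaluate the FOCE-I objective at fixed population parameters.

    Returns ``(ofv, conditional_etas)``; ``ofv`` is +inf when a subject's
    linearized covariance is not positive definite.
    """
    if pop.sigma_prop <= 0:
        raise ValueError("sigma_prop must be > 0 for estimation")
    prep = _Prep(data, config)
    ofv, eta, _ = _foce_ofv(
        prep, pop.theta, np.asarray(pop.omega), pop.sigma_prop,
        beta=beta_sex, on=config.sex_covariate_on, eta0=eta_init,
    )
    return ofv, eta


# ---------------------------------------------------------------------------
# outer parameterization


class _Pack:
    """Bijection between the optimizer vector and population parameters."""

    def __init__(self, config: ModelConfig):
        self.config = config
        names = ["lka", "lv", "lcl"]
        if config.estimate_lag:
            names.append("ltlag")
        names += ["lwka", "ll11", "l21", "ll22", "lsigma"]
        if config.sex_covariate_on is not None:
            names.append("beta")
        self.names = names

    def pack(self, pop: PopulationParams, beta: float = 0.0) -> np.ndarray:
        th = pop.theta
        x = [math.log(th.ka), math.log(th.v), math.log(th.cl)]
        if self.config.estimate_lag:
            x.append(math.log(max(th.tlag, 1e-6)))
        om = np.asarray(pop.omega)
        wka = math.sqrt(max(om[0, 0], 1e-10))
        l11 = math.sqrt(max(om[1, 1], 1e-10))
        l21 = om[1, 2] / l11
        l22 = math.sqrt(max(om[2, 2] - l21**2, 1e-10))
        x += [math.log(wka), math.log(l11), l21, math.log(l22), math.log(pop.sigma_prop)]
        if self.config.sex_covariate_on is not None:
            x.append(beta)
        return np.array(x)

    def unpack(self, x: np.ndarray):
        i = 0
        ka, v, cl = np.exp(x[0]), np.exp(x[1]), np.exp(x[2])
        i = 3
        if self.config.estimate_lag:
            tlag = float(np.exp(x[i])); i += 1
        else:
            tlag = 0.0
        wka, l11 = np.exp(x[i]), np.exp(x[i + 1])
        l21 = x[i + 2]
        l22 = np.exp(x[i + 3])
        sigma = float(np.exp(x[i + 4]))
        i += 5
        beta = float(x[i]) if self.config.sex_covariate_on is not None else 0.0
        omega = np.array(
            [
                [wka**2, 0.0, 0.0],
                [0.0, l11**2, l11 * l21],
                [0.0, l11 * l21, l21**2 + l22**2],
            ]
        )
        theta = StructuralParams(ka=float(ka), v=float(v), cl=float(cl), tlag=tlag)
        return theta, omega, sigma, beta

    def report(self, x: np.ndarray) -> dict[str, float]:
        """Natural-scale reporting vector."""
        theta, omega, sigma, beta = self.unpack(x)
        out = {
            "ka": theta.ka, "v": theta.v, "cl": theta.cl, "tlag": theta.tlag,
            "omega2_ka": omega[0, 0], "omega2_v": omega[1, 1], "omega2_cl": omega[2, 2],
            "rho_v_cl": omega[1, 2] / math.sqrt(omega[1, 1] * omega[2, 2]),
            "sigma_prop": sigma,
        }
        if self.config.sex_covariate_on is not None:
            out["beta_sex"] = beta
        if not self.config.estimate_lag:
            del out["tlag"]
        return out


@dataclass(frozen=True)
class FitResult:
    """Point estimates and diagnostics from one FOCE-I fit."""

    estimates: PopulationParams
    beta_sex: float
    ofv: float
    se: dict[str, float]
    rse_percent: dict[str, float]
    etas: np.ndarray = field(repr=False)
    subject_ids: list = field(repr=False)
    converged: bool
    n_iter: int
    trace: list = field(repr=False)
    config: ModelConfig
    x_opt: np.ndarray = field(repr=False)

    @property
    def params(self) -> dict[str, float]:
        return _Pack(self.config).report(self.x_opt)


def fit(
    data: PKDataset,
    init: PopulationParams,
    config: ModelConfig = ModelConfig(),
    beta_init: float = 0.0,
    compute_se: bool = True,
    polish_maxfev: int = 1200,
    lbfgs_maxiter: int = 200,
) -> FitResult:
    """Maximum-likelihood fit of the population model by FOCE-I.

    Two-stage outer optimization on the unconstrained (log / log-Cholesky)
    scale: a quasi-Newton descent with finite-difference gradients followed
    by a derivative-free simplex polish, which handles the mild noise floor
    left by the iterative inner problem.  Deterministic given data and
    starting values.  Standard errors come from the inverse numerical
    Hessian of OFV/2; when that matrix is not positive definite the
    estimates are still returned with SEs flagged NaN.
    """
    prep = _Prep(data, config)
    pack = _Pack(config)
    x0 = pack.pack(init, beta_init)
    warm = {"eta": np.zeros((prep.n, 3))}
    trace: list[float] = []

    def obj(x):
        theta, omega, sigma, beta = pack.unpack(x)
        try:
            ofv, eta, _ = _foce_ofv(
                prep, theta, omega, sigma, beta, config.sex_covariate_on, warm["eta"]
            )
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12
        if not np.isfinite(ofv):
            return 1e12
        warm["eta"] = eta
        trace.append(ofv)
        return ofv

    res1 = minimize(
        obj, x0, method="L-BFGS-B",
        options=dict(maxiter=lbfgs_maxiter, ftol=1e-11, eps=1e-4),
    )
    success = bool(res1.success)
    x_opt, nit = res1.x, int(res1.nit)
    if polish_maxfev > 0:
        res2 = minimize(
            obj, x_opt, method="Nelder-Mead",
            options=dict(maxfev=polish_maxfev, xatol=1e-6, fatol=1e-8, adaptive=True),
        )
        if res2.fun <= res1.fun:
            x_opt = res2.x
        success = success or bool(res2.success)
        nit += int(res2.nit)
    theta, omega, sigma, beta = pack.unpack(x_opt)
    ofv, eta, _ = _foce_ofv(prep, theta, omega, sigma, beta, config.sex_covariate_on, warm["eta"])
    estimates = PopulationParams(theta=theta, omega=omega, sigma_prop=sigma)

    rep = pack.report(x_opt)
    se = {k: math.nan for k in rep}
    rse = {k: math.nan for k in rep}
    if compute_se:
        try:
            cov = _covariance(obj, x_opt, pack)
            jac = _report_jacobian(pack, x_opt)
            cov_r = jac @ cov @ jac.T
            diag = np.diag(cov_r)
            keys = list(rep)
            for k, vkk in zip(keys, diag):
                if vkk > 0:
                    se[k] = math.sqrt(vkk)
                    denom = abs(rep[k])
                    rse[k] = 100.0 * se[k] / denom if denom > 0 else math.nan
        except np.linalg.LinAlgError:
            pass

    return FitResult(
        estimates=estimates, beta_sex=beta, ofv=ofv, se=se, rse_percent=rse,
        etas=eta, subject_ids=prep.ids, converged=success, n_iter=nit,
        trace=trace, config=config, x_opt=x_opt,
    )


def _covariance(obj, x_opt, pack, step=1e-3):
    """Asymptotic covariance 2*H^{-1} from the central-difference Hessian of OFV."""
    k = x_opt.size
    H = np.empty((k, k))
    f0 = obj(x_opt)
    hs = step * np.maximum(np.abs(x_opt), 1.0)
    for a in range(k):
        for b in range(a, k):
            ea = np.zeros(k); ea[a] = hs[a]
            eb = np.zeros(k); eb[b] = hs[b]
            if a == b:
                H[a, a] = (obj(x_opt + ea) - 2 * f0 + obj(x_opt - ea)) / hs[a] ** 2
            else:
                H[a, b] = H[b, a] = (
                    obj(x_opt + ea + eb) - obj(x_opt + ea - eb)
                    - obj(x_opt - ea + eb) + obj(x_opt - ea - eb)
                ) / (4 * hs[a] * hs[b])
    # OFV = -2 log L  =>  Fisher info ~ H/2  =>  cov = 2 H^{-1}
    eigvals = np.linalg.eigvalsh(H)
    if eigvals.min() <= 0:
        raise np.linalg.LinAlgError("OFV Hessian not positive definite")
    return 2.0 * np.linalg.inv(H)


def _report_jacobian(pack, x, step=1e-6):
    keys = list(pack.report(x))
    k = x.size
    J = np.empty((len(keys), k))
    for b in range(k):
        e = np.zeros(k); e[b] = step
        rp = pack.report(x + e)
        rm = pack.report(x - e)
        J[:, b] = [(rp[key] - rm[key]) / (2 * step) for key in keys]
    return J


# ---------------------------------------------------------------------------
# model comparison


def lrt(ofv_reduced: float, ofv_full: float, df_added: int = 1) -> tuple[float, bool]:
    """Likelihood-ratio test between nested fits.

    Returns ``(delta_ofv, significant)`` with significance declared iff the
    drop strictly exceeds the chi-squared 95th percentile (3.84 for one
    added parameter).  A materially negative drop signals an optimization
    failure in the full model and raises a warning-level error.
    """
    if df_added < 1:
        raise ValueError("df_added must be >= 1")
    delta = ofv_reduced - ofv_full
    if delta < -1e-3:
        import warnings

        warnings.warn(
            f"full model has higher OFV than reduced (delta={delta:.4g}); "
            "optimization of the full model likely failed",
            RuntimeWarning,
            stacklevel=2,
        )
    crit = float(chi2.ppf(0.95, df_added))
    return float(delta), bool(delta > crit)


def covariate_sex_test(
    data: PKDataset,
    init: PopulationParams,
    on: str = "cl",
    base_fit: FitResult | None = None,
) -> dict:
    """LRT for a multiplicative sex effect on CL (or V)."""
    if data.covariates is None or "sex" not in data.covariates.columns:
        raise ValueError("dataset has no sex labels")
    if data.covariates["sex"].nunique() < 2:
        raise ValueError("sex covariate not testable: all subjects share one label")
    if base_fit is None:
        base_fit = fit(data, init, ModelConfig(), compute_se=False)
    full = fit(
        data, base_fit.estimates, ModelConfig(sex_covariate_on=on),
        compute_se=False,
    )
    delta, significant = lrt(base_fit.ofv, full.ofv, df_added=1)
    return dict(
        delta_ofv=delta, significant=significant, beta_sex=full.beta_sex,
        base_fit=base_fit, full_fit=full, on=on,
    )


# ---------------------------------------------------------------------------
# bootstrap


@dataclass(frozen=True)
class BootstrapResult:
    """Per-parameter median and percentile 95% CI over resampled refits."""

    summary: pd.DataFrame = field(repr=False)  # index param, cols median/lo/hi
    replicates: pd.DataFrame = field(repr=False)
    n_requested: int
    n_converged: int

    def ci(self, param: str) -> tuple[float, float]:
        row = self.summary.loc[param]
        return float(row["ci_lo"]), float(row["ci_hi"])


def bootstrap(
    data: PKDataset,
    n_boot: int,
    seed: int,
    init: PopulationParams,
    config: ModelConfig = ModelConfig(),
    polish_maxfev: int = 150,
    lbfgs_maxiter: int = 40,
) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects with replacement, refit each.

    Replicate fits are warm-started from ``init`` (typically the original
    point estimates).  Replicates whose optimizer fails or returns a
    non-finite OFV are counted and excluded from the percentiles.
    """
    if data.n_subjects < 2:
        raise ValueError("bootstrap needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    ids = data.subject_ids
    rows = []
    n_conv = 0
    for b in range(n_boot):
        pick = [ids[k] for k in rng.integers(0, len(ids), size=len(ids))]
        sample = data.resample_subjects(pick)
        try:
            f = fit(sample, init, config, compute_se=False,
                    polish_maxfev=polish_maxfev, lbfgs_maxiter=lbfgs_maxiter)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not np.isfinite(f.ofv):
            continue
        n_conv += 1
        rows.append(f.params)
    if not rows:
        raise RuntimeError("all bootstrap replicates failed")
    reps = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "median": reps.median(),
            "ci_lo": reps.quantile(0.025),
            "ci_hi": reps.quantile(0.975),
        }
    )
    return BootstrapResult(
        summary=summary, replicates=reps, n_requested=n_boot, n_converged=n_conv
    )


# ---------------------------------------------------------------------------
# diagnostics


def cwres_and_gof(data: PKDataset, result: FitResult) -> pd.DataFrame:
    """Residual table: PRED, IPRED, IWRES and CWRES per usable observation.

    IWRES = (DV - IPRED) / (sigma * IPRED); CWRES standardizes
    ``DV - (f - G eta_hat)`` by the FOCE-linearized marginal covariance and
    is approximately standard normal under a correctly specified model.
    """
    config = result.config
    prep = _Prep(data, config)
    pop = result.estimates
    sigma2 = pop.sigma_prop**2
    omega = np.asarray(pop.omega) + 1e-10 * np.eye(3)
    eta = result.etas

    f, J = prep.predict_grad(pop.theta, eta, result.beta_sex, config.sex_covariate_on)
    pred = prep.predict(pop.theta, np.zeros_like(eta), result.beta_sex, config.sex_covariate_on)
    rows = []
    for i in range(prep.n):
        m = prep.mask[i]
        fc = np.maximum(f[i][m], _FLOOR)
        G = J[i][m]
        V = G @ omega @ G.T + np.diag(sigma2 * fc**2)
        e = (prep.dv[i] - f[i])[m] + G @ eta[i]
        L = np.linalg.cholesky(V)
        cwres = solve_triangular(L, e, lower=True)
        iwres = (prep.dv[i][m] - f[i][m]) / (pop.sigma_prop * fc)
        flagged = f[i][m] < _FLOOR
        for j, t in enumerate(prep.t[i][m]):
            rows.append(
                dict(
                    id=prep.ids[i], time=float(t), dv=float(prep.dv[i][m][j]),
                    pred=float(pred[i][m][j]), ipred=float(f[i][m][j]),
                    iwres=float(iwres[j]), cwres=float(cwres[j]), flagged=bool(flagged[j]),
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# visual predictive check


@dataclass(frozen=True)
class VPCResult:
    """Observed percentiles per time bin with simulated confidence bands."""

    bin_times: np.ndarray = field(repr=False)
    probs: tuple[float, ...]
    observed: pd.DataFrame = field(repr=False)  # index prob, columns bin time
    sim_lo: pd.DataFrame = field(repr=False)
    sim_hi: pd.DataFrame = field(repr=False)
    n_sim: int

    def coverage(self) -> float:
        """Fraction of (percentile, bin) cells with the observed curve inside
        its simulated 95% confidence band."""
        inside = (self.observed >= self.sim_lo) & (self.observed <= self.sim_hi)
        return float(inside.to_numpy().mean())


def vpc(
    data: PKDataset,
    pop: PopulationParams,
    n_sim: int = 1000,
    seed: int = 0,
    probs: tuple[float, ...] = (0.05, 0.50, 0.95),
    bin_decimals: int = 6,
) -> VPCResult:
    """Visual predictive check against ``n_sim`` model-simulated replicates.

    Observations are binned by nominal sampling time (one bin per distinct
    time).  Each replicate redraws subjects and residual error at the
    observed design; the 2.5th-97.5th percentile envelope of each simulated
    percentile forms the confidence band.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for stable confidence bands")
    obs = data.observations()
    times = obs["time"].round(bin_decimals).to_numpy()
    dv = obs["dv"].to_numpy(float)
    bins = np.unique(times)
    prep = _Prep(data, ModelConfig())
    rng = np.random.default_rng(seed)

    observed = np.array(
        [[np.quantile(dv[times == b], p) for b in bins] for p in probs]
    )
    sims = np.empty((n_sim, len(probs), bins.size))
    flat_mask = prep.mask
    obs_times_flat = prep.t[flat_mask].round(bin_decimals)
    for s in range(n_sim):
        individuals = sample_individuals(pop, prep.n, rng)
        eta = np.array([ind.eta for ind in individuals])
        f = prep.predict(pop.theta, eta, 0.0, None)
        sim_dv = np.clip(apply_residual_error(np.clip(f, 0, None), pop.sigma_prop, rng), 0, None)
        vals = sim_dv[flat_mask]
        for pi, p in enumerate(probs):
            sims[s, pi] = [np.quantile(vals[obs_times_flat == b], p) for b in bins]
    lo = np.quantile(sims, 0.025, axis=0)
    hi = np.quantile(sims, 0.975, axis=0)
    idx = pd.Index(list(probs), name="prob")
    cols = pd.Index(bins, name="time")
    return VPCResult(
        bin_times=bins, probs=tuple(probs),
        observed=pd.DataFrame(observed, index=idx, columns=cols),
        sim_lo=pd.DataFrame(lo, index=idx, columns=cols),
        sim_hi=pd.DataFrame(hi, index=idx, columns=cols),
        n_sim=n_sim,
    )
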