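"""Continuous-endpoint benchmark-dose analysis.

Fits continuous mean models to group summary statistics (n, mean, SD per
dose group) by maximum likelihood under a normal error model.  The
sufficient-statistic log-likelihood

    Σ_g [ −(n_g/2)·ln(2π σ_g²) − ((n_g−1)·s_g² + n_g·(m_g − μ_g)²)/(2 σ_g²) ]

equals the individual-data normal log-likelihood up to a data-independent
constant, so nothing is lost by modeling summaries.  The benchmark response
is either one (modeled) SD or a relative deviation from the control mean;
the BMDL is a one-sided 95% profile-likelihood bound obtained by pinning
the BMD with an equality constraint and bisecting the likelihood-ratio
cutoff, mirroring the quantal machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import chi2

from .datasets import BenchmarkResponse, ContinuousDataset
from .continuous_models import ContinuousModelSpec
from .quantal import BmdEstimate, NoBmdError, _multistart_maximize, _perturbed_starts

__all__ = ["ContinuousFit", "fit_continuous", "compute_bmd_continuous"]

_CHI2_DROP_95 = chi2.ppf(0.90, 1) / 2.0


@dataclass(frozen=True)
class ContinuousFit:
    """Maximum-likelihood fit of one continuous model to group summaries.

    ``theta_hat`` stacks the mean parameters, then the variance parameters:
    ln σ (constant) or (ln α, ρ) for σ² = α·μ^ρ.
    """

    spec: ContinuousModelSpec
    data: ContinuousDataset
    theta_hat: np.ndarray
    log_likelihood: float
    converged: bool

    @property
    def mean_params(self) -> np.ndarray:
        return self.theta_hat[: self.spec.n_mean_params]

    @property
    def sigma_hat(self) -> float:
        """Residual SD: constant-model σ, or the control-mean σ otherwise."""
        if self.spec.variance_model == "constant":
            return float(math.exp(self.theta_hat[-1]))
        ln_alpha, rho = self.theta_hat[-2:]
        mu0 = float(self.spec.mean(np.array([0.0]), self.mean_params)[0])
        return float(math.sqrt(math.exp(ln_alpha) * abs(mu0) ** rho))

    @property
    def n_params(self) -> int:
        return len(self.theta_hat)

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.n_params

    @property
    def fitted_means(self) -> np.ndarray:
        return self.spec.mean(np.array(self.data.doses), self.mean_params)


def _group_sigma2(spec: ContinuousModelSpec, mu: np.ndarray, var_params: np.ndarray):
    if spec.variance_model == "constant":
        return np.full_like(mu, math.exp(var_params[0]) ** 2)
    ln_alpha, rho = var_params
    return np.exp(ln_alpha) * np.abs(mu) ** rho


def _loglik_cont(spec: ContinuousModelSpec, data: ContinuousDataset, theta: np.ndarray) -> float:
    k = spec.n_mean_params
    mu = spec.mean(np.array(data.doses), theta[:k])
    sig2 = _group_sigma2(spec, mu, theta[k:])
    if np.any(~np.isfinite(mu)) or np.any(sig2 <= 0) or np.any(~np.isfinite(sig2)):
        return -1e12
    n = np.array(data.n_subjects, float)
    m = np.array(data.means)
    s = np.array(data.sds)
    ss = (n - 1) * s**2 + n * (m - mu) ** 2
    return float(np.sum(-0.5 * n * np.log(2.0 * math.pi * sig2) - ss / (2.0 * sig2)))


def individual_loglik_equivalent(data: ContinuousDataset, mu: np.ndarray, sig2: np.ndarray) -> float:
    """Reference form of the same likelihood (used by tests as an identity check)."""
    n = np.array(data.n_subjects, float)
    m = np.array(data.means)
    s = np.array(data.sds)
    ss = (n - 1) * s**2 + n * (m - mu) ** 2
    return float(np.sum(-0.5 * n * np.log(2.0 * math.pi * sig2) - ss / (2.0 * sig2)))


def _var_bounds(spec: ContinuousModelSpec, data: ContinuousDataset) -> list[tuple[float, float]]:
    s_typical = float(np.median(data.sds))
    if spec.variance_model == "constant":
        return [(math.log(s_typical) - 10.0, math.log(s_typical) + 10.0)]
    return [(2 * math.log(s_typical) - 20.0, 2 * math.log(s_typical) + 20.0), (-5.0, 5.0)]


def fit_continuous(
    data: ContinuousDataset,
    spec: ContinuousModelSpec,
    n_starts: int = 12,
    seed: int = 0,
) -> ContinuousFit:
    """Fit a continuous model to group summaries by maximum likelihood."""
    doses = np.array(data.doses)
    means = np.array(data.means)
    scale = float(max(np.max(np.abs(means)), np.max(data.sds), 1e-6))
    bounds = spec.mean_bounds(scale, float(doses.max())) + _var_bounds(spec, data)
    base_mean = spec.start_values(doses, means)
    if spec.variance_model == "constant":
        base_var = [math.log(float(np.sqrt(np.mean(np.array(data.sds) ** 2))))]
    else:
        base_var = [2 * math.log(float(np.median(data.sds))), 0.0]
    base = np.concatenate([base_mean, base_var])
    starts = _perturbed_starts(base, bounds, max(n_starts - 1, 0), seed)
    theta, ll, ok = _multistart_maximize(lambda t: _loglik_cont(spec, data, t), bounds, starts)
    res = minimize(
        lambda t: -_loglik_cont(spec, data, t),
        theta,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-12},
    )
    if np.isfinite(res.fun) and -res.fun >= ll:
        theta, ll = res.x, -res.fun
    return ContinuousFit(spec, data, theta, ll, ok and np.isfinite(ll))


def _bmr_target(fit_spec: ContinuousModelSpec, theta: np.ndarray, bmr: BenchmarkResponse) -> float:
    """The |μ(BMD) − μ(0)| change that defines the benchmark response."""
    k = fit_spec.n_mean_params
    mu0 = float(fit_spec.mean(np.array([0.0]), theta[:k])[0])
    if bmr.kind == "one_sd":
        if fit_spec.variance_model == "constant":
            return math.exp(theta[k])
        ln_alpha, rho = theta[k:]
        return math.sqrt(math.exp(ln_alpha) * abs(mu0) ** rho)
    if bmr.kind == "relative_deviation":
        return bmr.level * abs(mu0)
    raise NoBmdError(f"continuous BMD undefined for BMR kind {bmr.kind!r}")


def _bmd_from_theta(
    spec: ContinuousModelSpec, theta: np.ndarray, bmr: BenchmarkResponse, dose_max: float
) -> float:
    k = spec.n_mean_params
    target = _bmr_target(spec, theta, bmr)
    mu0 = float(spec.mean(np.array([0.0]), theta[:k])[0])

    def delta(d):
        return abs(float(spec.mean(np.array([d]), theta[:k])[0]) - mu0) - target

    hi = dose_max * 100.0
    if delta(hi) <= 0:
        raise NoBmdError("mean change never reaches the benchmark response")
    return float(brentq(delta, 0.0, hi, xtol=1e-12, rtol=1e-10))


def _profile_ll_at_bmd(
    fit: ContinuousFit, bmr: BenchmarkResponse, bmd0: float, warm: np.ndarray | None
) -> tuple[float, np.ndarray]:
    """Maximized log-likelihood subject to the BMD equaling ``bmd0``."""
    spec, data = fit.spec, fit.data
    doses = np.array(data.doses)
    scale = float(max(np.max(np.abs(data.means)), np.max(data.sds), 1e-6))
    bounds = spec.mean_bounds(scale, float(doses.max())) + _var_bounds(spec, data)
    k = spec.n_mean_params

    def constraint(theta):
        mu0 = float(spec.mean(np.array([0.0]), theta[:k])[0])
        mub = float(spec.mean(np.array([bmd0]), theta[:k])[0])
        return abs(mub - mu0) - _bmr_target(spec, theta, bmr)

    x0 = warm if warm is not None else fit.theta_hat
    best_ll, best_x = -np.inf, x0
    for fscale in (1.0, 0.95, 1.05):
        try:
            res = minimize(
                lambda t: -_loglik_cont(spec, data, t),
                x0 * fscale,
                method="SLSQP",
                bounds=bounds,
                constraints=[{"type": "eq", "fun": constraint}],
                options={"maxiter": 300, "ftol": 1e-10},
            )
        except (ValueError, FloatingPointError):
            continue
        if res.success and abs(constraint(res.x)) < 1e-6 * max(1.0, scale):
            ll = -res.fun
            if ll > best_ll:
                best_ll, best_x = ll, res.x
    return best_ll, best_x


def compute_bmd_continuous(
    fit: ContinuousFit,
    bmr: BenchmarkResponse,
    confidence_level: float = 0.95,
    compute_lower: bool = True,
) -> BmdEstimate:
    """BMD (and profile-likelihood BMDL) for a 1-SD or relative-deviation BMR."""
    if not fit.converged:
        raise NoBmdError("fit did not converge")
    dose_max = float(max(fit.data.doses))
    bmd = _bmd_from_theta(fit.spec, fit.theta_hat, bmr, dose_max)
    if not compute_lower:
        return BmdEstimate(bmr, bmd, bmd, confidence_level, fit.spec.name)
    drop = chi2.ppf(1.0 - 2.0 * (1.0 - confidence_level), 1) / 2.0
    target_ll = fit.log_likelihood - drop
    warm = None
    b, lo, hi = bmd, None, bmd
    at_floor = False
    for _ in range(40):
        b *= 0.6
        if b < bmd * 1e-6:
            at_floor = True
            break
        ll, warm = _profile_ll_at_bmd(fit, bmr, b, warm)
        if ll < target_ll:
            lo = b
            break
        hi = b
    if at_floor or lo is None:
        return BmdEstimate(bmr, bmd, bmd * 1e-6, confidence_level, fit.spec.name, True)

    cache = {"w": warm}

    def h(logb):
        ll, w = _profile_ll_at_bmd(fit, bmr, math.exp(logb), cache["w"])
        cache["w"] = w
        return ll - target_ll

    logb = brentq(h, math.log(lo), math.log(hi), xtol=1e-4)
    bmdl = min(math.exp(logb), bmd)
    return BmdEstimate(bmr, bmd, bmdl, confidence_level, fit.spec.name)
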