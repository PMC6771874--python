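"""Bayesian model averaging over the dichotomous suite.

Each suite model is given independent priors on its parameters, stated on a
transformed scale where they are Normal: logit scale for probabilities
(background, Hill plateau fraction), log scale for slopes and powers
(lognormal priors), identity for intercepts.  A maximum-a-posteriori fit in
the transformed space plus a Laplace approximation of the marginal
likelihood yields posterior model weights; the model-averaged BMD posterior
is then sampled from the mixture of per-model Laplace Gaussians.

The default prior parameters live in a versioned YAML config
(``data/priors_default.yaml``) so they can be revised without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import minimize

from .datasets import BenchmarkResponse, QuantalDataset
from .quantal import _loglik, _multistart_maximize, _perturbed_starts
from .quantal_models import QuantalModelSpec

__all__ = [
    "ParameterPrior",
    "BayesianQuantalFit",
    "MaBmdResult",
    "default_priors",
    "load_priors",
    "fit_bayesian",
    "fit_bayesian_suite",
    "model_average_bmd",
]

# scales on which each parameter kind is given a Normal prior
_SCALE_FOR_PARAM = {
    "background": "logit",
    "max_fraction": "logit",
    "intercept": "identity",
    "slope": "log",
    "power": "log",
}

_PHI_LIMIT = 25.0  # transformed-scale box to keep the optimizer finite


@dataclass(frozen=True)
class ParameterPrior:
    """Normal prior on a transformed parameter scale.

    ``scale='logit'`` means logit(θ) ~ N(mu, sigma) (a logistic-normal prior
    on the probability), ``'log'`` means θ is lognormal, ``'identity'`` a
    plain Normal.
    """

    scale: str
    mu: float
    sigma: float

    def logpdf(self, phi: float) -> float:
        z = (phi - self.mu) / self.sigma
        return -0.5 * z * z - math.log(self.sigma) - 0.5 * math.log(2.0 * math.pi)


def _param_kind(name: str) -> str:
    if name.startswith("beta"):
        return "slope"
    return name


def _transform(theta: np.ndarray, scales: list[str]) -> np.ndarray:
    out = np.empty_like(theta)
    for i, (v, s) in enumerate(zip(theta, scales)):
        if s == "logit":
            v = min(max(v, 1e-10), 1 - 1e-10)
            out[i] = math.log(v / (1 - v))
        elif s == "log":
            out[i] = math.log(max(v, 1e-12))
        else:
            out[i] = v
    return out


def _untransform(phi: np.ndarray, scales: list[str]) -> np.ndarray:
    out = np.empty_like(phi)
    for i, (v, s) in enumerate(zip(phi, scales)):
        if s == "logit":
            out[i] = 1.0 / (1.0 + math.exp(-v))
        elif s == "log":
            out[i] = math.exp(v)
        else:
            out[i] = v
    return out


def load_priors(path: str | Path) -> dict[str, list[ParameterPrior]]:
    """Read a per-model prior table from YAML."""
    raw = yaml.safe_load(Path(path).read_text())
    table = {}
    for model, entries in raw["priors"].items():
        table[model] = [
            ParameterPrior(e["scale"], float(e["mu"]), float(e["sigma"])) for e in entries
        ]
    return table


def default_priors() -> dict[str, list[ParameterPrior]]:
    """The packaged default prior table for the Bayesian suite."""
    ref = resources.files("bmdtox.data").joinpath("priors_default.yaml")
    with resources.as_file(ref) as path:
        return load_priors(path)


@dataclass(frozen=True)
class BayesianQuantalFit:
    """MAP fit and Laplace evidence of one model under its priors."""

    spec: QuantalModelSpec
    data: QuantalDataset
    priors: tuple[ParameterPrior, ...]
    map_theta: np.ndarray          # natural scale
    map_phi: np.ndarray            # transformed scale
    phi_cov: np.ndarray            # Laplace covariance in transformed space
    log_posterior_at_map: float
    laplace_log_marginal: float
    hessian_singular: bool
    posterior_weight: float = float("nan")  # filled by fit_bayesian_suite

    @property
    def scales(self) -> list[str]:
        return [_SCALE_FOR_PARAM[_param_kind(n)] for n in self.spec.param_names]


def _phi_bounds(spec: QuantalModelSpec, scales: list[str]) -> list[tuple[float, float]]:
    out = []
    for (lo, hi), s in zip(spec.bounds(), scales):
        if s == "logit":
            out.append((-_PHI_LIMIT, _PHI_LIMIT))
        elif s == "log":
            out.append((math.log(max(lo, 1e-10)), math.log(hi)))
        else:
            out.append((lo, hi))
    return out


def _num_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar f at x."""
    k = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [h[i], h[j]]
                xpm[[i, j]] += [h[i], -h[j]]
                xmp[[i, j]] += [-h[i], h[j]]
                xmm[[i, j]] += [-h[i], -h[j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4.0 * h[i] * h[j])
    return H


def fit_bayesian(
    data: QuantalDataset,
    spec: QuantalModelSpec,
    priors: list[ParameterPrior],
    n_starts: int = 10,
    seed: int = 0,
) -> BayesianQuantalFit:
    """MAP fit plus Laplace-approximated log marginal likelihood.

    The marginal likelihood uses the standard Laplace formula
    log m = log p(data, θ_MAP) + (k/2)·log 2π − ½·log det H, with H the
    negative Hessian of the log posterior in the transformed space.  A
    singular Hessian falls back to the pseudo-determinant and is flagged.
    """
    scales = [_SCALE_FOR_PARAM[_param_kind(n)] for n in spec.param_names]
    if len(priors) != len(scales):
        raise ValueError(
            f"{spec.name}: {len(priors)} priors given for {len(scales)} parameters"
        )
    bounds = _phi_bounds(spec, scales)

    def logpost(phi: np.ndarray) -> float:
        theta = _untransform(phi, scales)
        ll = _loglik(spec, data, theta)
        lp = sum(pr.logpdf(p) for pr, p in zip(priors, phi))
        return ll + lp

    doses = np.array(data.doses)
    props = np.array(data.proportions)
    base_phi = _transform(spec.start_values(doses, props), scales)
    prior_phi = np.array([pr.mu for pr in priors])
    starts = [base_phi, prior_phi]
    pos = doses[doses > 0]
    for ed in np.geomspace(pos.min() / 3.0, pos.max() * 3.0, 5):
        starts.append(_transform(spec.start_values(doses, props, ed=ed), scales))
    starts.extend(_perturbed_starts(base_phi, bounds, n_starts - 2, seed)[1:])
    phi_map, lp_map, _ = _multistart_maximize(logpost, bounds, starts)
    res = minimize(
        lambda p: -logpost(p), phi_map, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-12},
    )
    if np.isfinite(res.fun) and -res.fun >= lp_map:
        phi_map, lp_map = res.x, -res.fun

    H = -_num_hessian(logpost, phi_map)
    k = len(phi_map)
    # symmetrize and check conditioning
    H = 0.5 * (H + H.T)
    eigvals, eigvecs = np.linalg.eigh(H)
    singular = bool(np.any(eigvals <= 1e-10))
    pos_eigs = np.where(eigvals > 1e-10, eigvals, np.nan)
    if singular:
        good = eigvals[eigvals > 1e-10]
        logdet = float(np.sum(np.log(good)))
        inv_eigs = np.where(eigvals > 1e-10, 1.0 / np.where(eigvals > 1e-10, eigvals, 1.0), 0.0)
    else:
        logdet = float(np.sum(np.log(eigvals)))
        inv_eigs = 1.0 / eigvals
    cov = (eigvecs * inv_eigs) @ eigvecs.T
    log_marg = lp_map + 0.5 * k * math.log(2.0 * math.pi) - 0.5 * logdet
    return BayesianQuantalFit(
        spec=spec,
        data=data,
        priors=tuple(priors),
        map_theta=_untransform(phi_map, scales),
        map_phi=phi_map,
        phi_cov=cov,
        log_posterior_at_map=lp_map,
        laplace_log_marginal=log_marg,
        hessian_singular=singular,
    )


def fit_bayesian_suite(
    data: QuantalDataset,
    priors: dict[str, list[ParameterPrior]] | None = None,
    seed: int = 0,
) -> list[BayesianQuantalFit]:
    """Fit every model in the prior table and attach normalized weights."""
    priors = priors or default_priors()
    fits = []
    for name, model_priors in priors.items():
        spec = QuantalModelSpec(name, restricted=False)
        fits.append(fit_bayesian(data, spec, model_priors, seed=seed))
    logm = np.array([f.laplace_log_marginal for f in fits])
    w = np.exp(logm - logm.max())
    w /= w.sum()
    return [
        BayesianQuantalFit(
            spec=f.spec, data=f.data, priors=f.priors, map_theta=f.map_theta,
            map_phi=f.map_phi, phi_cov=f.phi_cov,
            log_posterior_at_map=f.log_posterior_at_map,
            laplace_log_marginal=f.laplace_log_marginal,
            hessian_singular=f.hessian_singular, posterior_weight=float(wi),
        )
        for f, wi in zip(fits, w)
    ]


@dataclass(frozen=True)
class MaBmdResult:
    """Model-averaged BMD posterior summary.

    ``bmd_ma`` is the posterior median, ``bmdl_ma`` the 5th percentile
    (a one-sided 95% lower bound).
    """

    bmd_ma: float
    bmdl_ma: float
    n_draws: int
    seed: int
    censored_fraction: float
    weights: dict[str, float]
    samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.bmdl_ma > self.bmd_ma:
            raise ValueError("BMDL_MA above BMD_MA")


def model_average_bmd(
    fits: list[BayesianQuantalFit],
    bmr: BenchmarkResponse,
    n_draws: int = 100_000,
    seed: int = 0,
    keep_samples: bool = False,
) -> MaBmdResult:
    """Sample the model-averaged BMD posterior from the Laplace mixture.

    A model is drawn per sample according to its posterior weight, parameters
    from that model's Laplace Gaussian (on the transformed scale, truncated to
    the constraint box by resampling), and the draw's BMD computed.  Draws for
    which the BMR is unattainable contribute a censored value at the search
    ceiling (100 × the highest tested dose); more than 20% censored draws is
    an error.
    """
    if bmr.kind != "extra_risk":
        raise ValueError("model averaging is defined here for extra-risk BMRs")
    if n_draws < 10_000:
        raise ValueError("n_draws must be at least 10000 for stable percentiles")
    weights = np.array([f.posterior_weight for f in fits])
    if not np.isfinite(weights).all() or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("posterior weights must be computed and sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_draws, weights)
    ceiling = 100.0 * max(fits[0].data.doses)
    draws = np.empty(n_draws)
    pos = 0
    n_censored = 0
    for fit, m in zip(fits, counts):
        if m == 0:
            continue
        scales = fit.scales
        bounds = np.array(_phi_bounds(fit.spec, scales))
        cov = 0.5 * (fit.phi_cov + fit.phi_cov.T)
        try:
            chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
        except np.linalg.LinAlgError:
            eigvals, eigvecs = np.linalg.eigh(cov)
            chol = eigvecs * np.sqrt(np.maximum(eigvals, 0.0))
        phis = fit.map_phi + rng.standard_normal((m, len(cov))) @ chol.T
        phis = np.clip(phis, bounds[:, 0], bounds[:, 1])
        for phi in phis:
            theta = _untransform(phi, scales)
            try:
                b = fit.spec.bmd(theta, bmr.level)
            except ValueError:
                b = ceiling
                n_censored += 1
            draws[pos] = min(b, ceiling)
            pos += 1
    draws = draws[:pos]
    frac_censored = n_censored / len(draws)
    if frac_censored > 0.20:
        raise RuntimeError(
            f"{frac_censored:.0%} of posterior draws cannot attain the BMR; "
            "the model-averaged BMD is not identifiable at this response level"
        )
    bmd_ma = float(np.median(draws))
    bmdl_ma = float(np.percentile(draws, 5.0))
    return MaBmdResult(
        bmd_ma=bmd_ma,
        bmdl_ma=bmdl_ma,
        n_draws=len(draws),
        seed=seed,
        censored_fraction=float(frac_censored),
        weights={f.spec.name: f.posterior_weight for f in fits},
        samples=draws if keep_samples else None,
    )
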