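"""Probabilistic reference-dose derivation by lognormal factor propagation.

The animal benchmark dose is treated as a lognormal random variable AD_M
whose median is the BMD and whose 5th percentile is the BMDL.  Dividing by
independent lognormal adjustment factors — allometric body-weight scaling
(AF_BW), residual interspecies toxicokinetics/toxicodynamics (AF_TK/TD),
and human variability between the median and the most-sensitive I% of the
population (AF_H^I) — yields the human-dose distributions

    HD_M^50% = AD_M / (AF_BW × AF_TK/TD)
    HD_M^I   = HD_M^50% / AF_H^I

The probabilistic RfD is the 5th percentile of HD_M^I, optionally divided
by a deterministic database uncertainty factor UF_D applied after the
percentile.  Because a quotient of independent lognormals is lognormal,
every percentile has a closed form; a Monte Carlo evaluator with a fixed
seed is provided as a cross-check and for reporting draws.

Default adjustment-factor parameters live in ``data/aprob_defaults.yaml``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import norm

__all__ = [
    "LognormalUncertain",
    "ProbabilisticChain",
    "PrfdResult",
    "Z95",
    "ad_from_bmd",
    "default_af_config",
    "load_af_config",
    "default_chain",
    "propagate",
    "variance_budget",
]

Z95 = float(norm.ppf(0.95))  # 1.6449: the z-score behind P95/P50 ratios

_PERCENTILES = (1.0, 5.0, 25.0, 50.0, 75.0, 95.0, 99.0)


@dataclass(frozen=True)
class LognormalUncertain:
    """A lognormal random variable stated as (median, P95/P50 ratio).

    sigma_ln = ln(p95/p50)/1.6449; a ratio of 1 is a degenerate point mass.
    """

    p50: float
    p95_over_p50: float = 1.0

    def __post_init__(self) -> None:
        if self.p50 <= 0:
            raise ValueError("median must be positive")
        if self.p95_over_p50 < 1.0:
            raise ValueError("P95/P50 ratio must be >= 1")

    @property
    def mu_ln(self) -> float:
        return math.log(self.p50)

    @property
    def sigma_ln(self) -> float:
        return math.log(self.p95_over_p50) / Z95

    def percentile(self, q: float) -> float:
        return math.exp(self.mu_ln + norm.ppf(q / 100.0) * self.sigma_ln)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sigma_ln == 0.0:
            return np.full(n, self.p50)
        return rng.lognormal(self.mu_ln, self.sigma_ln, n)


def ad_from_bmd(bmd: float, bmdl: float) -> LognormalUncertain:
    """Animal-dose uncertainty distribution from a (BMD, BMDL) pair.

    Lognormal with median = BMD and 5th percentile = BMDL, i.e.
    sigma_ln = ln(BMD/BMDL)/1.6449.
    """
    if not (0 < bmdl <= bmd):
        raise ValueError(f"require 0 < BMDL <= BMD, got ({bmd}, {bmdl})")
    return LognormalUncertain(p50=bmd, p95_over_p50=(bmd / bmdl))


@dataclass(frozen=True)
class ProbabilisticChain:
    """The full adjustment chain from animal BMD to probabilistic RfD."""

    ad: LognormalUncertain
    af_bw: LognormalUncertain
    af_tktd: LognormalUncertain
    af_h: LognormalUncertain
    target_incidence: float = 0.01
    uf_d: float = 1.0
    n_samples: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        # I = 0.5 is the degenerate median-human convention: AF_H collapses
        # to a point mass and HD_M^I coincides with HD_M^50%.
        if not (0.0 < self.target_incidence <= 0.5):
            raise ValueError("target incidence must be in (0, 0.5]")
        if self.target_incidence == 0.5 and (
            self.af_h.p50 != 1.0 or self.af_h.p95_over_p50 != 1.0
        ):
            raise ValueError("at I = 50% the human-variability factor must be degenerate at 1")
        if self.uf_d < 1.0:
            raise ValueError("UF_D must be >= 1")
        if self.n_samples < 10_000:
            raise ValueError("n_samples must be at least 10000")


@dataclass(frozen=True)
class PrfdResult:
    """Percentile tables and the pRfD from both evaluators."""

    hd50_percentiles: dict[float, float]
    hd_i_percentiles: dict[float, float]
    target_incidence: float
    uf_d: float
    prfd_raw: float            # closed form: P5 of HD_M^I / UF_D
    prfd_reported: float       # one significant figure
    prfd_raw_mc: float         # Monte Carlo evaluator
    hd_i_p5_closed: float
    hd_i_p5_mc: float
    variance_budget: dict[str, float]
    n_samples: int
    seed: int


def load_af_config(path: str | Path) -> dict:
    """Read adjustment-factor defaults from YAML."""
    return yaml.safe_load(Path(path).read_text())


def default_af_config() -> dict:
    ref = resources.files("bmdtox.data").joinpath("aprob_defaults.yaml")
    with resources.as_file(ref) as path:
        return load_af_config(path)


def _af_bw_from_config(cfg: dict, animal_bw: float, human_bw: float) -> LognormalUncertain:
    ex = cfg["af_bw"]["exponent"]
    ex_sd = cfg["af_bw"]["exponent_sd"]
    ratio = human_bw / animal_bw
    p50 = ratio**ex
    p95_over_p50 = ratio ** (Z95 * ex_sd)
    return LognormalUncertain(p50=p50, p95_over_p50=p95_over_p50)


def default_chain(
    bmd: float,
    bmdl: float,
    animal_bw: float,
    human_bw: float = 70.0,
    target_incidence: float = 0.01,
    uf_d: float = 1.0,
    config: dict | None = None,
    n_samples: int = 100_000,
    seed: int = 0,
) -> ProbabilisticChain:
    """Build the chain from a (BMD, BMDL) pair and the packaged AF defaults.

    The AF_BW median is (human_bw/animal_bw)^exponent with the allometric
    dose exponent and its uncertainty taken from the config; AF_TK/TD and
    AF_H^I are read directly as (median, P95/P50) pairs.
    """
    cfg = config or default_af_config()
    af_h_cfg = cfg["af_h"]["by_incidence"]
    if target_incidence == 0.5:
        af_h = LognormalUncertain(1.0, 1.0)  # median-human convention
    else:
        key = f"{target_incidence:g}"
        if key not in af_h_cfg:
            raise KeyError(
                f"no AF_H parameters for target incidence {key}; "
                f"configured: {sorted(af_h_cfg)}"
            )
        af_h = LognormalUncertain(af_h_cfg[key]["p50"], af_h_cfg[key]["p95_over_p50"])
    return ProbabilisticChain(
        ad=ad_from_bmd(bmd, bmdl),
        af_bw=_af_bw_from_config(cfg, animal_bw, human_bw),
        af_tktd=LognormalUncertain(
            cfg["af_tktd"]["p50"], cfg["af_tktd"]["p95_over_p50"]
        ),
        af_h=af_h,
        target_incidence=target_incidence,
        uf_d=uf_d,
        n_samples=n_samples,
        seed=seed,
    )


def _quotient_lognormal(chain: ProbabilisticChain, include_af_h: bool) -> tuple[float, float]:
    """(mu, sigma) of ln HD: quotient of independent lognormals is lognormal."""
    mu = chain.ad.mu_ln - chain.af_bw.mu_ln - chain.af_tktd.mu_ln
    var = chain.ad.sigma_ln**2 + chain.af_bw.sigma_ln**2 + chain.af_tktd.sigma_ln**2
    if include_af_h:
        mu -= chain.af_h.mu_ln
        var += chain.af_h.sigma_ln**2
    return mu, math.sqrt(var)


def propagate(chain: ProbabilisticChain) -> PrfdResult:
    """Evaluate the chain by closed form and Monte Carlo (both reported).

    The closed form uses the lognormal quotient algebra; the Monte Carlo
    evaluator draws all factors independently under the chain's seed.  The
    deterministic UF_D divides the 5th percentile, after the probabilistic
    part, and the reported pRfD is rounded to one significant figure.
    """
    mu50, sig50 = _quotient_lognormal(chain, include_af_h=False)
    mu_i, sig_i = _quotient_lognormal(chain, include_af_h=True)
    hd50_pct = {q: math.exp(mu50 + norm.ppf(q / 100.0) * sig50) for q in _PERCENTILES}
    hd_i_pct = {q: math.exp(mu_i + norm.ppf(q / 100.0) * sig_i) for q in _PERCENTILES}
    p5_closed = math.exp(mu_i + norm.ppf(0.05) * sig_i)

    rng = np.random.default_rng(chain.seed)
    n = chain.n_samples
    hd_i_samples = chain.ad.sample(rng, n) / (
        chain.af_bw.sample(rng, n) * chain.af_tktd.sample(rng, n) * chain.af_h.sample(rng, n)
    )
    p5_mc = float(np.percentile(hd_i_samples, 5.0))

    prfd_raw = p5_closed / chain.uf_d
    return PrfdResult(
        hd50_percentiles=hd50_pct,
        hd_i_percentiles=hd_i_pct,
        target_incidence=chain.target_incidence,
        uf_d=chain.uf_d,
        prfd_raw=prfd_raw,
        prfd_reported=_round_1sf(prfd_raw),
        prfd_raw_mc=p5_mc / chain.uf_d,
        hd_i_p5_closed=p5_closed,
        hd_i_p5_mc=p5_mc,
        variance_budget=variance_budget(chain),
        n_samples=n,
        seed=chain.seed,
    )


def variance_budget(chain: ProbabilisticChain) -> dict[str, float]:
    """Share of ln-scale variance contributed by each uncertain factor.

    Shares sum to 1; an all-degenerate chain has no budget and returns NaNs.
    """
    comps = {
        "ad": chain.ad.sigma_ln**2,
        "af_bw": chain.af_bw.sigma_ln**2,
        "af_tktd": chain.af_tktd.sigma_ln**2,
        "af_h": chain.af_h.sigma_ln**2,
    }
    total = sum(comps.values())
    if total == 0.0:
        return {k: float("nan") for k in comps}
    return {k: v / total for k, v in comps.items()}


def _round_1sf(x: float) -> float:
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp)
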