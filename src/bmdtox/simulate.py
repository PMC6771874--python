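"""Synthetic dose-response data with known truth.

Quantal replicates draw group incidences binomially from a chosen
dose-response curve; continuous replicates draw per-subject normal responses
around a chosen mean function and reduce them to group summaries (n, mean,
SD).  A single seeded generator makes every replicate reproducible, which is
what the parameter-recovery, coverage and goodness-of-fit-calibration
studies in the test-suite rely on.

``table1_like_design`` mirrors the chronic-bioassay layout behind the
packaged fixtures — four dose groups (0, 0.1, 1, 50 mg/kg/day) of 70
animals — with model parameters chosen so the expected incidences match the
observed fixture proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datasets import ContinuousDataset, QuantalDataset, builtin_fixture
from .continuous_models import ContinuousModelSpec
from .quantal_models import QuantalModelSpec

__all__ = ["SimulationDesign", "simulate_quantal", "simulate_continuous", "table1_like_design"]


@dataclass(frozen=True)
class SimulationDesign:
    """A repeatable simulation scenario: model, truth, layout, seed."""

    model: QuantalModelSpec | ContinuousModelSpec
    true_params: tuple[float, ...]
    doses: tuple[float, ...]
    n_per_group: int
    n_replicates: int = 1
    seed: int = 0
    sigma: float | None = None  # continuous only: residual SD

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def simulate_quantal(design: SimulationDesign) -> list[QuantalDataset]:
    """Binomial replicates from P(d; true_params)."""
    if not isinstance(design.model, QuantalModelSpec):
        raise TypeError("simulate_quantal needs a quantal model spec")
    doses = np.asarray(design.doses, float)
    p = design.model.prob(doses, np.asarray(design.true_params, float))
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError(f"true parameters give probabilities outside [0, 1]: {p}")
    rng = np.random.default_rng(design.seed)
    out = []
    for r in range(design.n_replicates):
        x = rng.binomial(design.n_per_group, p)
        groups = tuple((float(d), design.n_per_group, int(xi)) for d, xi in zip(doses, x))
        out.append(QuantalDataset(f"{design.model.name}_sim_{r}", groups))
    return out


def simulate_continuous(design: SimulationDesign) -> list[ContinuousDataset]:
    """Normal replicates around μ(d; true_params), reduced to group summaries."""
    if not isinstance(design.model, ContinuousModelSpec):
        raise TypeError("simulate_continuous needs a continuous model spec")
    if design.sigma is None or design.sigma <= 0:
        raise ValueError("continuous designs need sigma > 0")
    if design.n_per_group < 2:
        raise ValueError("continuous groups need n >= 2 to have an SD")
    doses = np.asarray(design.doses, float)
    mu = design.model.mean(doses, np.asarray(design.true_params, float))
    rng = np.random.default_rng(design.seed)
    out = []
    for r in range(design.n_replicates):
        groups = []
        for d, m in zip(doses, mu):
            y = rng.normal(m, design.sigma, design.n_per_group)
            groups.append((float(d), design.n_per_group, float(y.mean()), float(y.std(ddof=1))))
        direction = "decrease" if mu[-1] < mu[0] else "increase"
        out.append(
            ContinuousDataset(f"{design.model.name}_sim_{r}", tuple(groups), direction)
        )
    return out


def table1_like_design(
    endpoint: str,
    n_replicates: int = 1,
    seed: int = 0,
    n_per_group: int = 70,
    model_name: str = "log_logistic",
) -> SimulationDesign:
    """A chronic-bioassay-layout design whose expectation matches a fixture.

    Anchors the curve at the fixture's control and high-dose proportions
    (the two informative anchors of the four-group design), so expected
    incidences approximate the observed ones.  ``model_name`` selects the
    truth curve: ``log_logistic`` (slope 1.3) or ``quantal_linear`` — the
    two-parameter curve is fully identified by this sparse layout and is the
    right truth for consistency/stability studies, while the log-logistic
    exercises the shape machinery.
    """
    data = builtin_fixture(endpoint)
    props = np.array(data.proportions)
    doses = data.doses
    g = float(np.clip(props[0], 1e-3, 0.98))
    top = float(np.clip(props[-1], g + 5e-3, 0.995))
    er_top = (top - g) / (1.0 - g)  # extra risk at the top dose
    if model_name == "quantal_linear":
        b = float(-np.log1p(-er_top) / doses[-1])
        model = QuantalModelSpec("quantal_linear")
        params: tuple[float, ...] = (g, b)
    elif model_name == "log_logistic":
        beta = 1.3
        alpha = float(np.log(er_top / (1 - er_top)) - beta * np.log(doses[-1]))
        model = QuantalModelSpec("log_logistic")
        params = (g, alpha, beta)
    else:
        raise ValueError("model_name must be log_logistic or quantal_linear")
    return SimulationDesign(
        model=model,
        true_params=params,
        doses=doses,
        n_per_group=n_per_group,
        n_replicates=n_replicates,
        seed=seed,
    )
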