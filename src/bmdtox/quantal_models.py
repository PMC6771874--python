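"""The standard dichotomous dose-response model suite.

Nine models, each defining a response probability P(d; θ) that is
non-decreasing in dose under the default ("restricted") constraints.  The
background-multiplied models share the form P(d) = γ + (1 − γ)·F(d) with
F(0) = 0, so their extra risk [P(d) − P(0)]/[1 − P(0)] reduces to F(d) and
the BMD at extra risk A solves F(d) = A in closed form.  The logistic and
probit models have no explicit background parameter; their extra risk is
evaluated from P directly.

Restricted defaults bound the power/slope parameters at ≥ 1, preventing
supralinear (infinite-slope-at-zero) low-dose behavior; pass
``restricted=False`` for the unrestricted variants.

Each model also knows how to rebuild its full parameter vector from a fixed
BMD plus the remaining free parameters (``from_profile``), which is what the
profile-likelihood BMDL computation optimizes over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import special
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = ["QuantalModelSpec", "get_model", "suite", "SUITE_NAMES"]

_BIG_SLOPE = 1e4
_POWER_MAX = 18.0  # conventional upper bound for shape/power parameters


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


@dataclass(frozen=True)
class QuantalModelSpec:
    """A dichotomous model plus its parameter constraints.

    name
        One of logistic, log_logistic, probit, log_probit, gamma, weibull,
        multistage_k, quantal_linear, dichotomous_hill.  ``multistage_k``
        takes a polynomial ``degree``.
    restricted
        If True (default), power/slope parameters are bounded below at 1.
    """

    name: str
    restricted: bool = True
    degree: int = 2  # multistage only

    def __post_init__(self) -> None:
        if self.name not in _MODELS:
            raise ValueError(f"unknown quantal model {self.name!r}; known: {sorted(_MODELS)}")
        if self.name == "multistage_k" and self.degree < 1:
            raise ValueError("multistage degree must be >= 1")

    @property
    def label(self) -> str:
        if self.name == "multistage_k":
            return f"multistage (degree {self.degree})"
        return self.name.replace("_", " ")

    # -- delegation to the model implementation ---------------------------

    def _impl(self) -> "_Model":
        return _MODELS[self.name]

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.name == "multistage_k":
            return ("background",) + tuple(f"beta{i}" for i in range(1, self.degree + 1))
        return self._impl().param_names

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def bounds(self) -> list[tuple[float, float]]:
        return self._impl().bounds(self)

    def prob(self, dose, theta) -> np.ndarray:
        """Response probability P(dose; θ), vectorized over dose."""
        dose = np.asarray(dose, dtype=float)
        return np.clip(self._impl().prob(self, dose, np.asarray(theta, float)), 0.0, 1.0)

    def background(self, theta) -> float:
        """P(0; θ)."""
        return float(self.prob(np.array([0.0]), theta)[0])

    def extra_risk(self, theta, dose) -> np.ndarray:
        """Background-corrected risk [P(d) − P(0)]/[1 − P(0)]."""
        p0 = self.background(theta)
        if p0 >= 1.0 - 1e-12:
            raise ValueError("background response is 1; extra risk undefined")
        p = self.prob(dose, theta)
        return np.clip((p - p0) / (1.0 - p0), 0.0, 1.0)

    def bmd(self, theta, bmr_level: float) -> float:
        """Dose at which extra risk equals ``bmr_level`` (may raise ValueError)."""
        return self._impl().bmd(self, np.asarray(theta, float), float(bmr_level))

    def added_risk_bmd(self, theta, bmr_level: float) -> float:
        """Dose where P(d) − P(0) = level, by bracketed root-finding."""
        p0 = self.background(theta)
        if p0 + bmr_level >= 1.0:
            raise ValueError("added risk level unattainable (background too high)")
        # equivalent extra-risk level
        return self.bmd(theta, bmr_level / (1.0 - p0))

    # -- BMD-fixed reparameterization for profile likelihood --------------

    def profile_free_names(self) -> tuple[str, ...]:
        return self._impl().profile_free_names(self)

    def profile_free_bounds(self, bmr_level: float) -> list[tuple[float, float]]:
        return self._impl().profile_free_bounds(self, bmr_level)

    def from_profile(self, bmd: float, free: np.ndarray, bmr_level: float) -> np.ndarray | None:
        """Full θ with extra_risk(bmd) = bmr_level, or None if infeasible."""
        return self._impl().from_profile(self, float(bmd), np.asarray(free, float), bmr_level)

    def profile_free_from_theta(self, theta: np.ndarray) -> np.ndarray:
        return self._impl().profile_free_from_theta(self, np.asarray(theta, float))

    def start_values(self, doses, props, ed: float | None = None) -> np.ndarray:
        """Heuristic starting values from observed proportions.

        ``ed`` optionally overrides the rough half-maximal-dose guess; the
        fitter scans it over the positive doses for multi-start coverage.
        """
        return self._impl().start_values(
            self, np.asarray(doses, float), np.asarray(props, float), ed
        )


class _Model:
    param_names: tuple[str, ...] = ()

    def bounds(self, spec: QuantalModelSpec) -> list[tuple[float, float]]:
        raise NotImplementedError

    def prob(self, spec, dose, theta):
        raise NotImplementedError

    def bmd(self, spec, theta, a):
        raise NotImplementedError

    def profile_free_names(self, spec):
        raise NotImplementedError

    def profile_free_bounds(self, spec, a):
        raise NotImplementedError

    def from_profile(self, spec, bmd, free, a):
        raise NotImplementedError

    def profile_free_from_theta(self, spec, theta):
        raise NotImplementedError

    def start_values(self, spec, doses, props, ed=None):
        raise NotImplementedError


def _safe_log(d: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(d)


def _background_start(props: np.ndarray) -> float:
    return float(np.clip(props[0], 1e-3, 0.99))


def _ed50_start(doses: np.ndarray, props: np.ndarray) -> float:
    """Rough dose at half-maximal observed extra risk."""
    pos = doses[doses > 0]
    p0, pmax = props[0], props.max()
    if pmax <= p0 + 1e-9:
        return float(np.median(pos))
    target = p0 + 0.5 * (pmax - p0)
    idx = int(np.argmin(np.abs(props - target)))
    d = doses[idx]
    return float(d if d > 0 else np.median(pos))


class _QuantalLinear(_Model):
    # P = γ + (1 − γ)(1 − exp(−β d))
    param_names = ("background", "slope")

    def bounds(self, spec):
        return [(0.0, 1.0), (0.0, _BIG_SLOPE)]

    def prob(self, spec, dose, theta):
        g, b = theta
        return g + (1.0 - g) * (-np.expm1(-b * dose))

    def bmd(self, spec, theta, a):
        b = theta[1]
        if b <= 0:
            raise ValueError("zero slope: BMR unattainable")
        return float(-np.log1p(-a) / b)

    def profile_free_names(self, spec):
        return ("background",)

    def profile_free_bounds(self, spec, a):
        return [(0.0, 1.0)]

    def from_profile(self, spec, bmd, free, a):
        b = -np.log1p(-a) / bmd
        if b > _BIG_SLOPE:
            return None
        return np.array([free[0], b])

    def profile_free_from_theta(self, spec, theta):
        return theta[:1]

    def start_values(self, spec, doses, props, ed=None):
        g = _background_start(props)
        ed = ed or _ed50_start(doses, props)
        return np.array([g, np.log(2.0) / ed])


class _Multistage(_Model):
    # P = γ + (1 − γ)(1 − exp(−Σ βᵢ dⁱ)), βᵢ ≥ 0
    def bounds(self, spec):
        return [(0.0, 1.0)] + [(0.0, _BIG_SLOPE)] * spec.degree

    def prob(self, spec, dose, theta):
        g = theta[0]
        betas = theta[1:]
        s = np.zeros_like(dose)
        for i, b in enumerate(betas, start=1):
            s = s + b * dose**i
        return g + (1.0 - g) * (-np.expm1(-s))

    def bmd(self, spec, theta, a):
        target = -np.log1p(-a)
        betas = theta[1:]
        if np.all(betas <= 0):
            raise ValueError("all multistage coefficients zero: BMR unattainable")
        # smallest positive root of Σ βᵢ dⁱ − target = 0
        coeffs = np.concatenate(([-target], betas))  # ascending powers
        roots = np.polynomial.polynomial.polyroots(coeffs)
        real = roots[np.isreal(roots)].real
        pos = real[real > 0]
        if pos.size == 0:
            raise ValueError("no positive BMD root")
        return float(pos.min())

    def profile_free_names(self, spec):
        return ("background",) + tuple(f"beta{i}" for i in range(2, spec.degree + 1))

    def profile_free_bounds(self, spec, a):
        return [(0.0, 1.0)] + [(0.0, _BIG_SLOPE)] * (spec.degree - 1)

    def from_profile(self, spec, bmd, free, a):
        # β₁ absorbs the BMD constraint: Σ βᵢ·BMDⁱ = −ln(1 − A)
        target = -np.log1p(-a)
        higher = free[1:]
        resid = target - sum(b * bmd**i for i, b in enumerate(higher, start=2))
        b1 = resid / bmd
        if b1 < 0 or b1 > _BIG_SLOPE:
            return None
        return np.concatenate(([free[0], b1], higher))

    def profile_free_from_theta(self, spec, theta):
        return np.concatenate((theta[:1], theta[2:]))

    def start_values(self, spec, doses, props, ed=None):
        g = _background_start(props)
        ed = ed or _ed50_start(doses, props)
        theta = np.zeros(1 + spec.degree)
        theta[0] = g
        theta[1] = np.log(2.0) / ed
        return theta


class _LogLogistic(_Model):
    # P = γ + (1 − γ)/(1 + exp(−α − β ln d))
    param_names = ("background", "intercept", "slope")

    def bounds(self, spec):
        lo = 1.0 if spec.restricted else 1e-8
        return [(0.0, 1.0), (-40.0, 40.0), (lo, _POWER_MAX)]

    def prob(self, spec, dose, theta):
        g, alpha, beta = theta
        with np.errstate(over="ignore"):
            f = np.where(dose > 0, special.expit(alpha + beta * _safe_log(dose)), 0.0)
        return g + (1.0 - g) * f

    def bmd(self, spec, theta, a):
        _, alpha, beta = theta
        return float(np.exp((_logit(a) - alpha) / beta))

    def profile_free_names(self, spec):
        return ("background", "slope")

    def profile_free_bounds(self, spec, a):
        lo = 1.0 if spec.restricted else 1e-8
        return [(0.0, 1.0), (lo, _POWER_MAX)]

    def from_profile(self, spec, bmd, free, a):
        g, beta = free
        alpha = _logit(a) - beta * np.log(bmd)
        if not (-40.0 <= alpha <= 40.0):
            return None
        return np.array([g, alpha, beta])

    def profile_free_from_theta(self, spec, theta):
        return theta[[0, 2]]

    def start_values(self, spec, doses, props, ed=None):
        g = _background_start(props)
        ed = ed or _ed50_start(doses, props)
        beta = 1.3 if spec.restricted else 1.0
        return np.array([g, -beta * np.log(ed), beta])


class _LogProbit(_Model):
    # P = γ + (1 − γ)·Φ(α + β ln d)
    param_names = ("background", "intercept", "slope")

    def bounds(self, spec):
        lo = 1.0 if spec.restricted else 1e-8
        return [(0.0, 1.0), (-40.0, 40.0), (lo, _POWER_MAX)]

    def prob(self, spec, dose, theta):
        g, alpha, beta = theta
        f = np.where(dose > 0, norm.cdf(alpha + beta * _safe_log(dose)), 0.0)
        return g + (1.0 - g) * f

    def bmd(self, spec, theta, a):
        _, alpha, beta = theta
        return float(np.exp((norm.ppf(a) - alpha) / beta))

    def profile_free_names(self, spec):
        return ("background", "slope")

    def profile_free_bounds(self, spec, a):
        lo = 1.0 if spec.restricted else 1e-8
        return [(0.0, 1.0), (lo, _POWER_MAX)]

    def from_profile(self, spec, bmd, free, a):
        g, beta = free
        alpha = norm.ppf(a) - beta * np.log(bmd)
        if not (-40.0 <= alpha <= 40.0):
            return None
        return np.array([g, alpha, beta])

    def profile_free_from_theta(self, spec, theta):
        return theta[[0, 2]]

    def start_values(self, spec, doses, props, ed=None):
        g = _background_start(props)
        ed = ed or _ed50_start(doses, props)
        beta = 1.2 if spec.restricted else 0.8
        return np.array([g, -beta * np.log(ed), beta])


class _Weibull(_Model):
    # P = γ + (1 − γ)(1 − exp(−β d^α))
    param_names = ("background", "power", "slope")

    def bounds(self, spec):
        lo = 1.0 if spec.restricted else 1e-8
        return [(0.0, 1.0), (lo, _POWER_MAX), (0.0, _BIG_SLOPE)]

    def prob(self, spec, dose, theta):
        g, alpha, beta = theta
        with np.errstate(invalid="ignore"):
            t = np.where(dose > 0, dose**alpha, 0.0)
        return g + (1.0 - g) * (-np.expm1(-beta * t))

    def bmd(self, spec, theta, a):
        _, alpha, beta = theta
        if beta <= 0:
            raise ValueError("zero slope: BMR unattainable")
        return float((-np.log1p(-a) / beta) ** (1.0 / alpha))

    def profile_free_names(self, spec):
        return ("background", "power")

    def profile_free_bounds(self, spec, a):
        lo = 1.0 if spec.restricted else 1e-8
        return [(0.0, 1.0), (lo, _POWER_MAX)]

    def from_profile(self, spec, bmd, free, a):
        g, alpha = free
        with np.errstate(over="ignore"):
            beta = -np.log1p(-a) / bmd**alpha
        if not np.isfinite(beta) or beta > _BIG_SLOPE:
            return None
        return np.array([g, alpha, beta])

    def profile_free_from_theta(self, spec, theta):
        return theta[:2]

    def start_values(self, spec, doses, props, ed=None):
        g = _background_start(props)
        ed = ed or _ed50_start(doses, props)
        alpha = 1.2 if spec.restricted else 1.0
        return np.array([g, alpha, np.log(2.0) / ed**alpha])


class _Gamma(_Model):
    # P = γ + (1 − γ)·GammaCDF(β d; α)
    param_names = ("background", "power", "slope")

    def bounds(self, spec):
        lo = 1.0 if spec.restricted else 0.2
        return [(0.0, 1.0), (lo, _POWER_MAX), (0.0, _BIG_SLOPE)]

    def prob(self, spec, dose, theta):
        g, alpha, beta = theta
        return g + (1.0 - g) * special.gammainc(alpha, beta * dose)

    def bmd(self, spec, theta, a):
        _, alpha, beta = theta
        if beta <= 0:
            raise ValueError("zero slope: BMR unattainable")
        return float(special.gammaincinv(alpha, a) / beta)

    def profile_free_names(self, spec):
        return ("background", "power")

    def profile_free_bounds(self, spec, a):
        lo = 1.0 if spec.restricted else 0.2
        return [(0.0, 1.0), (lo, _POWER_MAX)]

    def from_profile(self, spec, bmd, free, a):
        g, alpha = free
        beta = special.gammaincinv(alpha, a) / bmd
        if not np.isfinite(beta) or beta > _BIG_SLOPE:
            return None
        return np.array([g, alpha, beta])

    def profile_free_from_theta(self, spec, theta):
        return theta[:2]

    def start_values(self, spec, doses, props, ed=None):
        g = _background_start(props)
        ed = ed or _ed50_start(doses, props)
        alpha = 1.3 if spec.restricted else 1.0
        return np.array([g, alpha, special.gammaincinv(alpha, 0.5) / ed])


class _Logistic(_Model):
    # P = 1/(1 + exp(−α − β d)); background is P(0) = expit(α)
    param_names = ("intercept", "slope")

    def bounds(self, spec):
        return [(-18.0, 18.0), (0.0, 100.0)]

    def prob(self, spec, dose, theta):
        alpha, beta = theta
        return special.expit(alpha + beta * dose)

    def bmd(self, spec, theta, a):
        alpha, beta = theta
        if beta <= 0:
            raise ValueError("zero slope: BMR unattainable")
        p0 = special.expit(alpha)
        pt = p0 + a * (1.0 - p0)
        return float((_logit(pt) - alpha) / beta)

    def profile_free_names(self, spec):
        return ("intercept",)

    def profile_free_bounds(self, spec, a):
        return [(-18.0, 18.0)]

    def from_profile(self, spec, bmd, free, a):
        alpha = free[0]
        p0 = special.expit(alpha)
        pt = p0 + a * (1.0 - p0)
        beta = (_logit(pt) - alpha) / bmd
        if beta < 0 or beta > 100.0:
            return None
        return np.array([alpha, beta])

    def profile_free_from_theta(self, spec, theta):
        return theta[:1]

    def start_values(self, spec, doses, props, ed=None):
        p0 = float(np.clip(props[0], 0.01, 0.95))
        ed = ed or _ed50_start(doses, props)
        pmax = float(np.clip(props.max(), p0 + 0.01, 0.99))
        alpha = _logit(p0)
        beta = (_logit(pmax) - alpha) / max(doses.max(), 1e-6)
        return np.array([alpha, max(beta, np.log(2.0) / ed / 10.0)])


class _Probit(_Model):
    # P = Φ(α + β d)
    param_names = ("intercept", "slope")

    def bounds(self, spec):
        return [(-18.0, 18.0), (0.0, 100.0)]

    def prob(self, spec, dose, theta):
        alpha, beta = theta
        return norm.cdf(alpha + beta * dose)

    def bmd(self, spec, theta, a):
        alpha, beta = theta
        if beta <= 0:
            raise ValueError("zero slope: BMR unattainable")
        p0 = norm.cdf(alpha)
        pt = p0 + a * (1.0 - p0)
        return float((norm.ppf(pt) - alpha) / beta)

    def profile_free_names(self, spec):
        return ("intercept",)

    def profile_free_bounds(self, spec, a):
        return [(-18.0, 18.0)]

    def from_profile(self, spec, bmd, free, a):
        alpha = free[0]
        p0 = norm.cdf(alpha)
        pt = p0 + a * (1.0 - p0)
        beta = (norm.ppf(pt) - alpha) / bmd
        if beta < 0 or beta > 100.0:
            return None
        return np.array([alpha, beta])

    def profile_free_from_theta(self, spec, theta):
        return theta[:1]

    def start_values(self, spec, doses, props, ed=None):
        p0 = float(np.clip(props[0], 0.01, 0.95))
        pmax = float(np.clip(props.max(), p0 + 0.01, 0.99))
        alpha = float(norm.ppf(p0))
        beta = (float(norm.ppf(pmax)) - alpha) / max(doses.max(), 1e-6)
        return np.array([alpha, max(beta, 1e-4)])


class _DichotomousHill(_Model):
    # P = γ + (ν − ν γ)/(1 + exp(−α − β ln d)); plateau at γ + ν(1 − γ)
    param_names = ("background", "max_fraction", "intercept", "slope")

    def bounds(self, spec):
        lo = 1.0 if spec.restricted else 1e-8
        return [(0.0, 1.0), (1e-8, 1.0), (-40.0, 40.0), (lo, _POWER_MAX)]

    def prob(self, spec, dose, theta):
        g, v, alpha, beta = theta
        with np.errstate(over="ignore"):
            f = np.where(dose > 0, special.expit(alpha + beta * _safe_log(dose)), 0.0)
        return g + v * (1.0 - g) * f

    def bmd(self, spec, theta, a):
        _, v, alpha, beta = theta
        if v <= a:
            raise ValueError(f"extra-risk plateau {v:.3g} below BMR level {a}: unattainable")
        return float(np.exp((_logit(a / v) - alpha) / beta))

    def profile_free_names(self, spec):
        return ("background", "max_fraction", "slope")

    def profile_free_bounds(self, spec, a):
        lo = 1.0 if spec.restricted else 1e-8
        return [(0.0, 1.0), (a + 1e-6, 1.0), (lo, _POWER_MAX)]

    def from_profile(self, spec, bmd, free, a):
        g, v, beta = free
        if v <= a:
            return None
        alpha = _logit(a / v) - beta * np.log(bmd)
        if not (-40.0 <= alpha <= 40.0):
            return None
        return np.array([g, v, alpha, beta])

    def profile_free_from_theta(self, spec, theta):
        return theta[[0, 1, 3]]

    def start_values(self, spec, doses, props, ed=None):
        g = _background_start(props)
        ed = ed or _ed50_start(doses, props)
        beta = 1.3 if spec.restricted else 1.0
        return np.array([g, 0.9, -beta * np.log(ed), beta])


_MODELS: dict[str, _Model] = {
    "quantal_linear": _QuantalLinear(),
    "multistage_k": _Multistage(),
    "log_logistic": _LogLogistic(),
    "log_probit": _LogProbit(),
    "weibull": _Weibull(),
    "gamma": _Gamma(),
    "logistic": _Logistic(),
    "probit": _Probit(),
    "dichotomous_hill": _DichotomousHill(),
}

SUITE_NAMES = (
    "quantal_linear",
    "multistage_k",
    "log_logistic",
    "log_probit",
    "weibull",
    "gamma",
    "logistic",
    "probit",
    "dichotomous_hill",
)


def get_model(name: str, restricted: bool = True, degree: int = 2) -> QuantalModelSpec:
    return QuantalModelSpec(name, restricted=restricted, degree=degree)


def suite(
    restricted: bool = True, n_groups: int | None = None, names: Sequence[str] = SUITE_NAMES
) -> list[QuantalModelSpec]:
    """The default nine-model suite.

    The multistage degree defaults to (number of dose groups − 1) capped at 3
    when ``n_groups`` is given, else 2.
    """
    degree = min(n_groups - 1, 3) if n_groups else 2
    return [QuantalModelSpec(n, restricted=restricted, degree=degree) for n in names]
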