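"""Continuous dose-response mean functions.

The standard continuous suite: linear, polynomial, power, Hill, and the
four nested exponential forms.  Each model defines a mean μ(d; θ) that is
monotone in dose under the default constraints; the sign of the trend is
carried by the slope-like parameter (linear/polynomial) or an explicit
direction (exponentials), so both adverse increases and decreases fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ContinuousModelSpec", "CONTINUOUS_SUITE"]

_POWER_MAX = 18.0


@dataclass(frozen=True)
class ContinuousModelSpec:
    """A continuous mean model plus its variance model.

    name
        linear, polynomial_k, power, hill, exponential_2, exponential_3,
        exponential_4, exponential_5.
    variance_model
        'constant' (single σ) or 'power_of_mean' (σ² = α·μ^ρ).
    direction
        +1 for responses rising with dose, −1 for falling (exponential
        models carry the sign explicitly; linear-family slopes may be
        negative so the direction is informational there).
    restricted
        power parameters bounded at ≥ 1 when True.
    """

    name: str
    variance_model: str = "constant"
    direction: int = -1
    restricted: bool = True
    degree: int = 2  # polynomial only

    def __post_init__(self) -> None:
        if self.name not in _MEANS:
            raise ValueError(f"unknown continuous model {self.name!r}; known: {sorted(_MEANS)}")
        if self.variance_model not in ("constant", "power_of_mean"):
            raise ValueError("variance_model must be constant or power_of_mean")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")

    @property
    def mean_param_names(self) -> tuple[str, ...]:
        if self.name == "polynomial_k":
            return ("intercept",) + tuple(f"beta{i}" for i in range(1, self.degree + 1))
        return _MEANS[self.name][0]

    @property
    def n_mean_params(self) -> int:
        return len(self.mean_param_names)

    def mean(self, dose, theta) -> np.ndarray:
        dose = np.asarray(dose, float)
        return _MEANS[self.name][1](self, dose, np.asarray(theta, float))

    def mean_bounds(self, scale: float, dose_max: float) -> list[tuple[float, float]]:
        """Parameter box; ``scale`` is a response-magnitude scale for slopes."""
        return _MEANS[self.name][2](self, scale, dose_max)

    def start_values(self, doses, means) -> np.ndarray:
        return _MEANS[self.name][3](self, np.asarray(doses, float), np.asarray(means, float))


def _mean_linear(spec, d, t):
    return t[0] + t[1] * d


def _bounds_linear(spec, s, dmax):
    return [(-10 * s, 10 * s), (-10 * s / dmax, 10 * s / dmax)]


def _start_linear(spec, d, m):
    b = (m[-1] - m[0]) / max(d[-1], 1e-12)
    return np.array([m[0], b])


def _mean_poly(spec, d, t):
    out = np.full_like(d, t[0])
    for i in range(1, spec.degree + 1):
        out = out + t[i] * d**i
    return out


def _bounds_poly(spec, s, dmax):
    out = [(-10 * s, 10 * s)]
    for i in range(1, spec.degree + 1):
        lim = 10 * s / dmax**i
        out.append((-lim, lim))
    return out


def _start_poly(spec, d, m):
    t = np.zeros(spec.degree + 1)
    t[0] = m[0]
    t[1] = (m[-1] - m[0]) / max(d[-1], 1e-12)
    return t


def _mean_power(spec, d, t):
    a, b, p = t
    with np.errstate(invalid="ignore"):
        dp = np.where(d > 0, d**p, 0.0)
    return a + b * dp


def _bounds_power(spec, s, dmax):
    lo = 1.0 if spec.restricted else 1e-2
    return [(-10 * s, 10 * s), (-10 * s, 10 * s), (lo, _POWER_MAX)]


def _start_power(spec, d, m):
    return np.array([m[0], (m[-1] - m[0]) / max(d[-1], 1e-12), 1.0])


def _mean_hill(spec, d, t):
    a, v, k, p = t
    with np.errstate(invalid="ignore"):
        dp = np.where(d > 0, d**p, 0.0)
    return a + v * dp / (k**p + dp)


def _bounds_hill(spec, s, dmax):
    lo = 1.0 if spec.restricted else 1e-2
    return [(-10 * s, 10 * s), (-10 * s, 10 * s), (dmax * 1e-4, dmax * 100), (lo, _POWER_MAX)]


def _start_hill(spec, d, m):
    pos = d[d > 0]
    return np.array([m[0], m[-1] - m[0], float(np.median(pos)), 1.5])


def _mean_exp2(spec, d, t):
    a, b = t
    return a * np.exp(spec.direction * b * d)


def _bounds_exp2(spec, s, dmax):
    return [(1e-8 * s if s > 0 else 1e-8, 100 * s), (0.0, 100.0 / dmax)]


def _start_exp2(spec, d, m):
    a = max(m[0], 1e-6)
    ratio = max(m[-1] / a, 1e-6)
    b = abs(np.log(ratio)) / max(d[-1], 1e-12)
    return np.array([a, b])


def _mean_exp3(spec, d, t):
    a, b, p = t
    with np.errstate(invalid="ignore"):
        bd = np.where(d > 0, (b * d) ** p, 0.0)
    return a * np.exp(spec.direction * bd)


def _bounds_exp3(spec, s, dmax):
    lo = 1.0 if spec.restricted else 1e-2
    return [(1e-8 * s if s > 0 else 1e-8, 100 * s), (1e-8, 100.0 / dmax), (lo, _POWER_MAX)]


def _start_exp3(spec, d, m):
    a, b = _start_exp2(spec, d, m)
    return np.array([a, b, 1.2])


def _mean_exp4(spec, d, t):
    a, b, c = t
    return a * (c - (c - 1.0) * np.exp(-b * d))


def _bounds_exp4(spec, s, dmax):
    # asymptote ratio c: below 1 for falling, above 1 for rising responses
    c_bounds = (1e-8, 1.0) if spec.direction < 0 else (1.0, 100.0)
    return [(1e-8 * s if s > 0 else 1e-8, 100 * s), (1e-8, 100.0 / dmax), c_bounds]


def _start_exp4(spec, d, m):
    a = max(m[0], 1e-6)
    c = float(np.clip(m[-1] / a, 1e-3, 100.0))
    c = min(c, 0.999) if spec.direction < 0 else max(c, 1.001)
    return np.array([a, np.log(2.0) / max(np.median(d[d > 0]), 1e-12), c])


def _mean_exp5(spec, d, t):
    a, b, c, p = t
    with np.errstate(invalid="ignore"):
        bd = np.where(d > 0, (b * d) ** p, 0.0)
    return a * (c - (c - 1.0) * np.exp(-bd))


def _bounds_exp5(spec, s, dmax):
    lo = 1.0 if spec.restricted else 1e-2
    return _bounds_exp4(spec, s, dmax) + [(lo, _POWER_MAX)]


def _start_exp5(spec, d, m):
    return np.append(_start_exp4(spec, d, m), 1.2)


_MEANS = {
    "linear": (("intercept", "slope"), _mean_linear, _bounds_linear, _start_linear),
    "polynomial_k": ((), _mean_poly, _bounds_poly, _start_poly),
    "power": (("intercept", "slope", "power"), _mean_power, _bounds_power, _start_power),
    "hill": (("intercept", "span", "ed50", "power"), _mean_hill, _bounds_hill, _start_hill),
    "exponential_2": (("baseline", "rate"), _mean_exp2, _bounds_exp2, _start_exp2),
    "exponential_3": (("baseline", "rate", "power"), _mean_exp3, _bounds_exp3, _start_exp3),
    "exponential_4": (("baseline", "rate", "asymptote_ratio"), _mean_exp4, _bounds_exp4, _start_exp4),
    "exponential_5": (
        ("baseline", "rate", "asymptote_ratio", "power"),
        _mean_exp5,
        _bounds_exp5,
        _start_exp5,
    ),
}

CONTINUOUS_SUITE = tuple(_MEANS)
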