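"""Continuous-endpoint fitting, benchmark responses and profile bounds."""

import numpy as np
import pytest

from bmdtox.continuous import (
    compute_bmd_continuous,
    fit_continuous,
    individual_loglik_equivalent,
    _loglik_cont,
)
from bmdtox.continuous_models import ContinuousModelSpec
from bmdtox.datasets import BenchmarkResponse, ContinuousDataset
from bmdtox.simulate import SimulationDesign, simulate_continuous

SD1 = BenchmarkResponse("one_sd")
REL5 = BenchmarkResponse("relative_deviation", 0.05)


def _linear_data(seed=3, b=-2.0, sigma=8.0, n=200):
    spec = ContinuousModelSpec("linear", direction=-1)
    design = SimulationDesign(
        model=spec, true_params=(100.0, b), doses=(0.0, 2.0, 5.0, 10.0),
        n_per_group=n, seed=seed, sigma=sigma,
    )
    return spec, simulate_continuous(design)[0]


def test_identical_means_give_zero_slope():
    d = ContinuousDataset(
        "flat", ((0.0, 30, 50.0, 5.0), (5.0, 30, 50.0, 5.0), (20.0, 30, 50.0, 5.0))
    )
    spec = ContinuousModelSpec("linear")
    fit = fit_continuous(d, spec)
    assert abs(fit.mean_params[1]) < 1e-4


def test_exponential3_parameter_recovery_large_n():
    """Generator truth (a=100, b=0.02, p=1.5, σ=5) recovered within 5%."""
    spec = ContinuousModelSpec("exponential_3", direction=-1)
    design = SimulationDesign(
        model=spec, true_params=(100.0, 0.02, 1.5),
        doses=(0.0, 5.0, 10.0, 25.0, 50.0, 100.0), n_per_group=10_000, seed=11, sigma=5.0,
    )
    data = simulate_continuous(design)[0]
    fit = fit_continuous(data, spec)
    np.testing.assert_allclose(fit.mean_params, [100.0, 0.02, 1.5], rtol=0.05)
    assert fit.sigma_hat == pytest.approx(5.0, rel=0.05)


def test_summary_loglik_equals_reference_form():
    """The sufficient-statistic likelihood matches the reference evaluation."""
    spec, data = _linear_data()
    theta = np.array([99.0, -1.9, np.log(8.2)])
    mu = spec.mean(np.array(data.doses), theta[:2])
    sig2 = np.full_like(mu, 8.2**2)
    assert _loglik_cont(spec, data, theta) == pytest.approx(
        individual_loglik_equivalent(data, mu, sig2), rel=1e-12
    )


def test_one_sd_bmd_closed_form_linear():
    spec, data = _linear_data()
    fit = fit_continuous(data, spec)
    est = compute_bmd_continuous(fit, SD1, compute_lower=False)
    assert est.bmd == pytest.approx(fit.sigma_hat / abs(fit.mean_params[1]), rel=1e-8)


def test_relative_deviation_bmd_closed_form_linear():
    spec, data = _linear_data()
    fit = fit_continuous(data, spec)
    est = compute_bmd_continuous(fit, REL5, compute_lower=False)
    expected = 0.05 * abs(fit.mean_params[0]) / abs(fit.mean_params[1])
    assert est.bmd == pytest.approx(expected, rel=1e-8)


def test_bmdl_below_bmd_and_positive():
    spec, data = _linear_data(seed=8)
    fit = fit_continuous(data, spec)
    est = compute_bmd_continuous(fit, SD1)
    assert 0 < est.bmdl <= est.bmd
    assert not est.bmdl_at_search_floor


def test_fetal_weight_like_bmd5_recovery():
    """A 5%-deviation dose of 52 is recovered at generator scale.

    Emulates a developmental-toxicity fetal-weight scenario: control mean
    ~5.9 g falling smoothly with dose, 5% change at dose 52.
    """
    spec = ContinuousModelSpec("power", direction=-1, restricted=True)
    # a + b*d^p with 5% drop of 5.9 at 52: b = -0.05*5.9/52^1.2
    a, p = 5.9, 1.2
    b = -0.05 * a / 52.0**p
    design = SimulationDesign(
        model=spec, true_params=(a, b, p), doses=(0.0, 10.0, 25.0, 50.0, 125.0),
        n_per_group=500, seed=17, sigma=0.25,
    )
    data = simulate_continuous(design)[0]
    fit = fit_continuous(data, spec)
    est = compute_bmd_continuous(fit, REL5, compute_lower=False)
    assert est.bmd == pytest.approx(52.0, rel=0.10)  # within Monte-Carlo error


def test_dose_scale_equivariance_continuous():
    spec, data = _linear_data(seed=5)
    c = 2.5
    scaled = ContinuousDataset(
        data.endpoint_name,
        tuple((d * c, n, m, s) for d, n, m, s in data.groups),
        data.adverse_direction,
    )
    f1, f2 = fit_continuous(data, spec), fit_continuous(scaled, spec)
    e1 = compute_bmd_continuous(f1, SD1, compute_lower=False)
    e2 = compute_bmd_continuous(f2, SD1, compute_lower=False)
    assert e2.bmd == pytest.approx(c * e1.bmd, rel=1e-6)


def test_one_sd_bmd_invariant_to_affine_response_rescaling():
    """Shifting/scaling the response units leaves the 1-SD BMD unchanged."""
    spec, data = _linear_data(seed=9)
    a, b = 3.0, 25.0  # y -> a*y + b
    rescaled = ContinuousDataset(
        data.endpoint_name,
        tuple((d, n, a * m + b, a * s) for d, n, m, s in data.groups),
        data.adverse_direction,
    )
    e1 = compute_bmd_continuous(fit_continuous(data, spec), SD1, compute_lower=False)
    e2 = compute_bmd_continuous(fit_continuous(rescaled, spec), SD1, compute_lower=False)
    assert e2.bmd == pytest.approx(e1.bmd, rel=1e-4)


def test_power_of_mean_variance_model_fits():
    spec = ContinuousModelSpec("linear", variance_model="power_of_mean", direction=-1)
    _, data = _linear_data(seed=12)
    fit = fit_continuous(data, spec)
    assert fit.converged
    assert np.isfinite(fit.log_likelihood)
    assert fit.sigma_hat > 0
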