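"""Lognormal adjustment-factor propagation for the probabilistic RfD."""

import math

import numpy as np
import pytest

from bmdtox.prfd import (
    LognormalUncertain,
    ProbabilisticChain,
    Z95,
    ad_from_bmd,
    default_af_config,
    default_chain,
    propagate,
    variance_budget,
)


def _chain(ad=None, bw=None, tktd=None, h=None, **kw):
    point = LognormalUncertain(1.0, 1.0)
    return ProbabilisticChain(
        ad=ad or LognormalUncertain(10.0, 2.0),
        af_bw=bw or point,
        af_tktd=tktd or point,
        af_h=h or point,
        **kw,
    )


class TestAdFromBmd:
    def test_sigma_from_published_bma_pair(self):
        ad = ad_from_bmd(14.2, 6.4)
        assert ad.sigma_ln == pytest.approx(math.log(14.2 / 6.4) / 1.6449, abs=1e-4)
        assert ad.sigma_ln == pytest.approx(0.4846, abs=2e-4)

    def test_fifth_percentile_round_trips_to_bmdl(self):
        ad = ad_from_bmd(14.2, 6.4)
        assert ad.percentile(5.0) == pytest.approx(6.4, rel=1e-9)

    def test_equal_pair_gives_point_mass(self):
        ad = ad_from_bmd(5.0, 5.0)
        assert ad.sigma_ln == 0.0

    def test_inverted_pair_rejected(self):
        with pytest.raises(ValueError):
            ad_from_bmd(6.4, 14.2)


class TestPropagate:
    def test_degenerate_chain_returns_bmdl(self):
        """All AFs point masses at 1: the pRfD is the AD 5th percentile = BMDL."""
        chain = _chain(ad=ad_from_bmd(14.2, 6.4), uf_d=1.0, n_samples=50_000, seed=1)
        res = propagate(chain)
        assert res.hd_i_p5_closed == pytest.approx(6.4, rel=1e-9)
        assert res.prfd_raw == pytest.approx(6.4, rel=1e-9)

    def test_monte_carlo_matches_closed_form_at_1e6(self):
        chain = default_chain(14.2, 6.4, animal_bw=0.29, n_samples=1_000_000, seed=3)
        res = propagate(chain)
        assert res.hd_i_p5_mc == pytest.approx(res.hd_i_p5_closed, rel=0.01)
        # and at every reported percentile, within MC error ~ 1/sqrt(n)
        mu_i = math.log(res.hd_i_percentiles[50.0])
        for q, v in res.hd_i_percentiles.items():
            assert v > 0

    def test_uf_d_divides_after_the_percentile(self):
        c1 = default_chain(14.2, 6.4, animal_bw=0.29, uf_d=1.0, seed=5)
        c3 = default_chain(14.2, 6.4, animal_bw=0.29, uf_d=3.0, seed=5)
        r1, r3 = propagate(c1), propagate(c3)
        assert r3.prfd_raw == pytest.approx(r1.prfd_raw / 3.0, rel=1e-12)
        assert r3.hd_i_p5_closed == pytest.approx(r1.hd_i_p5_closed, rel=1e-12)

    def test_median_chain_identity(self):
        """Median of HD^50% equals ad.p50 / (af_bw.p50 × af_tktd.p50) exactly."""
        chain = default_chain(14.2, 6.4, animal_bw=0.29, seed=2)
        res = propagate(chain)
        expected = chain.ad.p50 / (chain.af_bw.p50 * chain.af_tktd.p50)
        assert res.hd50_percentiles[50.0] == pytest.approx(expected, rel=1e-12)

    def test_widening_any_factor_lowers_the_5th_percentile(self):
        base = default_chain(14.2, 6.4, animal_bw=0.29, seed=2)
        p5_base = propagate(base).hd_i_p5_closed
        for name in ("af_bw", "af_tktd", "af_h"):
            widened = {
                "ad": base.ad, "af_bw": base.af_bw, "af_tktd": base.af_tktd, "af_h": base.af_h,
            }
            f = widened[name]
            widened[name] = LognormalUncertain(f.p50, f.p95_over_p50 * 1.5)
            chain = ProbabilisticChain(
                target_incidence=base.target_incidence, uf_d=base.uf_d,
                n_samples=base.n_samples, seed=base.seed, **widened,
            )
            assert propagate(chain).hd_i_p5_closed < p5_base

    def test_median_incidence_collapses_to_hd50(self):
        """I = 50% uses a degenerate AF_H, so HD^I coincides with HD^50%."""
        chain = default_chain(14.2, 6.4, animal_bw=0.29, target_incidence=0.5, seed=4)
        res = propagate(chain)
        assert res.hd_i_percentiles == pytest.approx(res.hd50_percentiles)

    def test_percentiles_monotone(self):
        res = propagate(default_chain(14.2, 6.4, animal_bw=0.29, seed=6))
        for table in (res.hd50_percentiles, res.hd_i_percentiles):
            qs = sorted(table)
            vals = [table[q] for q in qs]
            assert vals == sorted(vals)

    def test_small_sample_request_rejected(self):
        with pytest.raises(ValueError, match="10000"):
            _chain(n_samples=5_000)


class TestVarianceBudget:
    def test_only_ad_uncertain_gets_full_share(self):
        chain = _chain(ad=LognormalUncertain(10.0, 2.0))
        budget = variance_budget(chain)
        assert budget["ad"] == pytest.approx(1.0)

    def test_equal_sigmas_share_equally(self):
        chain = _chain(
            ad=LognormalUncertain(10.0, 2.0), h=LognormalUncertain(9.7, 2.0)
        )
        budget = variance_budget(chain)
        assert budget["ad"] == pytest.approx(0.5)
        assert budget["af_h"] == pytest.approx(0.5)

    def test_shares_sum_to_one_for_default_chain(self):
        budget = variance_budget(default_chain(14.2, 6.4, animal_bw=0.29))
        assert sum(budget.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_degenerate_chain_reports_nan(self):
        budget = variance_budget(_chain(ad=LognormalUncertain(10.0, 1.0)))
        assert all(math.isnan(v) for v in budget.values())


class TestDefaultConfig:
    def test_af_bw_median_follows_allometric_exponent(self):
        cfg = default_af_config()
        chain = default_chain(14.2, 6.4, animal_bw=0.29, human_bw=70.0)
        ratio = 70.0 / 0.29
        assert chain.af_bw.p50 == pytest.approx(ratio ** cfg["af_bw"]["exponent"], rel=1e-12)
        assert chain.af_bw.p95_over_p50 == pytest.approx(
            ratio ** (Z95 * cfg["af_bw"]["exponent_sd"]), rel=1e-12
        )

    def test_unknown_incidence_raises_with_available_keys(self):
        with pytest.raises(KeyError, match="0.01"):
            default_chain(14.2, 6.4, animal_bw=0.29, target_incidence=0.003)
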