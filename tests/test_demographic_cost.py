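"""Survivorship curve, replacement-chain cost, and footprint scaling."""

import numpy as np
import pytest

from eagle_demography import demographic_cost as dc
from eagle_demography.rates import canonical_rates


class TestSurvivorship:
    def test_forty_months_turbine_censored(self, turbine_rates):
        assert round(dc.survivorship(turbine_rates, 40), 3) == 0.695

    def test_boundaries(self, turbine_rates):
        assert dc.survivorship(turbine_rates, 0) == 1.0
        assert dc.survivorship(turbine_rates, 12) == pytest.approx(
            turbine_rates.s_juv
        )
        assert dc.survivorship(turbine_rates, 48) == pytest.approx(
            turbine_rates.s_juv * turbine_rates.s_sub**3
        )

    def test_non_increasing(self, turbine_rates):
        ages = np.linspace(0, 120, 241)
        phis = [dc.survivorship(turbine_rates, a) for a in ages]
        assert all(a >= b for a, b in zip(phis, phis[1:]))

    def test_multiplicative_over_stage_spans(self, turbine_rates):
        """phi factorises at stage boundaries: surviving to 40 months is
        surviving the juvenile year times 28 subadult months."""
        r = turbine_rates
        phi40 = dc.survivorship(r, 40)
        conditional = r.s_sub ** (28 / 12)
        assert phi40 == pytest.approx(
            dc.survivorship(r, 12) * conditional, abs=1e-12
        )

    def test_monthly_hazard_monte_carlo_oracle(self, turbine_rates):
        """An individual-based cohort under monthly stage hazards agrees
        with the fractional-exponent curve within binomial error."""
        rng = np.random.default_rng(100)
        n = 200_000
        r = turbine_rates
        p_m = np.concatenate([
            np.full(12, r.s_juv ** (1 / 12)),
            np.full(28, r.s_sub ** (1 / 12)),
        ])
        alive = np.ones(n, dtype=bool)
        for p in p_m:
            alive &= rng.random(n) < p
        est = alive.mean()
        truth = dc.survivorship(r, 40)
        se = np.sqrt(truth * (1 - truth) / n)
        assert abs(est - truth) < 3 * se

    def test_negative_age_rejected(self, turbine_rates):
        with pytest.raises(ValueError):
            dc.survivorship(turbine_rates, -1)


class TestPairsToProduce:
    def test_one_fledgling(self):
        assert round(dc.pairs_to_produce(1.0, 0.638), 3) == 1.567

    def test_forty_month_survivor(self, turbine_rates):
        need = 1.0 / dc.survivorship(turbine_rates, 40)
        assert round(dc.pairs_to_produce(need, 0.638), 3) == 2.256

    def test_zero_need(self):
        assert dc.pairs_to_produce(0.0, 0.638) == 0.0

    def test_zero_f2_rejected(self):
        with pytest.raises(ValueError):
            dc.pairs_to_produce(1.0, 0.0)


class TestReplacementChain:
    def test_published_chain_values(self, turbine_rates):
        ch = dc.replacement_chain(turbine_rates, 0.638, 40, 6)
        assert round(ch.pairs_initial, 3) == 2.256
        assert round(ch.series[1], 3) == 3.190
        assert ch.series[6] == pytest.approx(3.844, abs=0.005)
        assert ch.replacement_ratio == pytest.approx(0.4144, abs=0.0005)

    def test_limit_differs_from_published_reference_constant(self,
                                                         turbine_rates):
        """The geometric limit of the stated recursion is ~3.853; the
        published closed-form 3.931 is stored, never computed."""
        ch = dc.replacement_chain(turbine_rates, 0.638, 40, 6)
        assert ch.pairs_limit == pytest.approx(3.853, abs=0.005)
        assert ch.per_fatality_published == 3.931

    def test_series_monotone_and_converges_geometrically(self,
                                                         turbine_rates):
        ch = dc.replacement_chain(turbine_rates, 0.638, 40, 20)
        s = np.array(ch.series)
        assert np.all(np.diff(s) > 0)
        assert np.all(s < ch.pairs_limit)
        p0, r = ch.pairs_initial, ch.replacement_ratio
        for k, val in enumerate(ch.series):
            bound = p0 * r ** (k + 1) / (1 - r)
            assert abs(val - ch.pairs_limit) <= bound + 1e-12

    def test_limit_decreasing_in_rates_and_f2(self, turbine_rates):
        base = dc.replacement_chain(turbine_rates, 0.638, 40, 6).pairs_limit
        for key in ("s_juv", "s_sub", "s_breed"):
            up = turbine_rates.with_(
                **{key: getattr(turbine_rates, key) + 0.01}
            )
            assert dc.replacement_chain(up, 0.638, 40, 6).pairs_limit < base
        assert dc.replacement_chain(
            turbine_rates, 0.7, 40, 6
        ).pairs_limit < base

    def test_unsustainable_rates_flagged(self, turbine_rates):
        bad = turbine_rates.with_(s_breed=0.5, scenario="")
        ch = dc.replacement_chain(bad, 0.638, 40, 3)
        assert not ch.sustainable
        assert np.isinf(ch.pairs_limit)

    def test_cohort_monte_carlo_oracle(self, turbine_rates):
        """Simulate the narrative directly: the expected fledgling output
        needed for one 40-month survivor, and the expected breeder
        replacements per pair-year, reproduce P0 and the ratio r."""
        rng = np.random.default_rng(321)
        r = turbine_rates
        n = 400_000
        # fledglings surviving 40 months (12 juv + 28 sub monthly draws)
        alive = np.ones(n, dtype=bool)
        for p in [r.s_juv ** (1 / 12)] * 12 + [r.s_sub ** (1 / 12)] * 28:
            alive &= rng.random(n) < p
        phi_hat = alive.mean()
        p0_hat = 1.0 / (0.638 * phi_hat)
        ch = dc.replacement_chain(r, 0.638, 40, 1)
        assert p0_hat == pytest.approx(ch.pairs_initial, rel=0.02)
        # breeder deaths among 2-member pairs in a year
        deaths = rng.binomial(2, 1 - r.s_breed, size=n).mean()
        phi_r = r.s_juv * r.s_sub**3 * r.s_breed
        r_hat = deaths / (0.638 * phi_r)
        assert r_hat == pytest.approx(ch.replacement_ratio, rel=0.02)


class TestAgeResolved:
    def test_point_mass_degenerates(self, turbine_rates):
        lim = dc.replacement_chain(turbine_rates, 0.638, 40, 6).pairs_limit
        assert dc.age_resolved_cost(
            turbine_rates, 0.638, {40: 1.0}
        ) == pytest.approx(lim)

    def test_two_point_mixture_is_mean(self, turbine_rates):
        l20 = dc.replacement_chain(turbine_rates, 0.638, 20, 6).pairs_limit
        l40 = dc.replacement_chain(turbine_rates, 0.638, 40, 6).pairs_limit
        mixed = dc.age_resolved_cost(
            turbine_rates, 0.638, {20: 0.5, 40: 0.5}
        )
        assert mixed == pytest.approx((l20 + l40) / 2, abs=1e-12)

    def test_uniform_equals_per_month_average(self, turbine_rates):
        ages = list(range(13, 49))
        w = 1.0 / len(ages)
        got = dc.age_resolved_cost(
            turbine_rates, 0.638, {a: w for a in ages}
        )
        brute = np.mean(
            [dc.replacement_chain(turbine_rates, 0.638, a, 6).pairs_limit
             for a in ages]
        )
        assert got == pytest.approx(brute, abs=1e-12)

    def test_bad_weights_rejected(self, turbine_rates):
        with pytest.raises(ValueError):
            dc.age_resolved_cost(turbine_rates, 0.638, {40: 0.7})


class TestFootprint:
    def test_published_products(self):
        fp55 = dc.footprint(dc.PUBLISHED_PAIRS_PER_FATALITY, 55, 0.9)
        assert fp55.pairs_required == 216
        fp65 = dc.footprint(dc.PUBLISHED_PAIRS_PER_FATALITY, 65, 0.9)
        # 65 x 3.931 = 255.515: half-up rounding gives 256, one more
        # than the published 255
        assert 65 * dc.PUBLISHED_PAIRS_PER_FATALITY == pytest.approx(
            255.515
        )
        assert fp65.pairs_required == 256

    def test_resident_share(self):
        fp = dc.footprint(dc.PUBLISHED_PAIRS_PER_FATALITY, 55, 0.9)
        assert fp.resident_pairs == round(0.9 * 55 * 3.931)

    def test_zero_deaths(self):
        fp = dc.footprint(3.931, 0)
        assert fp.pairs_required == 0 and fp.resident_pairs == 0
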