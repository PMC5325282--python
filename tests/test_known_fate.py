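"""Risk sets, product-binomial MLEs, AICc ranking, annual survival, and
analytic what-if censoring."""

import numpy as np
import pytest

from eagle_demography import known_fate as kf
from eagle_demography.telemetry_io import (
    HUMAN_RELATED_CAUSES,
    SeasonInterval,
    TURBINE_CAUSES,
)

from conftest import make_history


def _cohort(n, entry, fates):
    """n individuals entering together; ``fates`` maps index ->
    (interval_offset, state) overriding the default alive run."""
    hs = []
    e = entry
    horizon = 3
    for i in range(n):
        if i in fates:
            off, state = fates[i]
            states = ["alive-detected"] * off + [state]
            cause = "Electrocution" if state == "dead" else None
        else:
            states = ["alive-detected"] * horizon
            cause = None
        hs.append(
            make_history(f"I{i}", entry=entry, states=tuple(states),
                         cause=cause)
        )
    return hs


class TestRiskSets:
    entry = SeasonInterval(1994, "Summer")

    def test_death_and_censor_arithmetic(self):
        # 10 tagged; 1 dies in interval 0; 1 censored after interval 0
        hs = _cohort(10, self.entry, {0: (0, "dead"), 1: (1, "censored")})
        rs = kf.build_risk_sets(hs, min_n=1)
        t = rs.table.set_index("interval")
        assert t.loc[self.entry, "n_risk"] == 10
        assert t.loc[self.entry, "n_deaths"] == 1
        assert t.loc[self.entry.next(), "n_risk"] == 8
        assert t.loc[self.entry.next(), "n_deaths"] == 0

    def test_all_censored_before_any_death(self):
        hs = _cohort(6, self.entry, {i: (1, "censored") for i in range(6)})
        rs = kf.build_risk_sets(hs, min_n=1)
        assert rs.total_deaths == 0

    def test_tail_truncation_at_min_n(self):
        # 12 enter; by the third interval only a handful remain detected
        hs = []
        for i in range(12):
            k = 3 if i < 4 else 1
            hs.append(make_history(f"I{i}", entry=self.entry,
                                   states=("alive-detected",) * k))
        rs = kf.build_risk_sets(hs, min_n=11)
        assert rs.n_intervals == 1  # tail below threshold dropped

    def test_no_interval_reaches_min_n(self):
        hs = _cohort(4, self.entry, {})
        with pytest.raises(kf.EmptyRiskSetError):
            kf.build_risk_sets(hs, min_n=11)

    def test_simulator_tally_matches_builder(self):
        """Risk sets equal the simulator's own per-interval exposure."""
        from eagle_demography.rates import canonical_rates
        from eagle_demography.synthetic_population import (
            SimulationConfig, simulate,
        )

        res = simulate(
            SimulationConfig(rates=canonical_rates("all_deaths"), seed=9)
        )
        rs = kf.build_risk_sets(res.histories, min_n=1)
        t = rs.table.set_index("interval")
        oracle = res.tagged_exposure.set_index("interval")
        assert len(t) == len(oracle)
        for iv in oracle.index:
            assert t.loc[iv, "n_risk"] == oracle.loc[iv, "n_risk"]
            assert t.loc[iv, "n_deaths"] == oracle.loc[iv, "n_deaths"]


class TestCensorByCause:
    entry = SeasonInterval(1994, "Summer")

    def test_turbine_death_becomes_censor(self):
        h = make_history(states=("alive-detected", "dead"),
                         cause="Wind turbine blade-strike")
        (out,) = kf.censor_by_cause([h], TURBINE_CAUSES)
        assert out.terminal_state == "censored"
        assert out.cause is None
        assert out.records[-1][0] == h.records[-1][0]

    def test_empty_set_is_identity(self):
        h = make_history(states=("alive-detected", "dead"),
                         cause="Lead")
        (out,) = kf.censor_by_cause([h], set())
        assert out == h

    def test_undiagnosed_never_censored(self):
        h = make_history(states=("dead",), cause="Undiagnosed fatality")
        (out,) = kf.censor_by_cause(
            [h], HUMAN_RELATED_CAUSES | {"Undiagnosed fatality"}
        )
        assert out.terminal_state == "dead"

    def test_human_set_removes_exactly_anthropogenic_deaths(self):
        causes = ["Wind turbine blade-strike", "Electrocution",
                  "Fledgling mishap", "Killed by eagle",
                  "Undiagnosed fatality", "Gunshot", "Lead"]
        hs = [
            make_history(f"I{i}", states=("alive-detected", "dead"),
                         cause=c)
            for i, c in enumerate(causes)
        ]
        out = kf.censor_by_cause(hs, HUMAN_RELATED_CAUSES)
        n_dead = sum(1 for h in out if h.terminal_state == "dead")
        n_anthro = sum(
            1 for c in causes if c in HUMAN_RELATED_CAUSES
        )
        assert n_dead == len(causes) - n_anthro

    def test_monotone_in_censor_set(self):
        """Censoring more causes never lowers the survival estimate."""
        rng = np.random.default_rng(5)
        causes = list(HUMAN_RELATED_CAUSES)
        hs = []
        for i in range(120):
            if rng.random() < 0.3:
                hs.append(make_history(
                    f"I{i}", states=("alive-detected", "dead"),
                    cause=causes[int(rng.integers(len(causes)))]))
            else:
                hs.append(make_history(
                    f"I{i}", states=("alive-detected",) * 3))
        prev = -1.0
        for cset in (set(), TURBINE_CAUSES, HUMAN_RELATED_CAUSES):
            rs = kf.build_risk_sets(kf.censor_by_cause(hs, cset), min_n=1)
            s = kf.fit_known_fate(rs, "constant").estimates[0]
            assert s >= prev
            prev = s


class TestFit:
    def test_single_interval_binomial(self):
        rs = kf.RiskSet.from_counts([10], [1])
        fit = kf.fit_known_fate(rs, "constant")
        assert fit.estimates[0] == pytest.approx(0.9)
        assert np.sqrt(fit.vcov[0, 0]) == pytest.approx(
            np.sqrt(0.9 * 0.1 / 10), abs=1e-12
        )

    def test_constant_pools_intervals(self):
        rs = kf.RiskSet.from_counts([10, 8], [1, 0])
        fit = kf.fit_known_fate(rs, "constant")
        assert fit.estimates[0] == pytest.approx(17 / 18)
        assert fit.K == 1 and fit.n_eff == 18

    def test_no_deaths_boundary(self):
        fit = kf.fit_known_fate(kf.RiskSet.from_counts([10], [0]),
                                "constant")
        assert fit.estimates[0] == 1.0
        assert fit.logL == 0.0
        assert fit.boundary

    def test_time_model_is_per_interval_proportion(self):
        rs = kf.RiskSet.from_counts([20, 15, 12], [2, 0, 3])
        fit = kf.fit_known_fate(rs, "time")
        assert fit.K == 3
        np.testing.assert_allclose(
            fit.estimates, [18 / 20, 1.0, 9 / 12]
        )

    def test_sex_model(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "interval": [0, 0, 1, 1],
                "sex": ["female", "male"] * 2,
                "n_risk": [10, 12, 9, 11],
                "n_deaths": [1, 2, 0, 1],
            }
        )
        rs = kf.RiskSet(table, by_sex=True)
        fit = kf.fit_known_fate(rs, "sex")
        assert fit.K == 2
        np.testing.assert_allclose(fit.estimates, [18 / 19, 20 / 23])
        fit2 = kf.fit_known_fate(rs, "sex_by_time")
        assert fit2.K == 4

    def test_logit_optimiser_agrees_with_closed_form(self):
        rs = kf.RiskSet.from_counts([30, 25, 22, 18], [3, 1, 2, 1])
        for model in ("constant", "time"):
            closed = kf.fit_known_fate(rs, model).estimates
            optim = kf._fit_logit_optim(rs, model)
            np.testing.assert_allclose(optim, closed, atol=1e-7)

    def test_kaplan_meier_identity_without_staggering(self):
        """With one entry cohort and no censoring, the product of
        seasonal MLEs is the Kaplan-Meier product-limit estimate."""
        n0, deaths = 50, [4, 3, 2, 5]
        n, d, at_risk = [], [], n0
        for dk in deaths:
            n.append(at_risk)
            d.append(dk)
            at_risk -= dk
        fit = kf.fit_known_fate(kf.RiskSet.from_counts(n, d), "time")
        km = np.prod([(nk - dk) / nk for nk, dk in zip(n, d)])
        assert np.prod(fit.estimates) == pytest.approx(km, abs=1e-12)
        ann = kf.annual_from_seasonal(fit)
        assert ann.S_hat == pytest.approx(km, abs=1e-12)


class TestRanking:
    def _fit(self, logL, K, n_eff=100, model="constant"):
        return kf.SurvivalFit(
            model=model, param_names=["S"] * K,
            estimates=np.full(K, 0.9), vcov=np.eye(K) * 1e-4,
            logL=logL, K=K, n_eff=n_eff, aicc=kf._aicc(logL, K, n_eff),
        )

    def test_single_model(self):
        df = kf.rank_models([self._fit(-50.0, 1)])
        assert df["dAICc"].iloc[0] == 0.0
        assert df["weight"].iloc[0] == pytest.approx(1.0)

    def test_parsimony_wins_at_equal_likelihood(self):
        a = self._fit(-50.0, 1, model="constant")
        b = self._fit(-50.0, 2, model="sex")
        df = kf.rank_models([a, b])
        assert df["model"].iloc[0] == "constant"

    def test_weights_from_hand_computed_aicc(self):
        # direct evaluation of w_m = exp(-d_m/2)/sum for AICc 100,102,110
        d = np.array([0.0, 2.0, 10.0])
        expected = np.exp(-d / 2) / np.exp(-d / 2).sum()
        fits = []
        for target in (100.0, 102.0, 110.0):
            # choose logL so that _aicc lands exactly on target (K=1)
            n = 1000
            logL = -(target - 2 - 4 / (n - 2)) / 2
            fits.append(self._fit(logL, 1, n_eff=n))
        df = kf.rank_models(fits)
        np.testing.assert_allclose(
            np.sort(df["weight"])[::-1], expected, atol=1e-9
        )
        assert df["weight"].sum() == pytest.approx(1.0)

    def test_mixed_n_eff_rejected(self):
        with pytest.raises(ValueError, match="identical data"):
            kf.rank_models([self._fit(-50, 1, 100),
                            self._fit(-50, 1, 200)])

    def test_aicc_approaches_aic_for_large_samples(self):
        K, logL = 2, -120.0
        aic = -2 * logL + 2 * K
        assert abs(kf._aicc(logL, K, 10**4 * K + 1) - aic) < 0.01


class TestAnnual:
    def test_constant_power_identity(self):
        fit = kf.fit_known_fate(
            kf.RiskSet.from_counts([100], [5]), "constant"
        )
        ann = kf.annual_from_seasonal(fit)
        assert ann.S_hat == pytest.approx(0.95**4)

    def test_delta_method_closed_form(self):
        S, v = 0.95, 0.95 * 0.05 / 100
        fit = kf.fit_known_fate(
            kf.RiskSet.from_counts([100], [5]), "constant"
        )
        ann = kf.annual_from_seasonal(fit)
        assert ann.SE == pytest.approx(np.sqrt((4 * S**3) ** 2 * v))

    def test_ci_is_asymmetric_and_bounded(self):
        fit = kf.fit_known_fate(
            kf.RiskSet.from_counts([40, 38, 36, 35], [2, 2, 1, 1]),
            "constant",
        )
        ann = kf.annual_from_seasonal(fit)
        lo, hi = ann.ci95
        assert 0 < lo < ann.S_hat < hi < 1
        # logit-scale intervals are asymmetric around the estimate
        assert (ann.S_hat - lo) != pytest.approx(hi - ann.S_hat, abs=1e-4)

    def test_needs_enough_intervals(self):
        fit = kf.fit_known_fate(
            kf.RiskSet.from_counts([30, 28], [1, 1]), "time"
        )
        with pytest.raises(ValueError):
            kf.annual_from_seasonal(fit)


class TestRecovery:
    """Simulation-based parameter recovery and CI calibration."""

    def test_ci_coverage_at_085(self):
        """95% CIs from 500-individual cohorts over 12 intervals cover
        the true annual survival in >= 93% of replicates (1000, so the
        bound sits above Monte-Carlo noise; true coverage is ~95%)."""
        from eagle_demography.synthetic_population import (
            simulate_risk_set_replicates,
        )

        rng = np.random.default_rng(2024)
        true_s = 0.85
        n_rep = 1000
        n, d = simulate_risk_set_replicates(true_s, 500, 12, n_rep, rng)
        hits = 0
        for k in range(n_rep):
            fit = kf.fit_known_fate(
                kf.RiskSet.from_counts(n[k], d[k]), "constant"
            )
            lo, hi = kf.annual_from_seasonal(fit).ci95
            hits += lo <= true_s <= hi
        assert hits >= 0.93 * n_rep

    @pytest.mark.parametrize(
        "scenario", ["all_deaths", "turbine_censored", "human_censored"]
    )
    def test_recovery_within_two_se(self, scenario):
        """Refits at each stage's published survival recover it within
        2 SE in >= 90% of replicates (1000 per stage, enough that the
        bound is judged above Monte-Carlo noise)."""
        from eagle_demography.rates import canonical_rates
        from eagle_demography.synthetic_population import (
            simulate_risk_set_replicates,
        )

        r = canonical_rates(scenario)
        stage_setups = {  # sample size and retained intervals as studied
            "s_juv": (101, 4), "s_sub": (155, 12),
            "s_float": (51, 12), "s_breed": (47, 16),
        }
        rng = np.random.default_rng(77)
        n_rep = 1000
        for key, (n0, t) in stage_setups.items():
            true_s = getattr(r, key)
            n, d = simulate_risk_set_replicates(true_s, n0, t, n_rep, rng)
            ok = 0
            for k in range(n_rep):
                fit = kf.fit_known_fate(
                    kf.RiskSet.from_counts(n[k], d[k]), "constant"
                )
                ann = kf.annual_from_seasonal(fit)
                if ann.SE > 0 and abs(ann.S_hat - true_s) <= 2 * ann.SE:
                    ok += 1
                elif ann.SE == 0 and ann.S_hat == pytest.approx(1.0):
                    # boundary replicate with no deaths at very high S
                    ok += true_s > 0.97
            assert ok >= 0.90 * n_rep, (scenario, key, ok)
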