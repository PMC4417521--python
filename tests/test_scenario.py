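import copy
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crcisim import sample_households
from crcisim.scenario import (
    ScenarioConfig,
    apply_intervention_effect,
    assign_risk_factors,
    clamping_deficit,
    compliance_adjusted_rates,
    simulate_uptake,
)
from crcisim.services import eligibility_table
from crcisim.types import FEMALE, MALE, Household, Person

from conftest import N_LARGE, SEED


class TestInterventionEffect:
    @pytest.mark.parametrize(
        "r,e,expected",
        [(0.765, 0.1, 0.7885), (1.0, 0.3, 1.0), (0.5, 0.0, 0.5), (0.0, 1.0, 1.0)],
    )
    def test_values(self, r, e, expected):
        assert apply_intervention_effect(r, e) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_intervention_effect(1.2, 0.1)
        with pytest.raises(ValueError):
            apply_intervention_effect(0.5, -0.1)

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(r=st.floats(0, 1), e=st.floats(0, 1))
    def test_bounded_and_monotone(self, r, e):
        out = apply_intervention_effect(r, e)
        assert r - 1e-12 <= out <= 1.0 + 1e-12


class TestComplianceRates:
    def test_high_rate_symmetric(self):
        adh, non = compliance_adjusted_rates(0.9)
        assert adh == pytest.approx(0.999)
        assert non == pytest.approx(0.801)
        assert 0.5 * (adh + non) == pytest.approx(0.9)

    def test_low_rate_floored(self):
        adh, non = compliance_adjusted_rates(0.09)
        assert non == 0.0
        assert adh == pytest.approx(0.18)

    def test_full_uptake_unchanged(self):
        assert compliance_adjusted_rates(1.0) == (1.0, 1.0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(r=st.floats(0, 1))
    def test_mixture_mean_preserved(self, r):
        adh, non = compliance_adjusted_rates(r)
        assert 0.0 <= non <= adh <= 1.0
        assert clamping_deficit(r) == pytest.approx(0.0, abs=1e-12)


class TestRiskFactors:
    def _two_adult_households(self, n):
        return [
            Household(i, "Married (at least one < 65), no children",
                      [Person(age=40, sex=FEMALE), Person(age=42, sex=MALE)])
            for i in range(n)
        ]

    def test_zero_prevalence_sets_no_flags(self, spec):
        spec0 = copy.deepcopy(spec)
        for f in spec0.risk_factors.values():
            for key in ("prevalence", "partnered_rate", "teen_rate"):
                if key in f:
                    f[key] = 0.0
        hh = assign_risk_factors(self._two_adult_households(200), spec0, "none", seed=0)
        assert not any(p.smoker or p.diabetic or p.pregnant or p.at_risk_flu
                       for h in hh for p in h)

    def test_out_of_range_prevalence_rejected(self, spec):
        bad = copy.deepcopy(spec)
        bad.risk_factors["smoking"]["prevalence"] = 1.5
        with pytest.raises(ValueError):
            assign_risk_factors(self._two_adult_households(2), bad, "none", seed=0)

    def test_marginal_prevalence_recovered(self, spec, population_20k_flagged):
        people = [p for h in population_20k_flagged for p in h]
        adults = [p for p in people if p.age >= 16]
        p_smoke = spec.risk_factors["smoking"]["prevalence"]
        se = math.sqrt(p_smoke * (1 - p_smoke) / len(adults))
        assert abs(sum(p.smoker for p in adults) / len(adults) - p_smoke) <= 3 * se

    def test_diabetics_always_at_risk(self, population_20k_flagged):
        assert all(
            p.at_risk_flu
            for h in population_20k_flagged
            for p in h
            if p.diabetic
        )

    def test_high_clustering_concordant_and_marginal_preserved(self, spec):
        hh = assign_risk_factors(
            self._two_adult_households(20_000), spec, "high", seed=2
        )
        # all-or-none within household
        assert all(len({p.smoker for p in h}) == 1 for h in hh)
        p_smoke = spec.risk_factors["smoking"]["prevalence"]
        share = np.mean([h.members[0].smoker for h in hh])
        se = math.sqrt(p_smoke * (1 - p_smoke) / len(hh))
        assert abs(share - p_smoke) <= 3 * se

    def test_population_untouched_by_risk_seed(self, spec, population_20k):
        # risk assignment copies; base ages/sexes identical across risk seeds
        a = assign_risk_factors(population_20k[:500], spec, "none", seed=1)
        b = assign_risk_factors(population_20k[:500], spec, "none", seed=99)
        for ha, hb in zip(a, b):
            assert [(p.age, p.sex) for p in ha] == [(p.age, p.sex) for p in hb]


class TestSimulateUptake:
    def _tiny_setup(self, registry, spec):
        hh = sample_households(spec, 400, seed=7)
        hh = assign_risk_factors(hh, spec, "none", seed=7)
        elig = eligibility_table(hh, registry, seed=7)
        return hh, elig

    def test_zero_rate_means_nothing_taken(self, registry, spec):
        hh, elig = self._tiny_setup(registry, spec)
        elig = elig.assign(uptake=0.0)
        cfg = ScenarioConfig(intervention_effect=0.0, n_households=400, seed=7)
        out = simulate_uptake(hh, elig, registry, cfg)
        assert out["taken"].sum() == 0

    def test_full_effect_means_everything_taken(self, registry, spec):
        hh, elig = self._tiny_setup(registry, spec)
        cfg = ScenarioConfig(intervention_effect=1.0, n_households=400, seed=7)
        out = simulate_uptake(hh, elig, registry, cfg, arm="intervention")
        assert out["taken"].sum() == out["count"].sum()

    def test_marginal_uptake_recovery(self, registry, spec, baseline_run, population_20k_flagged):
        hh = population_20k_flagged
        elig = eligibility_table(hh, registry, seed=SEED)
        cfg = ScenarioConfig(intervention_effect=0.0, n_households=N_LARGE, seed=SEED)
        out = simulate_uptake(hh, elig, registry, cfg)
        for svc, grp in out.groupby("service"):
            r = grp["uptake"].iloc[0]
            n = len(grp)
            se = math.sqrt(max(r * (1 - r), 1e-9) / n)
            assert abs(grp["taken"].mean() - r) <= max(3 * se, 1e-9), svc

    def test_compliance_labels_shared_between_arms(self, registry, spec):
        hh, elig = self._tiny_setup(registry, spec)
        cfg = ScenarioConfig(
            intervention_effect=0.2, compliance_clustering="high",
            n_households=400, seed=7,
        )
        out_c = simulate_uptake(hh, elig, registry, cfg, arm="control")
        out_i = simulate_uptake(hh, elig, registry, cfg, arm="intervention")
        # a household's records are adherent in both arms or in neither:
        # adherent rate >= marginal in both, non-adherent <= in both
        merged = out_c[["household_id", "uptake", "rate"]].copy()
        merged["rate_i"] = out_i["rate"]
        up_c = merged["rate"] >= merged["uptake"]
        up_i = merged["rate_i"] >= merged["uptake"].map(
            lambda r: apply_intervention_effect(r, 0.2)
        ) - 1e-12
        assert (up_c == up_i).all()

    def test_determinism(self, registry, spec):
        hh, elig = self._tiny_setup(registry, spec)
        cfg = ScenarioConfig(intervention_effect=0.1, n_households=400, seed=7)
        a = simulate_uptake(hh, elig, registry, cfg, arm="intervention")
        b = simulate_uptake(hh, elig, registry, cfg, arm="intervention")
        pd.testing.assert_frame_equal(a, b)
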