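import itertools
import math

import numpy as np
import pandas as pd
import pytest

from crcisim import (
    compute_crci,
    eligibility_by_household_type,
    exact_expected_crci,
    load_reference_eligibility_table,
    summarize_sample,
    weighted_eligibility_totals,
)
from crcisim.scenario import ScenarioConfig, simulate_uptake
from crcisim.types import FEMALE, MALE, Household, Person


def _records(hid, services_taken):
    """(eligibilities, outcomes) frames for one household given a
    {service: taken} mapping."""
    elig = pd.DataFrame(
        {
            "household_id": hid,
            "person_index": range(len(services_taken)),
            "service": list(services_taken),
            "count": 1,
        }
    )
    out = elig.assign(taken=[int(v) for v in services_taken.values()])
    return elig, out


class TestComputeCrci:
    def test_three_eligibilities_one_taken(self):
        # child eligible for flu, mother for breast + cervical, father for
        # nothing; one service taken -> score 1/3
        elig, out = _records(
            5, {"influenza_child": True, "breast_screen": False, "cervical_screen": False}
        )
        res = compute_crci(elig, out)
        assert (res.numerator, res.denominator) == (1, 3)
        assert res.value == pytest.approx(1 / 3)

    def test_single_service_taken(self):
        elig, out = _records(2, {"cervical_screen": True})
        res = compute_crci(elig, out)
        assert res.value == 1.0

    def test_no_eligibility_is_undefined_not_zero(self):
        elig, out = _records(9, {})
        res = compute_crci(elig, out)
        assert not res.defined
        assert math.isnan(res.value)
        assert (res.numerator, res.denominator) == (0, 0)

    def test_foreign_household_rejected(self):
        elig, _ = _records(1, {"cervical_screen": True})
        _, out = _records(2, {"cervical_screen": True})
        with pytest.raises(ValueError, match="multiple households"):
            compute_crci(elig, out)


def _results_frame(rows):
    return pd.DataFrame(
        rows, columns=["household_id", "household_type", "numerator", "denominator"]
    ).assign(crci=lambda d: np.where(d.denominator > 0, d.numerator / d.denominator.replace(0, 1), np.nan))


class TestSummarize:
    def test_mixed_sample(self):
        frame = _results_frame(
            [(0, "a", 1, 1), (1, "a", 0, 0), (2, "a", 1, 3)]
        )
        s = summarize_sample(frame)
        assert s.valid_fraction == pytest.approx(2 / 3)
        assert s.mean == pytest.approx((1 + 1 / 3) / 2)
        assert s.eligibility_distribution["0"] == pytest.approx(1 / 3)
        assert sum(s.eligibility_distribution.values()) == pytest.approx(1.0)

    def test_all_undefined(self):
        frame = _results_frame([(0, "a", 0, 0), (1, "a", 0, 0)])
        s = summarize_sample(frame)
        assert s.valid_fraction == 0.0
        assert math.isnan(s.mean)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_sample(_results_frame([]))

    def test_scale_invariance(self, baseline_run):
        base = baseline_run.crci_control
        doubled = pd.concat([base, base], ignore_index=True)
        s1, s2 = summarize_sample(base), summarize_sample(doubled)
        assert s1.mean == pytest.approx(s2.mean)
        assert s1.sd == pytest.approx(s2.sd, rel=1e-4)  # ddof-1 at n=20k
        for b in s1.eligibility_distribution:
            assert s1.eligibility_distribution[b] == pytest.approx(
                s2.eligibility_distribution[b]
            )

    def test_valid_fraction_complements_zero_bin(self, baseline_run):
        s = baseline_run.control_summary
        assert s.valid_fraction + s.eligibility_distribution["0"] == pytest.approx(1.0)


class TestEligibilityByType:
    def test_weighted_totals_of_reference_table(self):
        table = load_reference_eligibility_table()
        totals = weighted_eligibility_totals(table)
        assert totals["no_services_pct"] == pytest.approx(11.7, abs=0.1)
        assert totals["one_service_pct"] == pytest.approx(26.4, abs=0.1)
        assert totals["two_services_pct"] == pytest.approx(20.7, abs=0.1)
        assert totals["three_services_pct"] == pytest.approx(15.3, abs=0.1)
        assert totals["four_plus_pct"] == pytest.approx(25.8, abs=0.1)

    def test_single_type_totals_equal_its_shares(self):
        table = pd.DataFrame(
            [
                {
                    "household_type": "only",
                    "prevalence_pct": 100.0,
                    "no_services_pct": 10.0,
                    "one_service_pct": 20.0,
                    "two_services_pct": 30.0,
                    "three_services_pct": 25.0,
                    "four_plus_pct": 15.0,
                }
            ]
        )
        totals = weighted_eligibility_totals(table)
        assert totals["two_services_pct"] == pytest.approx(30.0)

    def test_per_type_breakdown_shape(self, baseline_run):
        by_type = eligibility_by_household_type(baseline_run.crci_control)
        assert by_type["prevalence_pct"].sum() == pytest.approx(100.0)
        shares = by_type[
            ["no_services_pct", "one_service_pct", "two_services_pct",
             "three_services_pct", "four_plus_pct"]
        ].sum(axis=1)
        assert np.allclose(shares, 100.0)


class TestExactOracle:
    def test_degenerate_cases(self):
        assert exact_expected_crci([]) is None
        assert exact_expected_crci([1.0, 1.0]) == pytest.approx((1.0, 0.0))
        mean, var = exact_expected_crci([0.765])
        assert mean == pytest.approx(0.765)
        assert var == pytest.approx(0.765 * 0.235)

    def test_matches_full_enumeration(self):
        rates = [0.682, 0.733, 0.765]
        mean, var = exact_expected_crci(rates)
        # independent brute force over all 2^3 outcomes
        e = v = 0.0
        for outcome in itertools.product([0, 1], repeat=3):
            p = 1.0
            for r, o in zip(rates, outcome):
                p *= r if o else 1 - r
            e += p * sum(outcome) / 3
        for outcome in itertools.product([0, 1], repeat=3):
            p = 1.0
            for r, o in zip(rates, outcome):
                p *= r if o else 1 - r
            v += p * (sum(outcome) / 3 - e) ** 2
        assert mean == pytest.approx(e)
        assert var == pytest.approx(v)

    def test_monte_carlo_agreement(self, registry):
        """Replicated uptake draws through the simulation machinery converge
        to the enumerated expectation for a fixed household fixture."""
        households = [
            Household(0, "t", [Person(age=67, sex=FEMALE)]),
            Household(1, "t", [Person(age=30, sex=FEMALE)]),
        ]
        rates = {"breast_screen": 0.733, "influenza_65plus": 0.682,
                 "cervical_screen": 0.765}
        elig = pd.DataFrame(
            {
                "household_id": [0, 0, 1],
                "household_type": "t",
                "person_index": 0,
                "service": ["breast_screen", "influenza_65plus", "cervical_screen"],
                "count": 1,
                "uptake": [rates["breast_screen"], rates["influenza_65plus"],
                           rates["cervical_screen"]],
            }
        )
        n_rep = 10_000
        sums = {0: 0.0, 1: 0.0}
        for rep in range(n_rep):
            cfg = ScenarioConfig(intervention_effect=0.0, n_households=2, seed=rep)
            out = simulate_uptake(households, elig, registry, cfg)
            taken = out["taken"].to_numpy()
            sums[0] += (taken[0] + taken[1]) / 2
            sums[1] += taken[2]
        for hid, svc_rates in ((0, [0.733, 0.682]), (1, [0.765])):
            mean, var = exact_expected_crci(svc_rates)
            mc = sums[hid] / n_rep
            se = math.sqrt(var / n_rep)
            assert abs(mc - mean) <= 3 * se, hid
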