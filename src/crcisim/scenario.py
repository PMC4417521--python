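"""Risk-factor allocation, uptake-rate transforms, and uptake draws.

Three transforms act on a service's baseline uptake rate ``r``:

* the intervention effect ``e`` (the fraction of otherwise-forgone services
  taken up because of the community-health-worker visits) maps
  ``r -> r + e * (1 - r)``;
* household compliance clustering splits the population 50/50 into
  generally-adherent households (``r -> r + 0.99 * (1 - r)``) and
  generally-non-adherent ones (``r -> r - 0.99 * (1 - r)``, floored at 0
  with the adherent rate capped so the 50/50 mixture mean is preserved);
* each eligibility record's outcome is then a Bernoulli draw at the
  transformed rate.

Risk factors (smoking, diabetes, at-risk-for-influenza, pregnancy) are
allocated by Bernoulli draws at age/sex-band prevalences.  Under "high"
risk clustering, smoking/diabetes/at-risk become all-or-none at household
level (every band-eligible member shares the factor), with the household
probability equal to the per-person prevalence so each person's marginal is
unchanged - the most extreme within-household concordance consistent with
the stated marginals.  Pregnancy is always per-person.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .demographics import DemographicSpec
from .rng import stream
from .services import ServiceDefinition
from .types import CHILDBEARING_BAND, FEMALE, Household

__all__ = [
    "ScenarioConfig",
    "assign_risk_factors",
    "apply_intervention_effect",
    "compliance_adjusted_rates",
    "clamping_deficit",
    "simulate_uptake",
    "outcomes_export_frame",
]

CLUSTERING_MODES = ("none", "high")

#: Household types whose first two members form a married/cohabiting couple;
#: pregnancy hazard is constant among their childbearing-age female partners.
_PARTNERED_PREFIXES = ("Married", "Same-sex partnerships")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: effect size, clustering modes, scale, seed."""

    intervention_effect: float = 0.0
    risk_clustering: str = "none"
    compliance_clustering: str = "none"
    compliant_household_share: float = 0.5
    n_households: int = 20_000
    seed: int = 0
    period_years: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.intervention_effect <= 1.0):
            raise ValueError("intervention_effect must be in [0, 1]")
        if self.risk_clustering not in CLUSTERING_MODES:
            raise ValueError(f"risk_clustering must be one of {CLUSTERING_MODES}")
        if self.compliance_clustering not in CLUSTERING_MODES:
            raise ValueError(f"compliance_clustering must be one of {CLUSTERING_MODES}")
        if not (0.0 <= self.compliant_household_share <= 1.0):
            raise ValueError("compliant_household_share must be in [0, 1]")
        if self.n_households < 1:
            raise ValueError("n_households must be >= 1")
        if self.period_years <= 0:
            raise ValueError("period_years must be positive")


def _band_eligible(age: int, cfg: dict) -> bool:
    return cfg.get("min_age", 0) <= age <= cfg.get("max_age", 105)


def assign_risk_factors(
    households: list[Household],
    spec: DemographicSpec,
    mode: str = "none",
    seed: int = 0,
) -> list[Household]:
    """Return a deep copy of the population with risk flags assigned.

    ``mode="none"`` draws independently per person; ``mode="high"`` makes
    smoking, diabetes and the extra at-risk factor all-or-none within each
    household.  Diabetes always implies the at-risk-influenza flag.
    Pregnancy is assigned per person: a constant hazard among female
    partners of childbearing age in couple households plus a smaller
    teenage allowance elsewhere.
    """
    if mode not in CLUSTERING_MODES:
        raise ValueError(f"mode must be one of {CLUSTERING_MODES}")
    rf = spec.risk_factors
    for fname in ("smoking", "diabetes", "at_risk_extra"):
        p = rf.get(fname, {}).get("prevalence", 0.0)
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"risk_factors[{fname!r}].prevalence outside [0, 1]")
    rng = stream(seed, "risk")
    preg = rf.get("pregnancy", {})
    lo_cb, hi_cb = CHILDBEARING_BAND
    out: list[Household] = []
    for hh in households:
        if mode == "high":
            hh_draws = {
                f: rng.random() < rf.get(f, {}).get("prevalence", 0.0)
                for f in ("smoking", "diabetes", "at_risk_extra")
            }
        members = []
        for idx, person in enumerate(hh):
            flags = {}
            for fname, flag in (
                ("smoking", "smoker"),
                ("diabetes", "diabetic"),
                ("at_risk_extra", "at_risk_flu"),
            ):
                cfg = rf.get(fname, {})
                p = cfg.get("prevalence", 0.0)
                if not _band_eligible(person.age, cfg):
                    flags[flag] = False
                elif mode == "high":
                    flags[flag] = hh_draws[fname]
                else:
                    flags[flag] = bool(rng.random() < p)
            pregnant = False
            if person.sex == FEMALE and lo_cb <= person.age <= hi_cb:
                partnered = (
                    hh.household_type.startswith(_PARTNERED_PREFIXES) and idx < 2
                )
                rate = preg.get("partnered_rate", 0.0) if partnered else (
                    preg.get("teen_rate", 0.0) if person.age <= 19 else 0.0
                )
                pregnant = bool(rng.random() < rate)
            diabetic = flags["diabetic"]
            members.append(
                replace(
                    person,
                    smoker=flags["smoker"],
                    diabetic=diabetic,
                    pregnant=pregnant,
                    at_risk_flu=flags["at_risk_flu"] or diabetic,
                )
            )
        out.append(
            Household(
                household_id=hh.household_id,
                household_type=hh.household_type,
                members=members,
            )
        )
    return out


def apply_intervention_effect(r: float, e: float) -> float:
    """Uptake rate under an intervention taking up a fraction ``e`` of
    otherwise-forgone services: ``r + e * (1 - r)``."""
    if not (0.0 <= r <= 1.0):
        raise ValueError("uptake rate r must be in [0, 1]")
    if not (0.0 <= e <= 1.0):
        raise ValueError("intervention effect e must be in [0, 1]")
    return r + e * (1.0 - r)


def compliance_adjusted_rates(r: float) -> tuple[float, float]:
    """(adherent, non-adherent) uptake rates under strong household
    compliance clustering.

    The non-adherent rate ``r - 0.99 * (1 - r)`` is floored at 0 (the
    modification needed for rates below 50%); the adherent rate is then
    ``min(1, 2r - r_nonadherent)`` so a 50/50 household mixture preserves
    the marginal rate.
    """
    if not (0.0 <= r <= 1.0):
        raise ValueError("uptake rate r must be in [0, 1]")
    r_non = max(0.0, r - 0.99 * (1.0 - r))
    r_adh = min(1.0, 2.0 * r - r_non)
    return r_adh, r_non


def clamping_deficit(r: float) -> float:
    """Shortfall of the 50/50 compliance mixture mean below ``r`` (zero
    whenever the adherent-rate cap at 1 is not binding)."""
    r_adh, r_non = compliance_adjusted_rates(r)
    return r - 0.5 * (r_adh + r_non)


def simulate_uptake(
    households: list[Household],
    eligibilities: pd.DataFrame,
    registry: list[ServiceDefinition],
    config: ScenarioConfig,
    seed: int | None = None,
    arm: str | None = None,
) -> pd.DataFrame:
    """Draw uptake outcomes for every eligibility record.

    Returns the eligibility table with two extra columns: ``rate`` (the
    transformed per-record uptake probability) and ``taken`` (0/1 Bernoulli
    outcome).  Control and intervention arms use separate child streams of
    the root seed, while household compliance labels come from their own
    stream so both arms see the same adherent/non-adherent households.
    """
    if seed is None:
        seed = config.seed
    if arm is None:
        arm = "control" if config.intervention_effect == 0 else "intervention"
    if arm not in ("control", "intervention"):
        raise ValueError("arm must be 'control' or 'intervention'")

    out = eligibilities.copy()
    if out.empty:
        out["rate"] = pd.Series(dtype=float)
        out["taken"] = pd.Series(dtype=int)
        return out

    rates = out["uptake"].to_numpy(dtype=float)
    if (rates < 0).any() or (rates > 1).any():
        raise ValueError("eligibility table contains uptake rates outside [0, 1]")
    e = config.intervention_effect if arm == "intervention" else 0.0
    rates = rates + e * (1.0 - rates)

    if config.compliance_clustering == "high":
        comp_rng = stream(seed, "compliance")
        labels = {
            hh.household_id: comp_rng.random() < config.compliant_household_share
            for hh in households
        }
        adherent = out["household_id"].map(labels).to_numpy(dtype=bool)
        adj = np.array([compliance_adjusted_rates(r) for r in rates])
        rates = np.where(adherent, adj[:, 0], adj[:, 1])

    draw_rng = stream(seed, f"uptake_{arm}")
    taken = (draw_rng.random(len(rates)) < rates).astype(int)
    out["rate"] = rates
    out["taken"] = taken * out["count"].to_numpy()
    return out


def outcomes_export_frame(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Uptake outcomes in the export column layout (one row per person and
    service: household_id, person_index, service, eligible_count,
    taken_count)."""
    return outcomes.rename(
        columns={"count": "eligible_count", "taken": "taken_count"}
    )[["household_id", "person_index", "service", "eligible_count", "taken_count"]]
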