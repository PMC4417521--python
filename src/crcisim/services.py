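"""The preventive-service registry and per-person eligibility decisions.

Each :class:`ServiceDefinition` encodes one NHS-style preventive service: an
inclusive age band, an optional sex filter, an optional risk-flag
requirement, a screening interval ``k`` in years, and a baseline uptake rate
``r``.  The shipped default registry mirrors the published North Wales
schedule: infant and preschool immunisations, childhood and adult seasonal
influenza, HPV, cervical/breast/bowel cancer screening, diabetic retinal
screening, pregnancy influenza, and smoking-cessation clinics.  Chlamydia
screening is carried in the registry but excluded from the composite score
(its records are confidential and not obtainable from routine data), so it
never produces eligibility records.

Multi-year screening programmes (cervical every 3 years, bowel every 2)
make only part of the eligible age band due in any single study year; the
annual eligibility fraction combines the schedule share ``1/k``, the
fraction newly entering the age band (all due), and previous non-attenders
(all still due).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .rng import stream
from .types import FEMALE, MALE, Household, Person

__all__ = [
    "ServiceDefinition",
    "EligibilityRecord",
    "default_registry",
    "load_registry",
    "registry_to_frame",
    "frame_to_registry",
    "annual_eligibility_fraction",
    "eligible_services",
    "eligibility_table",
]

RISK_PREDICATES = ("none", "smoker", "diabetic", "pregnant", "at_risk_flu")


@dataclass(frozen=True)
class ServiceDefinition:
    """One preventive service: who is eligible and how often they take it up."""

    name: str
    min_age: int
    max_age: int
    sex_filter: str = "any"  # female | male | any
    risk_predicate: str = "none"
    interval_years: int = 1
    baseline_uptake: float = 0.0
    included_in_crci: bool = True
    estimated: bool = False
    exclusion_group: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.baseline_uptake <= 1.0):
            raise ValueError(f"{self.name}: uptake {self.baseline_uptake} outside [0,1]")
        if self.min_age > self.max_age:
            raise ValueError(f"{self.name}: min_age > max_age")
        if self.interval_years < 1:
            raise ValueError(f"{self.name}: interval_years must be >= 1")
        if self.sex_filter not in ("any", FEMALE, MALE):
            raise ValueError(f"{self.name}: bad sex_filter {self.sex_filter!r}")
        if self.risk_predicate not in RISK_PREDICATES:
            raise ValueError(f"{self.name}: bad risk_predicate {self.risk_predicate!r}")

    def matches(self, person: Person) -> bool:
        """Age/sex/risk eligibility of a person, before any interval draw."""
        if not (self.min_age <= person.age <= self.max_age):
            return False
        if self.sex_filter != "any" and person.sex != self.sex_filter:
            return False
        if self.risk_predicate != "none" and not getattr(person, self.risk_predicate):
            return False
        return True

    @property
    def band_width_years(self) -> int:
        return self.max_age - self.min_age + 1

    def annual_entry_fraction(self) -> float:
        """Fraction of the eligible band newly entering it each year (1/width)."""
        return 1.0 / self.band_width_years


@dataclass(frozen=True)
class EligibilityRecord:
    """One person's eligibility for one score-eligible service in the period."""

    household_id: int
    person_index: int
    service: str
    count: int = 1


def annual_eligibility_fraction(k: int, f_new: float, r: float) -> float:
    """Probability a person in a ``k``-yearly programme's age band is due the
    service in a single year.

    New entrants to the age band (fraction ``f_new``) are all due; of the
    rest, ``1/k`` are due on schedule, and of those not due on schedule a
    fraction ``1 - r`` did not attend previously and so remain due.  The
    result is clamped to [0, 1].
    """
    if k < 1:
        raise ValueError("interval k must be >= 1")
    if not (0.0 <= f_new <= 1.0):
        raise ValueError("f_new must be in [0, 1]")
    if not (0.0 <= r <= 1.0):
        raise ValueError("uptake r must be in [0, 1]")
    p = f_new + (1.0 - f_new) * (1.0 / k + (1.0 - 1.0 / k) * (1.0 - r))
    return float(min(1.0, max(0.0, p)))


def _coerce_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in ("true", "1", "yes")


def frame_to_registry(frame: pd.DataFrame) -> list[ServiceDefinition]:
    out = []
    for row in frame.itertuples():
        group = getattr(row, "exclusion_group", None)
        if group is not None and (pd.isna(group) or str(group).strip() == ""):
            group = None
        out.append(
            ServiceDefinition(
                name=str(row.name),
                min_age=int(row.min_age),
                max_age=int(row.max_age),
                sex_filter=str(row.sex),
                risk_predicate=str(row.risk_predicate),
                interval_years=int(row.interval_years),
                baseline_uptake=float(row.uptake),
                included_in_crci=_coerce_bool(row.included_in_crci),
                estimated=_coerce_bool(getattr(row, "estimated", False)),
                exclusion_group=str(group) if group is not None else None,
            )
        )
    return out


def registry_to_frame(registry: list[ServiceDefinition]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [s.name for s in registry],
            "min_age": [s.min_age for s in registry],
            "max_age": [s.max_age for s in registry],
            "sex": [s.sex_filter for s in registry],
            "risk_predicate": [s.risk_predicate for s in registry],
            "interval_years": [s.interval_years for s in registry],
            "uptake": [s.baseline_uptake for s in registry],
            "included_in_crci": [s.included_in_crci for s in registry],
            "estimated": [s.estimated for s in registry],
            "exclusion_group": [s.exclusion_group or "" for s in registry],
        }
    )


def load_registry(path: str | Path | None = None) -> list[ServiceDefinition]:
    """Load a registry CSV; ``None``/"default" loads the shipped schedule."""
    if path is None or path == "default":
        text = (
            resources.files("crcisim.data")
            .joinpath("default_registry.csv")
            .read_text(encoding="utf-8")
        )
        frame = pd.read_csv(io.StringIO(text))
    else:
        frame = pd.read_csv(path)
    return frame_to_registry(frame)


def default_registry() -> list[ServiceDefinition]:
    """The shipped service registry (published uptake rates; new programmes
    without published rates carry estimated, flagged rates)."""
    return load_registry(None)


def service_lookup(registry: list[ServiceDefinition]) -> dict[str, ServiceDefinition]:
    return {s.name: s for s in registry}


def _inclusion_probability(svc: ServiceDefinition) -> float:
    if svc.interval_years == 1:
        return 1.0
    return annual_eligibility_fraction(
        svc.interval_years, svc.annual_entry_fraction(), svc.baseline_uptake
    )


def eligible_services(
    person: Person,
    registry: list[ServiceDefinition],
    period_years: float = 1.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    household_id: int = 0,
    person_index: int = 0,
) -> list[EligibilityRecord]:
    """Eligibility records for one person over the study period.

    Services excluded from the composite score never yield records.  Within
    an exclusion group (the influenza family) only the first matching
    service in registry order applies, so nobody is counted due two flu
    vaccinations.  Services with interval ``k > 1`` are included by a
    Bernoulli draw with the annual eligibility fraction.
    """
    if rng is None:
        rng = stream(0 if seed is None else seed, "eligibility")
    if period_years <= 0:
        raise ValueError("period_years must be positive")
    taken_groups: set[str] = set()
    records: list[EligibilityRecord] = []
    for svc in registry:
        if not svc.included_in_crci or not svc.matches(person):
            continue
        if svc.exclusion_group:
            if svc.exclusion_group in taken_groups:
                continue
            taken_groups.add(svc.exclusion_group)
        p = _inclusion_probability(svc)
        if p < 1.0 and rng.random() >= p:
            continue
        records.append(
            EligibilityRecord(
                household_id=household_id,
                person_index=person_index,
                service=svc.name,
                count=1,
            )
        )
    return records


def eligibility_table(
    households: list[Household],
    registry: list[ServiceDefinition],
    period_years: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Population-level eligibility: one row per (person, service) with the
    service's baseline uptake rate attached.

    Columns: household_id, household_type, person_index, service, count,
    uptake.  Households with no eligible member still matter downstream (the
    composite score is undefined for them), so callers must not assume every
    household appears here.
    """
    rng = stream(seed, "eligibility")
    rows: list[tuple] = []
    rates = {s.name: s.baseline_uptake for s in registry}
    for hh in households:
        for i, person in enumerate(hh):
            for rec in eligible_services(
                person,
                registry,
                period_years,
                rng=rng,
                household_id=hh.household_id,
                person_index=i,
            ):
                rows.append(
                    (rec.household_id, hh.household_type, rec.person_index,
                     rec.service, rec.count, rates[rec.service])
                )
    return pd.DataFrame(
        rows,
        columns=["household_id", "household_type", "person_index",
                 "service", "count", "uptake"],
    )
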