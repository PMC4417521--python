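"""Synthesis of household populations from a demographic specification.

The synthesizer is driven entirely by a :class:`DemographicSpec`: a set of
census-style household types (single occupancy, married/cohabiting couples
with and without children, lone parents, same-sex partnerships, student and
other households), each with a prevalence and a composition rule, plus
risk-factor prevalences by age/sex band.  Households are sampled type-first
(one categorical draw per household) and then composed member by member
according to the type's rule: reference-adult ages come from band
distributions, partner ages from the reference age plus a symmetric
triangular gap, parent ages from the youngest child's age plus a
mother's-age-at-birth draw, and sibling ages from uniform 1-4 year spacings.

A default specification calibrated to the 2011 England and Wales census
household-type distribution ships with the package; pass your own file to
model a different population (for example a deprived area with more lone
parents).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .rng import stream
from .types import FEMALE, MALE, MAX_HOUSEHOLD_SIZE, Household, Person

__all__ = [
    "AGE_SEX_BANDS",
    "DemographicSpec",
    "SpecValidationError",
    "load_demographic_spec",
    "sample_households",
    "population_marginals",
    "population_to_frame",
    "frame_to_households",
]

#: The 20 census household-type categories every spec must cover.
CANONICAL_HOUSEHOLD_TYPES = (
    "Single person (16 to 64)",
    "Single person (65 plus)",
    "Married (at least one < 65), no children",
    "Married (65 plus), no children",
    "Married with one dependent child",
    "Married with two or more dependent children",
    "Married with only non-dependent child(ren)",
    "Lone mothers with one dependent child",
    "Lone mothers with two or more dependent children",
    "Lone mothers with only non-dependent child(ren)",
    "Lone fathers with one dependent child",
    "Lone fathers with two or more dependent children",
    "Lone fathers with only non-dependent child(ren)",
    "Same-sex partnerships, no children",
    "Same-sex partnerships with child(ren)",
    "Other households with one dependent child",
    "Other households with more than one dependent child",
    "Student households, all students",
    "Other households (all 65 plus)",
    "Other households (not all 65 plus)",
)

#: Exhaustive age/sex partition used for population marginals: single years
#: for infants, unisex child/youth bands, and sex-specific adult bands.
AGE_SEX_BANDS: tuple[tuple[str, int, int, str | None], ...] = (
    ("Baby 0 to 11 months", 0, 0, None),
    ("Infant 12 to 23 months", 1, 1, None),
    ("Infant 2 years", 2, 2, None),
    ("Infant 3 years", 3, 3, None),
    ("Child 4 to 15 years", 4, 15, None),
    ("Youth 16 to 19 years", 16, 19, None),
    ("Female 20 to 25 years", 20, 25, FEMALE),
    ("Female 26 to 49 years", 26, 49, FEMALE),
    ("Female 50 to 59 years", 50, 59, FEMALE),
    ("Female 60 to 64 years", 60, 64, FEMALE),
    ("Female 65 to 70 years", 65, 70, FEMALE),
    ("Female 71 to 74 years", 71, 74, FEMALE),
    ("Female 75 years plus", 75, 105, FEMALE),
    ("Male 20 to 25 years", 20, 25, MALE),
    ("Male 26 to 59 years", 26, 59, MALE),
    ("Male 60 to 64 years", 60, 64, MALE),
    ("Male 65 to 70 years", 65, 70, MALE),
    ("Male 71 to 74 years", 71, 74, MALE),
    ("Male 75 years plus", 75, 105, MALE),
)


class SpecValidationError(ValueError):
    """A demographic specification failed validation; the message names the field."""


def _parse_band(label: str) -> tuple[int, int]:
    lo, _, hi = label.partition("-")
    try:
        lo_i, hi_i = int(lo), int(hi)
    except ValueError:
        raise SpecValidationError(f"malformed age band {label!r}") from None
    if lo_i > hi_i:
        raise SpecValidationError(f"age band {label!r} has lo > hi")
    return lo_i, hi_i


def _check_dist(name: str, dist: dict[str, float]) -> None:
    if not dist:
        raise SpecValidationError(f"{name}: empty distribution")
    vals = list(dist.values())
    if any(v < 0 for v in vals):
        raise SpecValidationError(f"{name}: negative probability")
    if abs(sum(vals) - 1.0) > 1e-9:
        raise SpecValidationError(f"{name}: probabilities sum to {sum(vals):.6f}, not 1")


def _draw_cat(rng: np.random.Generator, dist: dict[str, float]) -> str:
    keys = list(dist)
    probs = np.fromiter(dist.values(), dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _draw_age(rng: np.random.Generator, age_dist: dict[str, float]) -> int:
    lo, hi = _parse_band(_draw_cat(rng, age_dist))
    return int(rng.integers(lo, hi + 1))


@dataclass
class DemographicSpec:
    """Validated demographic specification driving household synthesis.

    ``household_types`` maps each canonical type to ``{"prevalence": p,
    "rule": {...}}``; ``defaults`` holds shared composition parameters
    (partner age gap, mother's age at birth, sibling spacing, dependent-child
    age cap, child sex ratio); ``risk_factors`` holds per-factor prevalences
    with their eligible age bands.
    """

    household_types: dict[str, dict[str, Any]]
    defaults: dict[str, Any]
    risk_factors: dict[str, Any]
    spec_version: str = "1"
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def type_prevalences(self) -> dict[str, float]:
        return {t: cfg["prevalence"] for t, cfg in self.household_types.items()}

    def validate(self) -> None:
        missing = [t for t in CANONICAL_HOUSEHOLD_TYPES if t not in self.household_types]
        if missing:
            raise SpecValidationError(f"household_types: missing {missing}")
        total = 0.0
        for t, cfg in self.household_types.items():
            p = cfg.get("prevalence")
            if p is None or p < 0:
                raise SpecValidationError(f"household_types[{t!r}].prevalence invalid")
            total += p
            rule = cfg.get("rule")
            if not isinstance(rule, dict) or "structure" not in rule:
                raise SpecValidationError(f"household_types[{t!r}].rule missing structure")
            for key, val in rule.items():
                if key.endswith("_dist"):
                    _check_dist(f"household_types[{t!r}].rule.{key}", val)
                if isinstance(val, dict):
                    for sub, subval in val.items():
                        if sub.endswith("_dist"):
                            _check_dist(
                                f"household_types[{t!r}].rule.{key}.{sub}", subval
                            )
        if abs(total - 1.0) > 1e-9:
            raise SpecValidationError(
                f"household_types: prevalences sum to {total:.6f}, not 1"
            )
        for fname, cfg in self.risk_factors.items():
            for key in ("prevalence", "partnered_rate", "teen_rate"):
                if key in cfg and not (0.0 <= cfg[key] <= 1.0):
                    raise SpecValidationError(
                        f"risk_factors[{fname!r}].{key} outside [0, 1]"
                    )

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "DemographicSpec":
        return cls(
            household_types=payload["household_types"],
            defaults=payload.get("defaults", {}),
            risk_factors=payload.get("risk_factors", {}),
            spec_version=str(payload.get("spec_version", "1")),
            notes=payload.get("notes", {}),
        )


def load_demographic_spec(path: str | Path | None = None) -> DemographicSpec:
    """Load and validate a demographic spec; ``None``/"default" loads the
    shipped England-and-Wales-calibrated fixture."""
    if path is None or path == "default":
        text = (
            resources.files("crcisim.data")
            .joinpath("default_demographics.json")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    return DemographicSpec.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Composition engine
# ---------------------------------------------------------------------------


def _triangular_gap(rng: np.random.Generator, half_range: int) -> int:
    # Discrete symmetric triangular around 0: sum of two uniforms.
    a = rng.integers(-half_range, 1)
    b = rng.integers(0, half_range + 1)
    return int(a + b)


def _sample_children(
    rng: np.random.Generator, rule: dict, defaults: dict
) -> list[int]:
    """Ages of dependent children: youngest from a band distribution, older
    siblings from uniform spacings, capped at the dependent-age limit."""
    cfg = rule.get("dependent_children")
    if not cfg:
        return []
    count = int(_draw_cat(rng, cfg["count_dist"]))
    youngest = _draw_age(rng, cfg["youngest_age_dist"])
    cap = int(defaults.get("dependent_child_max_age", 17))
    youngest = min(youngest, cap)
    spacing = defaults.get("sibling_spacing", {"min": 1, "max": 4})
    lo, hi = spacing["min"], spacing["max"]
    ages = [youngest]
    for _ in range(count - 1):
        ages.append(min(ages[-1] + int(rng.integers(lo, hi + 1)), cap))
    return ages


def _sample_nondependent(rng: np.random.Generator, rule: dict) -> list[int]:
    cfg = rule.get("nondependent_children")
    if not cfg:
        return []
    count = int(_draw_cat(rng, cfg["count_dist"]))
    return sorted(_draw_age(rng, cfg["age_dist"]) for _ in range(count))


def _mother_age(rng: np.random.Generator, anchor_child_age: int, defaults: dict) -> int:
    birth = defaults.get("mother_age_at_birth", {"min": 20, "max": 40})
    return anchor_child_age + int(rng.integers(birth["min"], birth["max"] + 1))


def _child_sex(rng: np.random.Generator, defaults: dict) -> str:
    share = defaults.get("child_sex_female_share", 0.487)
    return FEMALE if rng.random() < share else MALE


def _compose(
    rng: np.random.Generator, htype: str, rule: dict, defaults: dict
) -> list[Person]:
    structure = rule["structure"]
    dep_ages = _sample_children(rng, rule, defaults)
    nondep_ages = _sample_nondependent(rng, rule)
    members: list[Person] = []

    if structure in ("single", "lone_parent", "couple"):
        if dep_ages:
            ref_age = _mother_age(rng, min(dep_ages), defaults)
        elif nondep_ages:
            ref_age = _mother_age(rng, max(nondep_ages), defaults)
        else:
            ref_age = _draw_age(rng, rule["adult_age_dist"])
        if structure == "couple":
            if rule.get("same_sex"):
                sex = FEMALE if rng.random() < rule.get("sex_female_share", 0.5) else MALE
                ref_sex = partner_sex = sex
            else:
                ref_sex, partner_sex = FEMALE, MALE
            gap_cfg = defaults.get("partner_age_gap", {"half_range": 10})
            partner_age = ref_age + _triangular_gap(rng, int(gap_cfg["half_range"]))
            floor = int(rule.get("partner_min_age", 16))
            partner_age = int(np.clip(partner_age, floor, 105))
            members.append(Person(age=min(ref_age, 105), sex=ref_sex))
            members.append(Person(age=partner_age, sex=partner_sex))
        else:
            share = rule.get("sex_female_share", 0.5)
            sex = FEMALE if rng.random() < share else MALE
            members.append(Person(age=min(ref_age, 105), sex=sex))
    elif structure == "group":
        cfg = rule["adults"]
        count = int(_draw_cat(rng, cfg["count_dist"]))
        share = cfg.get("sex_female_share", 0.5)
        for _ in range(count):
            sex = FEMALE if rng.random() < share else MALE
            members.append(Person(age=_draw_age(rng, cfg["age_dist"]), sex=sex))
    else:  # pragma: no cover - blocked by validation
        raise SpecValidationError(f"unknown structure {structure!r}")

    extra = rule.get("extra_adults")
    if extra:
        count = int(_draw_cat(rng, extra["count_dist"]))
        share = extra.get("sex_female_share", 0.5)
        for _ in range(count):
            sex = FEMALE if rng.random() < share else MALE
            members.append(Person(age=_draw_age(rng, extra["age_dist"]), sex=sex))

    for age in nondep_ages:
        members.append(Person(age=age, sex=_child_sex(rng, defaults)))
    for age in dep_ages:
        members.append(Person(age=age, sex=_child_sex(rng, defaults)))

    return members[:MAX_HOUSEHOLD_SIZE]


def check_household(hh: Household, rule: dict) -> list[str]:
    """Structural-consistency violations of a household against its type rule
    (empty list = valid)."""
    problems: list[str] = []
    if not (1 <= hh.size <= MAX_HOUSEHOLD_SIZE):
        problems.append(f"size {hh.size} outside bounds")
    structure = rule["structure"]
    if structure == "single" and hh.size != 1:
        problems.append("single-person type with more than one member")
    if structure == "couple" and hh.size < 2:
        problems.append("couple type with fewer than two members")
    if "all_min_age" in rule and any(p.age < rule["all_min_age"] for p in hh):
        problems.append(f"member younger than {rule['all_min_age']}")
    if "any_max_age" in rule and all(p.age > rule["any_max_age"] for p in hh):
        problems.append(f"no member aged <= {rule['any_max_age']}")
    dep_cfg = rule.get("dependent_children")
    if dep_cfg:
        min_count = min(int(k) for k in dep_cfg["count_dist"])
        cap = 17
        n_dep = sum(1 for p in hh if p.age <= cap)
        if n_dep < min_count:
            problems.append(f"expected >= {min_count} dependent children, found {n_dep}")
    return problems


def sample_households(
    spec: DemographicSpec, n: int, seed: int
) -> list[Household]:
    """Draw ``n`` households: a categorical type draw per household, then the
    type's composition rule.  Identical ``(spec, n, seed)`` gives an identical
    population; the stream is independent of scenario-stage draws."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = stream(seed, "demographics")
    types = list(spec.household_types)
    probs = np.array([spec.household_types[t]["prevalence"] for t in types])
    probs = probs / probs.sum()
    type_idx = rng.choice(len(types), size=n, p=probs)
    defaults = spec.defaults
    out = []
    for hid, ti in enumerate(type_idx):
        htype = types[ti]
        rule = spec.household_types[htype]["rule"]
        # Rejection-sample the rare compositions that violate a type's age
        # constraint (e.g. an all-elderly draw for a "not all 65 plus" type).
        for _ in range(100):
            members = _compose(rng, htype, rule, defaults)
            hh = Household(household_id=hid, household_type=htype, members=members)
            if not check_household(hh, rule):
                break
        out.append(hh)
    return out


# ---------------------------------------------------------------------------
# Marginals and CSV round-trip
# ---------------------------------------------------------------------------


def band_of(age: int, sex: str) -> str:
    """Name of the age/sex band containing this person."""
    for name, lo, hi, band_sex in AGE_SEX_BANDS:
        if lo <= age <= hi and (band_sex is None or band_sex == sex):
            return name
    raise ValueError(f"no band for age={age}, sex={sex}")


def population_marginals(households: Sequence[Household]) -> pd.DataFrame:
    """Per-band individual shares and household presence shares.

    Individual shares sum to 1 over the exhaustive age/sex partition; the
    household share of a band is the fraction of households with at least one
    member in it.
    """
    if not households:
        raise ValueError("population_marginals requires a non-empty collection")
    n_people = sum(h.size for h in households)
    n_hh = len(households)
    rows = []
    for name, lo, hi, band_sex in AGE_SEX_BANDS:
        in_band = lambda p: lo <= p.age <= hi and (band_sex is None or p.sex == band_sex)
        count = sum(1 for h in households for p in h if in_band(p))
        hh_count = sum(1 for h in households if any(in_band(p) for p in h))
        rows.append(
            {
                "band": name,
                "individual_share": count / n_people,
                "household_share": hh_count / n_hh,
            }
        )
    return pd.DataFrame(rows)


def population_to_frame(households: Iterable[Household]) -> pd.DataFrame:
    """One row per person: household_id, household_type, person_index, age,
    sex and the four risk flags."""
    rows = []
    for h in households:
        for i, p in enumerate(h):
            rows.append(
                {
                    "household_id": h.household_id,
                    "household_type": h.household_type,
                    "person_index": i,
                    "age": p.age,
                    "sex": p.sex,
                    "smoker": p.smoker,
                    "diabetic": p.diabetic,
                    "pregnant": p.pregnant,
                    "at_risk_flu": p.at_risk_flu,
                }
            )
    return pd.DataFrame(rows)


def frame_to_households(frame: pd.DataFrame) -> list[Household]:
    """Inverse of :func:`population_to_frame`."""
    out = []
    for hid, grp in frame.groupby("household_id", sort=True):
        grp = grp.sort_values("person_index")
        members = [
            Person(
                age=int(r.age),
                sex=str(r.sex),
                smoker=bool(r.smoker),
                diabetic=bool(r.diabetic),
                pregnant=bool(r.pregnant),
                at_risk_flu=bool(r.at_risk_flu),
            )
            for r in grp.itertuples()
        ]
        out.append(
            Household(
                household_id=int(hid),
                household_type=str(grp.iloc[0]["household_type"]),
                members=members,
            )
        )
    return out
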