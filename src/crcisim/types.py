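"""Core domain types: people, households, and the constants that bind them.

A *household* is one or more people living at one postal address; it is the
unit at which the composite uptake score is defined and at which the
community-health-worker intervention is delivered.  A *person* carries the
age, sex and risk-factor flags that drive service eligibility.  People who
move in or out of a household during the study period are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

MAX_HOUSEHOLD_SIZE = 8
MAX_AGE = 105

FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)

#: Age band (inclusive) within which pregnancy may be assigned.
CHILDBEARING_BAND = (16, 44)


@dataclass
class Person:
    """An individual; the unit of service eligibility.

    Risk flags default to ``False`` and are set later by
    :func:`crcisim.scenario.assign_risk_factors`.  A diabetic person is
    always also flagged at risk for seasonal influenza.
    """

    age: int
    sex: str
    smoker: bool = False
    diabetic: bool = False
    pregnant: bool = False
    at_risk_flu: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.age <= MAX_AGE):
            raise ValueError(f"age {self.age} outside [0, {MAX_AGE}]")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        self._check_flags()

    def _check_flags(self) -> None:
        if self.pregnant:
            lo, hi = CHILDBEARING_BAND
            if self.sex != FEMALE or not (lo <= self.age <= hi):
                raise ValueError(
                    "pregnant flag requires a female in the childbearing band"
                )
        if self.diabetic and not self.at_risk_flu:
            raise ValueError("diabetic persons must be flagged at_risk_flu")

    def with_flags(
        self,
        *,
        smoker: bool | None = None,
        diabetic: bool | None = None,
        pregnant: bool | None = None,
        at_risk_flu: bool | None = None,
    ) -> "Person":
        """Return a copy with the given risk flags replaced.

        Diabetes forces the at-risk-influenza flag on the copy.
        """
        new_diabetic = self.diabetic if diabetic is None else diabetic
        new_at_risk = self.at_risk_flu if at_risk_flu is None else at_risk_flu
        return replace(
            self,
            smoker=self.smoker if smoker is None else smoker,
            diabetic=new_diabetic,
            pregnant=self.pregnant if pregnant is None else pregnant,
            at_risk_flu=new_at_risk or new_diabetic,
        )


@dataclass
class Household:
    """An ordered set of people living at one address; the unit of analysis."""

    household_id: int
    household_type: str
    members: list[Person] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (1 <= len(self.members) <= MAX_HOUSEHOLD_SIZE):
            raise ValueError(
                f"household size must be 1..{MAX_HOUSEHOLD_SIZE}, "
                f"got {len(self.members)}"
            )

    @property
    def size(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Person]:
        return iter(self.members)
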