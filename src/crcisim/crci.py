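"""The Composite Referral Completion Indicator (CRCI).

The CRCI of a household is the proportion of the preventive services its
members received, out of those they were eligible to receive during the
study period: numerator = services taken up, denominator = eligibility
slots summed over members (a service two people are eligible for counts
twice).  A household eligible for nothing has numerator and denominator
zero and an *undefined* score - not a zero - and is excluded from sample
means but re-enters sample-size arithmetic through the valid fraction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from math import nan

import numpy as np
import pandas as pd

from .types import Household

__all__ = [
    "CRCIResult",
    "SampleSummary",
    "compute_crci",
    "compute_crci_all",
    "summarize_sample",
    "eligibility_by_household_type",
    "weighted_eligibility_totals",
    "load_reference_eligibility_table",
    "exact_expected_crci",
]

ELIGIBILITY_BINS = ("0", "1", "2", "3", "4+")


@dataclass(frozen=True)
class CRCIResult:
    """Per-household score: numerator, denominator, and value or undefined."""

    household_id: int
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not (0 <= self.numerator <= self.denominator):
            raise ValueError("need 0 <= numerator <= denominator")

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def value(self) -> float:
        """The score, or NaN for a household eligible for no services."""
        return self.numerator / self.denominator if self.defined else nan


@dataclass(frozen=True)
class SampleSummary:
    """Sample-level CRCI characteristics used in sample-size calculations."""

    n_households: int
    valid_fraction: float
    mean: float  # over households with a defined score; NaN if none
    sd: float  # sample SD (n-1) over defined scores; NaN if < 2 defined
    eligibility_distribution: dict[str, float]  # shares eligible for 0,1,2,3,4+


def compute_crci(eligibilities: pd.DataFrame, outcomes: pd.DataFrame) -> CRCIResult:
    """Score one household from its eligibility records and uptake outcomes.

    ``outcomes`` must cover exactly the same household as ``eligibilities``;
    rows referring to any other household raise ``ValueError``.
    """
    hh_ids = set(eligibilities["household_id"]) | set(outcomes["household_id"])
    if len(hh_ids) > 1:
        raise ValueError(f"records span multiple households: {sorted(hh_ids)}")
    denom = int(eligibilities["count"].sum()) if len(eligibilities) else 0
    numer = int(outcomes["taken"].sum()) if len(outcomes) else 0
    hid = int(next(iter(hh_ids))) if hh_ids else 0
    return CRCIResult(household_id=hid, numerator=numer, denominator=denom)


def compute_crci_all(
    households: list[Household], outcomes: pd.DataFrame
) -> pd.DataFrame:
    """Per-household scores for a whole population.

    Households absent from ``outcomes`` (eligible for nothing) appear with
    denominator 0 and an undefined (NaN) score.  Columns: household_id,
    household_type, numerator, denominator, crci.
    """
    base = pd.DataFrame(
        {
            "household_id": [h.household_id for h in households],
            "household_type": [h.household_type for h in households],
        }
    )
    if len(outcomes):
        agg = (
            outcomes.groupby("household_id")
            .agg(numerator=("taken", "sum"), denominator=("count", "sum"))
            .reset_index()
        )
    else:
        agg = pd.DataFrame(columns=["household_id", "numerator", "denominator"])
    merged = base.merge(agg, on="household_id", how="left").fillna(
        {"numerator": 0, "denominator": 0}
    )
    merged["numerator"] = merged["numerator"].astype(int)
    merged["denominator"] = merged["denominator"].astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        merged["crci"] = np.where(
            merged["denominator"] > 0,
            merged["numerator"] / merged["denominator"].replace(0, 1),
            nan,
        )
    return merged


def _bin_label(d: int) -> str:
    return str(d) if d < 4 else "4+"


def summarize_sample(results: pd.DataFrame) -> SampleSummary:
    """Mean/SD over defined scores, valid fraction, eligibility distribution.

    ``results`` is the frame from :func:`compute_crci_all` (needs columns
    ``denominator`` and ``crci``).
    """
    if results is None or not len(results):
        raise ValueError("summarize_sample requires a non-empty collection")
    n = len(results)
    defined = results["denominator"] > 0
    valid_fraction = float(defined.mean())
    vals = results.loc[defined, "crci"]
    mean = float(vals.mean()) if len(vals) else nan
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else nan
    bins = {b: 0.0 for b in ELIGIBILITY_BINS}
    counts = results["denominator"].map(_bin_label).value_counts()
    for b, c in counts.items():
        bins[b] = c / n
    return SampleSummary(
        n_households=n,
        valid_fraction=valid_fraction,
        mean=mean,
        sd=sd,
        eligibility_distribution=bins,
    )


def eligibility_by_household_type(results: pd.DataFrame) -> pd.DataFrame:
    """Eligibility-count distribution per household type.

    One row per type with its prevalence in the sample (percent) and the
    percent of its households eligible for 0/1/2/3/4+ services - the shape
    of the published by-type table.  Pass the result to
    :func:`weighted_eligibility_totals` for prevalence-weighted totals.
    """
    if not len(results):
        raise ValueError("empty results")
    n = len(results)
    rows = []
    for htype, grp in results.groupby("household_type", sort=False):
        shares = (
            grp["denominator"].map(_bin_label).value_counts(normalize=True) * 100.0
        )
        rows.append(
            {
                "household_type": htype,
                "prevalence_pct": 100.0 * len(grp) / n,
                "no_services_pct": shares.get("0", 0.0),
                "one_service_pct": shares.get("1", 0.0),
                "two_services_pct": shares.get("2", 0.0),
                "three_services_pct": shares.get("3", 0.0),
                "four_plus_pct": shares.get("4+", 0.0),
            }
        )
    return pd.DataFrame(rows)


_SHARE_COLUMNS = (
    "no_services_pct",
    "one_service_pct",
    "two_services_pct",
    "three_services_pct",
    "four_plus_pct",
)


def weighted_eligibility_totals(table: pd.DataFrame) -> pd.Series:
    """Prevalence-weighted totals of the per-type eligibility shares.

    ``table`` needs a ``prevalence_pct`` column and the five share columns;
    prevalences are renormalized to sum to 1 (printed tables carry rounding),
    so totals are in percent of all households.
    """
    w = table["prevalence_pct"].to_numpy(dtype=float)
    w = w / w.sum()
    return pd.Series(
        {col: float(np.dot(w, table[col].to_numpy(dtype=float))) for col in _SHARE_COLUMNS}
    )


def load_reference_eligibility_table() -> pd.DataFrame:
    """The published England-and-Wales eligibility-by-type distribution
    shipped with the package (percent units, as printed)."""
    text = (
        resources.files("crcisim.data")
        .joinpath("reference_eligibility_by_type.csv")
        .read_text(encoding="utf-8")
    )
    return pd.read_csv(io.StringIO(text))


def exact_expected_crci(rates: list[float]) -> tuple[float, float] | None:
    """Exact expectation and variance of a household's score given its
    eligibility slots' uptake probabilities.

    The number of services taken is Poisson-binomial; its full probability
    mass function is built by enumeration (dynamic-programming convolution
    over the ``d`` independent Bernoulli slots), and E[X/d] and Var[X/d]
    are read off it.  Returns ``None`` for the undefined case ``d = 0``.
    Intended as a brute-force oracle; ``d`` is capped at 20.
    """
    d = len(rates)
    if d == 0:
        return None
    if d > 20:
        raise ValueError("oracle capped at 20 eligibility slots")
    for r in rates:
        if not (0.0 <= r <= 1.0):
            raise ValueError("rates must be in [0, 1]")
    pmf = np.zeros(d + 1)
    pmf[0] = 1.0
    for r in rates:
        pmf[1:] = pmf[1:] * (1.0 - r) + pmf[:-1] * r
        pmf[0] *= 1.0 - r
    support = np.arange(d + 1) / d
    mean = float(np.dot(pmf, support))
    var = float(np.dot(pmf, (support - mean) ** 2))
    return mean, var
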