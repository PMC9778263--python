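"""Cohort assignment and cohort-specific rate tables.

Every person belongs to exactly one sex x 5-year-birth-year x
birth-state cohort; rates are lifetime ever/never proportions within each
cohort (no person-time).  Comorbidity rates are estimated on the
EMR-linked subpopulation, cancer and AD rates on the full genealogy
population; both denominators are explicit arguments so the choice is
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pandas as pd

from .errors import CohortRateError, DataError


class CohortKey(NamedTuple):
    """Sex, 5-year birth bin (half-open [start, start+5)), birth state."""

    sex: str
    bin_start: int
    utah_born: bool


def birth_year_bin(birth_year: int, width: int = 5) -> int:
    """Bin start for a birth year; bins anchored at multiples of ``width``."""
    return (int(birth_year) // width) * width


def assign_cohort(sex, birth_year, utah_born) -> CohortKey:
    """Deterministic cohort key for one person."""
    if pd.isna(sex) or pd.isna(birth_year) or pd.isna(utah_born):
        raise DataError(
            f"cohort assignment needs sex, birth_year, birth-state flag "
            f"(got {sex!r}, {birth_year!r}, {utah_born!r})"
        )
    return CohortKey(str(sex), birth_year_bin(birth_year), bool(utah_born))


def cohort_keys(individuals: pd.DataFrame) -> pd.Series:
    """Cohort key per person, indexed by person_id."""
    for col in ("sex", "birth_year", "utah_born"):
        if individuals[col].isna().any():
            bad = individuals.loc[individuals[col].isna(), "person_id"].iloc[0]
            raise DataError(f"person {bad}: missing {col} for cohort assignment")
    keys = [
        CohortKey(row.sex, birth_year_bin(row.birth_year), bool(row.utah_born))
        for row in individuals.itertuples(index=False)
    ]
    return pd.Series(keys, index=individuals["person_id"].to_numpy(), name="cohort")


@dataclass
class RateTable:
    """Per-cohort affected/total counts and rates for one phenotype.

    Zero-member cohorts are never present (they are omitted, not stored as
    zero-rate); a lookup for an absent cohort raises
    :class:`CohortRateError` rather than imputing.
    """

    phenotype: str
    counts: dict[CohortKey, tuple[int, int]]
    source_population_size: int

    def __post_init__(self) -> None:
        for key, (affected, total) in self.counts.items():
            if total <= 0 or affected < 0 or affected > total:
                raise DataError(
                    f"cohort {key}: invalid counts affected={affected}, total={total}"
                )
        if sum(t for _, t in self.counts.values()) != self.source_population_size:
            raise DataError("cohort totals do not sum to source population size")

    def rate(self, key: CohortKey) -> float:
        if key not in self.counts:
            raise CohortRateError(
                f"no {self.phenotype!r} rate estimated for cohort {key}"
            )
        affected, total = self.counts[key]
        return affected / total

    @property
    def total_affected(self) -> int:
        return sum(a for a, _ in self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "phenotype": self.phenotype,
                "sex": k.sex,
                "bin_start": k.bin_start,
                "utah_born": k.utah_born,
                "affected": a,
                "total": t,
                "rate": a / t,
            }
            for k, (a, t) in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RateTable":
        phenos = frame["phenotype"].unique()
        if len(phenos) != 1:
            raise DataError(f"rate-table frame must hold one phenotype, got {phenos}")
        counts = {
            CohortKey(r.sex, int(r.bin_start), bool(r.utah_born)): (
                int(r.affected),
                int(r.total),
            )
            for r in frame.itertuples(index=False)
        }
        return cls(
            phenotype=str(phenos[0]),
            counts=counts,
            source_population_size=int(frame["total"].sum()),
        )


def build_rate_table(
    individuals: pd.DataFrame,
    affected_ids: Iterable[int],
    phenotype: str,
) -> RateTable:
    """Estimate cohort-specific ever/never rates on a population subset.

    ``individuals`` is the denominator population (e.g. the EMR-linked
    subpopulation for comorbidities, the full genealogy population for
    cancer and AD); ``affected_ids`` the persons ever diagnosed.
    """
    if len(individuals) == 0:
        raise DataError(f"empty denominator population for {phenotype!r}")
    affected = set(affected_ids)
    unknown = affected - set(individuals["person_id"])
    if unknown:
        raise DataError(
            f"{phenotype!r}: {len(unknown)} affected ids outside the "
            f"denominator population (e.g. {next(iter(unknown))})"
        )
    keys = cohort_keys(individuals)
    counts: dict[CohortKey, list[int]] = {}
    for pid, key in keys.items():
        entry = counts.setdefault(key, [0, 0])
        entry[1] += 1
        if pid in affected:
            entry[0] += 1
    return RateTable(
        phenotype=phenotype,
        counts={k: (a, t) for k, (a, t) in counts.items()},
        source_population_size=len(individuals),
    )


def eligible_cancer_sites(
    cancer_records: pd.DataFrame,
    site_labels: Iterable[str],
    min_cases: int = 100,
) -> list[str]:
    """Sites with at least ``min_cases`` distinct affected persons.

    Returns eligible site labels in the order given; the derived
    'any cancer' union is the caller's to append, since its eligibility is
    not case-count based.
    """
    by_site = cancer_records.groupby("site")["person_id"].nunique()
    return [s for s in site_labels if int(by_site.get(s, 0)) >= min_cases]
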