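"""Family-history constellations and high-risk set selection.

A constellation is a signature of counts of AD-affected relatives,
stratified by degree of relatedness and — for second- and third-degree
kin — by maternal/paternal lineage, with each count capped at 3+.  Every
eligible person carries exactly one signature, so "belonging to a
high-risk constellation" is a single membership and cannot double-count.

The per-constellation relative risk is the indirect-standardization (SMR)
estimator: observed AD-affected probands divided by the expected number,
the sum of each proband's cohort-specific AD rate.  Constellations with
RR strictly above the threshold define the high-risk set, from which
already-diagnosed persons are removed.

Degree-1 relatives are pooled without lineage (a parent is
unambiguously maternal or paternal, but siblings and children are not,
and pooling keeps the signature space compact); affected degree-2/3
relatives with lineage ``none`` (descendant- and sibling-side kin) are
not counted.  The signature scheme is pluggable via ``signature_fn``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, NamedTuple

import pandas as pd

from .cohorts import RateTable, assign_cohort, cohort_keys
from .errors import DataError
from .pedigree import MATERNAL, PATERNAL, PedigreeGraph, RelativeSet

SIGNATURE_CAP = 3


class Signature(NamedTuple):
    """Counts (capped at 3) of affected relatives per stratum."""

    fdr: int
    sdr_maternal: int
    sdr_paternal: int
    tdr_maternal: int
    tdr_paternal: int

    def label(self) -> str:
        return (
            f"FDR={self.fdr};SDRm={self.sdr_maternal};SDRp={self.sdr_paternal};"
            f"TDRm={self.tdr_maternal};TDRp={self.tdr_paternal}"
        )


def constellation_signature(
    relset: RelativeSet, ad_flags: Mapping[int, bool], cap: int = SIGNATURE_CAP
) -> Signature:
    """Signature of one proband's affected relatives (proband excluded)."""

    def count(degree: int, lineages: tuple[str, ...] | None) -> int:
        total = sum(
            1
            for rel, lin in relset.by_degree.get(degree, {}).items()
            if ad_flags.get(rel, False) and (lineages is None or lin in lineages)
        )
        return min(total, cap)

    return Signature(
        fdr=count(1, None),
        sdr_maternal=count(2, (MATERNAL,)),
        sdr_paternal=count(2, (PATERNAL,)),
        tdr_maternal=count(3, (MATERNAL,)),
        tdr_paternal=count(3, (PATERNAL,)),
    )


@dataclass
class Constellation:
    """One family-history signature with its proband set and risk estimate."""

    signature: Signature
    probands: set[int]
    observed: int
    expected: float

    @property
    def rr(self) -> float | None:
        """Observed/expected; None (undefined) when expected is zero."""
        if self.expected <= 0:
            return None
        return self.observed / self.expected


def group_probands_by_constellation(
    graph: PedigreeGraph,
    ad_flags: Mapping[int, bool],
    eligible_ids: Iterable[int] | None = None,
    cap: int = SIGNATURE_CAP,
    signature_fn: Callable[..., Signature] = constellation_signature,
) -> dict[Signature, set[int]]:
    """Assign every eligible person to its (single) constellation."""
    if eligible_ids is None:
        eligible_ids = list(graph.individuals["person_id"])
    groups: dict[Signature, set[int]] = {}
    for pid in eligible_ids:
        relset = graph.relatives_by_degree(int(pid), max_degree=3)
        sig = signature_fn(relset, ad_flags, cap=cap)
        groups.setdefault(sig, set()).add(int(pid))
    return groups


def constellation_rr(
    probands: set[int],
    ad_flags: Mapping[int, bool],
    ad_rates: RateTable,
    individuals: pd.DataFrame,
) -> tuple[int, float, float | None]:
    """Observed count, expected count, and their ratio for one proband set.

    Expected is the sum over probands of their cohort-specific AD rate;
    a proband in a cohort with no estimated rate raises
    :class:`~famrisk.errors.CohortRateError` naming the cohort.
    """
    info = individuals.set_index("person_id")
    observed = sum(1 for p in probands if ad_flags.get(p, False))
    expected = 0.0
    for p in sorted(probands):
        row = info.loc[p]
        key = assign_cohort(row["sex"], row["birth_year"], row["utah_born"])
        expected += ad_rates.rate(key)
    rr = observed / expected if expected > 0 else None
    return observed, expected, rr


def estimate_constellations(
    graph: PedigreeGraph,
    ad_flags: Mapping[int, bool],
    ad_rates: RateTable,
    individuals: pd.DataFrame,
    eligible_ids: Iterable[int] | None = None,
    cap: int = SIGNATURE_CAP,
) -> list[Constellation]:
    """Group probands and estimate O, E and RR for every constellation."""
    groups = group_probands_by_constellation(graph, ad_flags, eligible_ids, cap)
    keys = cohort_keys(individuals)
    person_rate = {
        pid: ad_rates.rate(key) for pid, key in keys.items()
    }
    out = []
    for sig in sorted(groups):
        probands = groups[sig]
        observed = sum(1 for p in probands if ad_flags.get(p, False))
        expected = sum(person_rate[p] for p in probands)
        out.append(
            Constellation(
                signature=sig, probands=probands,
                observed=observed, expected=expected,
            )
        )
    return out


@dataclass
class HighRiskSelection:
    """High-risk member set with the selection bookkeeping."""

    members: set[int]
    identified: int  # members of qualifying constellations, pre-exclusion
    excluded: int  # of those, already AD-diagnosed
    qualifying_signatures: list[Signature]

    @property
    def analyzed(self) -> int:
        return self.identified - self.excluded


def select_high_risk(
    constellations: Iterable[Constellation],
    ad_flags: Mapping[int, bool],
    rr_threshold: float = 2.0,
    min_probands: int = 10,
) -> HighRiskSelection:
    """Union of proband sets with RR strictly above threshold, minus cases.

    Constellations below ``min_probands`` probands are ignored (small sets
    give unstable RRs); already AD-diagnosed persons are removed from the
    selected union so the returned members are high-risk but undiagnosed.
    """
    if rr_threshold <= 0:
        raise DataError(f"rr_threshold must be positive (got {rr_threshold})")
    selected: set[int] = set()
    signatures = []
    for con in constellations:
        if len(con.probands) < min_probands:
            continue
        if con.rr is not None and con.rr > rr_threshold:
            selected |= con.probands
            signatures.append(con.signature)
    diagnosed = {p for p in selected if ad_flags.get(p, False)}
    return HighRiskSelection(
        members=selected - diagnosed,
        identified=len(selected),
        excluded=len(diagnosed),
        qualifying_signatures=signatures,
    )


def constellation_report(constellations: Iterable[Constellation]) -> pd.DataFrame:
    """Flat table of every constellation's signature, counts and RR."""
    rows = []
    for con in constellations:
        rows.append(
            {
                "fdr": con.signature.fdr,
                "sdr_maternal": con.signature.sdr_maternal,
                "sdr_paternal": con.signature.sdr_paternal,
                "tdr_maternal": con.signature.tdr_maternal,
                "tdr_paternal": con.signature.tdr_paternal,
                "n_probands": len(con.probands),
                "observed": con.observed,
                "expected": con.expected,
                "rr": con.rr,
            }
        )
    return pd.DataFrame(rows)
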