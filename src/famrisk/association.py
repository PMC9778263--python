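"""Observed/expected risk estimation with Agresti-style intervals.

The relative risk of each phenotype in the high-risk set is the
indirectly standardized ratio O/E: observed affected members over the sum
of the members' cohort-specific rates.  The 95% interval treats O/n as a
binomial proportion, applies the Agresti-Coull adjusted-Wald interval
(z^2/2 pseudo-successes, z^2 pseudo-trials), and rescales to the RR axis
by n/E; the two-sided p-value comes from the binomial score statistic
z = (O - E) / sqrt(E (1 - E/n)).  These choices are isolated in
:func:`agresti_rr_ci` / :func:`two_sided_p` so alternatives (exact
Poisson, mid-P) can be swapped in.

Multiple testing uses the Bonferroni rule: the significance threshold is
alpha divided by the number of tests m, equivalently p_adjusted =
min(1, m * p_raw).  Distribution contrasts (sex, binary BMI) use
Pearson's chi-squared on a 2x2 table, Yates-corrected by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohorts import RateTable, assign_cohort
from .errors import DataError


def observed_expected(
    member_ids: Iterable[int],
    affected_ids: set[int],
    rates: RateTable,
    individuals: pd.DataFrame,
) -> tuple[int, float]:
    """Observed affected members and expected count from cohort rates."""
    members = sorted(set(member_ids))
    if not members:
        return 0, 0.0
    info = individuals.set_index("person_id")
    missing = [m for m in members if m not in info.index]
    if missing:
        raise DataError(f"members not in population table: {missing[:5]}")
    observed = sum(1 for m in members if m in affected_ids)
    cache: dict = {}
    expected = 0.0
    for m in members:
        row = info.loc[m]
        key = assign_cohort(row["sex"], row["birth_year"], row["utah_born"])
        if key not in cache:
            cache[key] = rates.rate(key)
        expected += cache[key]
    return observed, expected


def agresti_rr_ci(
    observed: int, expected: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Adjusted-Wald (Agresti-Coull) interval for O/E.

    The binomial interval for the proportion O/n is rescaled to the RR
    axis by n/E; the lower bound is clipped at zero.
    """
    if n <= 0 or expected <= 0 or not 0 <= observed <= n:
        raise DataError(
            f"invalid counts for CI: O={observed}, E={expected}, n={n}"
        )
    z = stats.norm.ppf(0.5 + level / 2)
    n_tilde = n + z * z
    p_tilde = (observed + z * z / 2) / n_tilde
    half = z * np.sqrt(p_tilde * (1 - p_tilde) / n_tilde)
    scale = n / expected
    return max(0.0, (p_tilde - half) * scale), (p_tilde + half) * scale


def two_sided_p(observed: int, expected: float, n: int) -> float:
    """Two-sided binomial score-test p-value for O against E."""
    if n <= 0 or not 0 <= observed <= n:
        raise DataError(f"invalid counts: O={observed}, n={n}")
    if expected <= 0 or expected >= n:
        raise DataError(
            f"score test undefined for E={expected} with n={n}"
        )
    z = (observed - expected) / np.sqrt(expected * (1 - expected / n))
    return float(min(1.0, 2 * stats.norm.sf(abs(z))))


@dataclass(frozen=True)
class RiskEstimate:
    """O/E relative risk for one phenotype, with inference annotations."""

    phenotype: str
    observed: int
    expected: float
    n: int
    rr: float
    ci_low: float
    ci_high: float
    p_raw: float
    level: float = 0.95
    p_adjusted: float | None = None
    n_tests: int | None = None
    significant: bool | None = None


def estimate_risk(
    phenotype: str,
    observed: int,
    expected: float,
    n: int,
    level: float = 0.95,
) -> RiskEstimate:
    """Point estimate, interval and raw p-value for one phenotype."""
    if expected <= 0:
        raise DataError(
            f"{phenotype!r}: expected count must be positive (got {expected})"
        )
    lo, hi = agresti_rr_ci(observed, expected, n, level)
    return RiskEstimate(
        phenotype=phenotype,
        observed=observed,
        expected=expected,
        n=n,
        rr=observed / expected,
        ci_low=lo,
        ci_high=hi,
        p_raw=two_sided_p(observed, expected, n),
        level=level,
    )


def undefined_risk(
    phenotype: str, n: int = 0, level: float = 0.95
) -> RiskEstimate:
    """Placeholder estimate for an empty member set or zero expected count.

    The RR is undefined (NaN) and the estimate never reaches significance;
    it is carried through reports so the phenotype row is not silently
    dropped.
    """
    nan = float("nan")
    return RiskEstimate(
        phenotype=phenotype, observed=0, expected=0.0, n=n,
        rr=nan, ci_low=nan, ci_high=nan, p_raw=nan, level=level,
    )


def bonferroni_adjust(
    estimates: Iterable[RiskEstimate], m: int | None = None, alpha: float = 0.05
) -> list[RiskEstimate]:
    """Annotate estimates with Bonferroni-adjusted p-values and flags.

    ``m`` defaults to the number of estimates; an estimate is significant
    iff p_raw < alpha/m, equivalently p_adjusted < alpha.
    """
    estimates = list(estimates)
    if m is None:
        m = len(estimates)
    if m <= 0:
        raise DataError("number of tests m must be positive")
    if m < len(estimates):
        raise DataError(
            f"m={m} smaller than the {len(estimates)} estimates it corrects"
        )
    out = []
    for e in estimates:
        if np.isnan(e.p_raw):
            out.append(replace(e, p_adjusted=float("nan"), n_tests=m,
                               significant=None))
        else:
            out.append(
                replace(
                    e,
                    p_adjusted=min(1.0, m * e.p_raw),
                    n_tests=m,
                    significant=bool(e.p_raw < alpha / m),
                )
            )
    return out


def chi2_2x2(
    table: np.ndarray | list[list[int]], yates: bool = True
) -> tuple[float, float]:
    """Pearson's chi-squared test on a 2x2 contingency table.

    With ``yates`` (default) the continuity correction N/2 is subtracted
    from |ad - bc| before squaring.  Returns (statistic, p) with 1 df.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise DataError(f"need a nonnegative 2x2 table, got shape {t.shape}")
    a, b, c, d = t.ravel()
    n = t.sum()
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows <= 0).any() or (cols <= 0).any():
        raise DataError("all margins of the 2x2 table must be positive")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2)
    statistic = n * diff**2 / (rows[0] * rows[1] * cols[0] * cols[1])
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def summarize_distribution(counts: Mapping[str, int]) -> pd.DataFrame:
    """Counts, exact proportions, and display percentages (1 decimal)."""
    total = sum(counts.values())
    if total <= 0:
        raise DataError("distribution total must be positive")
    rows = [
        {
            "group": group,
            "count": count,
            "proportion": count / total,
            "percent": round(100.0 * count / total, 1),
        }
        for group, count in counts.items()
    ]
    return pd.DataFrame(rows)


def estimates_frame(estimates: Iterable[RiskEstimate]) -> pd.DataFrame:
    """Flatten risk estimates into the results-table layout."""
    return pd.DataFrame(
        [
            {
                "phenotype": e.phenotype,
                "observed": e.observed,
                "expected": e.expected,
                "n": e.n,
                "rr": e.rr,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p_raw": e.p_raw,
                "p_adjusted": e.p_adjusted,
                "m": e.n_tests,
                "significant": e.significant,
            }
            for e in estimates
        ]
    )
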