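import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from famrisk import (
    DataError,
    agresti_rr_ci,
    bonferroni_adjust,
    build_rate_table,
    chi2_2x2,
    estimate_risk,
    observed_expected,
    summarize_distribution,
    two_sided_p,
)
from famrisk.association import undefined_risk


def _population_two_cohorts():
    rows = []
    for i in range(100):
        rows.append((i + 1, "F", 1940, True))
    for i in range(100):
        rows.append((i + 101, "F", 1950, True))
    return pd.DataFrame(rows, columns=["person_id", "sex", "birth_year",
                                       "utah_born"])


def test_observed_expected_hand_computation():
    """Cohort rates 0.05 and 0.10 over 100 members each give E = 15;
    12 flagged members give RR = 0.8."""
    individuals = _population_two_cohorts()
    source = pd.concat([individuals] * 10, ignore_index=True)
    source["person_id"] = range(1, 2001)
    affected_src = set(
        source.loc[source["birth_year"] == 1940, "person_id"][:50]
    ) | set(source.loc[source["birth_year"] == 1950, "person_id"][:100])
    rates = build_rate_table(source, affected_src, "x")
    members = set(individuals["person_id"])
    flagged = set(range(1, 13))
    o, e = observed_expected(members, flagged, rates, individuals)
    assert o == 12
    assert e == pytest.approx(15.0, abs=1e-12)
    assert o / e == pytest.approx(0.8)


def test_observed_expected_self_standardization():
    individuals = _population_two_cohorts()
    affected = set(range(1, 31))
    rates = build_rate_table(individuals, affected, "x")
    o, e = observed_expected(
        set(individuals["person_id"]), affected, rates, individuals
    )
    assert o == 30
    assert e == pytest.approx(30.0, abs=1e-9)


def test_observed_expected_empty_set():
    individuals = _population_two_cohorts()
    rates = build_rate_table(individuals, set(), "x")
    assert observed_expected(set(), set(), rates, individuals) == (0, 0.0)
    est = undefined_risk("x")
    assert math.isnan(est.rr) and est.observed == 0


def _agresti_oracle(o, e, n, level=0.95):
    # direct transcription of the adjusted-Wald formulas
    z = stats.norm.ppf(1 - (1 - level) / 2)
    nt = n + z**2
    pt = (o + z**2 / 2) / nt
    h = z * math.sqrt(pt * (1 - pt) / nt)
    return max(0.0, (pt - h) * n / e), (pt + h) * n / e


@pytest.mark.parametrize(
    "o,e,n",
    [(50, 40.0, 1000), (0, 5.0, 200), (12, 15.0, 200), (999, 900.0, 1000),
     (3, 0.4, 50)],
)
def test_agresti_interval_matches_formula_oracle(o, e, n):
    lo, hi = agresti_rr_ci(o, e, n)
    olo, ohi = _agresti_oracle(o, e, n)
    assert lo == pytest.approx(olo, rel=1e-12)
    assert hi == pytest.approx(ohi, rel=1e-12)


def test_interval_contains_point_estimate_and_clips_at_zero():
    lo, hi = agresti_rr_ci(100, 100.0, 10_000)
    assert lo <= 1.0 <= hi
    lo0, _ = agresti_rr_ci(0, 10.0, 1000)
    assert lo0 == 0.0


def test_p_value_is_one_at_null_and_monotone():
    assert two_sided_p(40, 40.0, 1000) == pytest.approx(1.0)
    ps = [two_sided_p(40 + d, 40.0, 1000) for d in range(0, 30, 5)]
    assert ps == sorted(ps, reverse=True)


def test_p_value_tracks_exact_binomial_within_factor():
    """Score-test p agrees with the exact two-sided binomial test within a
    factor of 1.5 across a grid of moderate counts (exact p >= 0.01; the
    normal approximation is not expected to track deep tails
    multiplicatively)."""
    for n, e in [(1000, 100.0), (2000, 400.0), (5000, 250.0)]:
        for o in range(int(e * 0.5), int(e * 1.6)):
            p_exact = stats.binomtest(o, n, e / n).pvalue
            if p_exact < 0.01:
                continue
            p_score = two_sided_p(o, e, n)
            assert p_score / p_exact < 1.5 and p_exact / p_score < 1.5, (n, e, o)


def test_p_value_domain_errors():
    with pytest.raises(DataError):
        two_sided_p(5, 0.0, 100)
    with pytest.raises(DataError):
        two_sided_p(5, 100.0, 100)


def test_bonferroni_identity_and_arithmetic():
    est = estimate_risk("x", 50, 40.0, 1000)
    (single,) = bonferroni_adjust([est], m=1)
    assert single.p_adjusted == pytest.approx(single.p_raw)

    est2 = estimate_risk("y", 60, 40.0, 1000)
    fake = [e for e in [est, est2]]
    adjusted = bonferroni_adjust(fake, m=20)
    for raw, adj in zip(fake, adjusted):
        assert adj.p_adjusted == pytest.approx(min(1.0, 20 * raw.p_raw))
    # p_raw = 0.01 at m = 20 -> adjusted 0.2, not significant
    assert not [a for a in adjusted if 0.009 < a.p_raw < 0.011 and a.significant]


def test_bonferroni_flag_count_matches_brute_force():
    rng = np.random.default_rng(4)
    estimates = [
        estimate_risk(f"p{i}", int(o), 50.0, 2000)
        for i, o in enumerate(rng.integers(20, 110, size=15))
    ]
    m = 21
    adjusted = bonferroni_adjust(estimates, m=m)
    brute = sum(1 for e in estimates if e.p_raw < 0.05 / m)
    assert sum(1 for a in adjusted if a.significant) == brute


def test_bonferroni_rejects_m_smaller_than_estimates():
    ests = [estimate_risk("x", 50, 40.0, 1000)] * 3
    with pytest.raises(DataError):
        bonferroni_adjust(ests, m=2)


def test_chi2_proportional_table_is_null():
    statistic, p = chi2_2x2([[10, 20], [100, 200]], yates=False)
    assert statistic == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


@settings(derandomize=True, max_examples=100)
@given(
    st.tuples(*[st.integers(min_value=5, max_value=5000)] * 4),
    st.booleans(),
)
def test_chi2_matches_scipy_and_is_swap_invariant(cells, yates):
    a, b, c, d = cells
    table = [[a, b], [c, d]]
    statistic, p = chi2_2x2(table, yates=yates)
    ref_stat, ref_p, _, _ = stats.chi2_contingency(table, correction=yates)
    assert statistic == pytest.approx(ref_stat, rel=1e-9)
    assert p == pytest.approx(ref_p, rel=1e-9, abs=1e-300)
    for swapped in ([[c, d], [a, b]], [[b, a], [d, c]]):
        s2, p2 = chi2_2x2(swapped, yates=yates)
        assert s2 == pytest.approx(statistic)
        assert p2 == pytest.approx(p)


def test_chi2_rejects_zero_margin():
    with pytest.raises(DataError):
        chi2_2x2([[0, 0], [5, 5]])


def test_summarize_distribution_percentages():
    frame = summarize_distribution({"a": 1, "b": 3, "c": 0})
    assert list(frame["percent"]) == [25.0, 75.0, 0.0]
    assert frame["proportion"].sum() == pytest.approx(1.0)
    with pytest.raises(DataError):
        summarize_distribution({"a": 0})


def test_interval_coverage_quick_check():
    """~95% of Agresti intervals cover the true RR (spot check; the full
    1000-replicate calibration lives in the acceptance suite)."""
    rng = np.random.default_rng(2)
    rates = np.repeat([0.05, 0.15], 2500)
    theta = 1.2
    e = float(rates.sum())
    n = rates.size
    cover = sum(
        (lambda o: (lambda lh: lh[0] <= theta <= lh[1])(
            agresti_rr_ci(o, e, n)))(int((rng.random(n) < rates * theta).sum()))
        for _ in range(200)
    )
    assert 0.90 <= cover / 200 <= 1.0
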