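"""End-to-end orchestration: bundle -> pedigree -> rates -> constellations
-> high-risk selection -> association -> report tables.

Denominator conventions: AD and cancer rates are estimated on the full
genealogy population (death-certificate and registry ascertainment cover
everyone); comorbidity rates on the EMR-linked subpopulation, and the
comorbidity O/E likewise restricted to EMR-linked high-risk members (no
chart, no observable diagnosis).  The comparison populations include the
high-risk members themselves — the selected set is compared against the
whole population, overlap and all.

Every run writes a manifest recording the seed, parameters, and stage
counts; the bookkeeping identity identified - excluded = analyzed is
asserted before any report is rendered.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import (
    RiskEstimate,
    bonferroni_adjust,
    chi2_2x2,
    estimate_risk,
    estimates_frame,
    observed_expected,
    summarize_distribution,
    undefined_risk,
)
from .cohorts import RateTable, build_rate_table, eligible_cancer_sites
from .constellations import (
    Constellation,
    HighRiskSelection,
    constellation_report,
    estimate_constellations,
    select_high_risk,
)
from .errors import ConfigError, DataError
from .pedigree import build_pedigree, genealogy_complete
from .phenotypes import (
    AD_LABEL,
    ANY_CANCER,
    BMI_BINARY_HIGH,
    BMI_BINARY_LOW,
    COMORBIDITIES,
    CancerSiteCatalog,
    bmi,
    bmi_category,
    collapse_bmi,
    default_phenotype_catalog,
    person_phenotype_flags,
)
from .simulate import PopulationBundle, SimConfig, generate_population, read_bundle


@dataclass
class PipelineConfig:
    """Everything one reproducible pipeline run needs.

    Exactly one of ``sim`` (generate a synthetic bundle) or ``bundle_dir``
    (load an existing one) must be provided.
    """

    sim: SimConfig | None = None
    bundle_dir: str | Path | None = None
    rr_threshold: float = 2.0
    min_probands: int = 10
    signature_cap: int = 3
    min_cancer_cases: int = 100
    completeness_filter: bool = False
    confidence_level: float = 0.95
    alpha: float = 0.05
    yates: bool = True
    out_dir: str | Path | None = None

    def validate(self) -> None:
        if (self.sim is None) == (self.bundle_dir is None):
            raise ConfigError("provide exactly one of sim or bundle_dir")
        if self.rr_threshold <= 0:
            raise ConfigError("rr_threshold: must be positive")
        if not 0 < self.confidence_level < 1:
            raise ConfigError("confidence_level: must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha: must lie in (0, 1)")
        if self.sim is not None:
            self.sim.validate()


@dataclass
class DistributionComparison:
    """A 2x2 high-risk vs population contrast with its chi-squared test."""

    label: str
    high_risk: dict[str, int]
    population: dict[str, int]
    statistic: float
    p_value: float


@dataclass
class PipelineResult:
    bundle: PopulationBundle
    ad_rates: RateTable
    constellations: list[Constellation]
    selection: HighRiskSelection
    comorbidity_estimates: list[RiskEstimate]
    cancer_estimates: list[RiskEstimate]
    sex_comparison: DistributionComparison
    bmi_comparison: DistributionComparison | None
    manifest: dict = field(default_factory=dict)


def compare_distribution(
    label: str,
    high_risk_counts: dict[str, int],
    population_counts: dict[str, int],
    yates: bool = True,
) -> DistributionComparison:
    """Chi-squared contrast of a binary distribution against the population."""
    groups = list(high_risk_counts)
    if len(groups) != 2 or list(population_counts) != groups:
        raise DataError(f"{label}: need the same two groups in both populations")
    table = [
        [high_risk_counts[groups[0]], population_counts[groups[0]]],
        [high_risk_counts[groups[1]], population_counts[groups[1]]],
    ]
    statistic, p = chi2_2x2(table, yates=yates)
    return DistributionComparison(
        label=label,
        high_risk=dict(high_risk_counts),
        population=dict(population_counts),
        statistic=statistic,
        p_value=p,
    )


def _bmi_binary_counts(individuals: pd.DataFrame, biometrics: pd.DataFrame,
                       ids: set[int] | None = None) -> dict[str, int]:
    rows = biometrics
    if ids is not None:
        rows = rows[rows["person_id"].isin(ids)]
    counts = {BMI_BINARY_LOW: 0, BMI_BINARY_HIGH: 0}
    for r in rows.itertuples(index=False):
        group = collapse_bmi(bmi_category(bmi(r.height_cm, r.weight_kg)))
        counts[group] += 1
    return counts


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; see the module docstring for conventions."""
    config.validate()
    stage = "load"
    try:
        if config.sim is not None:
            bundle = generate_population(config.sim)
        else:
            bundle = read_bundle(config.bundle_dir)

        stage = "pedigree"
        individuals = bundle.individuals
        graph = build_pedigree(individuals)

        stage = "phenotyping"
        catalog = default_phenotype_catalog()
        site_catalog = CancerSiteCatalog()
        flags = person_phenotype_flags(catalog, bundle.diagnoses)
        ad_set = set(flags.index[flags[AD_LABEL]]) if AD_LABEL in flags else set()
        ad_flags = {pid: True for pid in ad_set}
        comorbid_sets = {
            label: set(flags.index[flags[label]]) if label in flags else set()
            for label in COMORBIDITIES
        }
        site_flags = site_catalog.site_flags(bundle.cancer_records)

        stage = "rates"
        ad_rates = build_rate_table(individuals, ad_set, AD_LABEL)
        emr_pop = individuals[individuals["emr_linked"].astype(bool)]

        stage = "constellations"
        if config.completeness_filter:
            eligible = [
                int(p)
                for p in individuals["person_id"]
                if genealogy_complete(graph, int(p))
            ]
        else:
            eligible = [int(p) for p in individuals["person_id"]]
        constellations = estimate_constellations(
            graph, ad_flags, ad_rates, individuals, eligible,
            cap=config.signature_cap,
        )

        stage = "high-risk selection"
        selection = select_high_risk(
            constellations,
            ad_flags,
            rr_threshold=config.rr_threshold,
            min_probands=config.min_probands,
        )
        if selection.identified - selection.excluded != selection.analyzed:
            raise DataError("selection bookkeeping identity violated")

        stage = "association"
        members = selection.members
        if not members:
            raise DataError(
                "high-risk set is empty; no constellation passed "
                f"rr > {config.rr_threshold} with >= {config.min_probands} probands"
            )
        emr_ids = set(emr_pop["person_id"])

        def _estimate(label: str, o: int, e: float, n: int) -> RiskEstimate:
            if n == 0 or e <= 0:
                return undefined_risk(label, n, config.confidence_level)
            return estimate_risk(label, o, e, n, config.confidence_level)

        raw_estimates: list[RiskEstimate] = []
        member_subset = members & emr_ids
        for label in COMORBIDITIES:
            rates = build_rate_table(emr_pop, comorbid_sets[label], label)
            o, e = observed_expected(member_subset, comorbid_sets[label],
                                     rates, individuals)
            raw_estimates.append(_estimate(label, o, e, len(member_subset)))
        n_comorbid = len(raw_estimates)

        sites = eligible_cancer_sites(
            bundle.cancer_records, site_catalog.sites, config.min_cancer_cases
        )
        for label in [*sites, ANY_CANCER]:
            affected = (
                set(site_flags.index[site_flags[label]])
                if label in site_flags
                else set()
            )
            rates = build_rate_table(individuals, affected, label)
            o, e = observed_expected(members, affected, rates, individuals)
            raw_estimates.append(_estimate(label, o, e, len(members)))
        adjusted = bonferroni_adjust(raw_estimates, alpha=config.alpha)
        comorbidity_estimates = adjusted[:n_comorbid]
        cancer_estimates = adjusted[n_comorbid:]

        stage = "distributions"
        by_id = individuals.set_index("person_id")
        member_sex = by_id.loc[sorted(members), "sex"]
        sex_comparison = compare_distribution(
            "sex",
            {"male": int((member_sex == "M").sum()),
             "female": int((member_sex == "F").sum())},
            {"male": int((individuals["sex"] == "M").sum()),
             "female": int((individuals["sex"] == "F").sum())},
            yates=config.yates,
        )
        bmi_comparison = None
        hr_bmi = _bmi_binary_counts(individuals, bundle.biometrics, members)
        pop_bmi = _bmi_binary_counts(individuals, bundle.biometrics)
        if min(hr_bmi.values()) > 0 and min(pop_bmi.values()) > 0:
            bmi_comparison = compare_distribution(
                "bmi", hr_bmi, pop_bmi, yates=config.yates
            )

        stage = "manifest"
        manifest = {
            "famrisk_version": __version__,
            "seed": config.sim.rng_seed if config.sim is not None else None,
            "parameters": {
                "rr_threshold": config.rr_threshold,
                "min_probands": config.min_probands,
                "signature_cap": config.signature_cap,
                "min_cancer_cases": config.min_cancer_cases,
                "completeness_filter": config.completeness_filter,
                "confidence_level": config.confidence_level,
                "alpha": config.alpha,
                "yates": config.yates,
                "n_tests": len(adjusted),
            },
            "counts": {
                "population": len(individuals),
                "emr_linked": len(emr_pop),
                "eligible": len(eligible),
                "ad_cases": len(ad_set),
                "constellations": len(constellations),
                "qualifying_constellations": len(selection.qualifying_signatures),
                "identified": selection.identified,
                "excluded": selection.excluded,
                "analyzed": selection.analyzed,
            },
        }
        assert (
            manifest["counts"]["identified"] - manifest["counts"]["excluded"]
            == manifest["counts"]["analyzed"]
        )
    except Exception as exc:
        if isinstance(exc, (DataError, ConfigError)):
            raise type(exc)(f"[stage: {stage}] {exc}") from exc
        raise

    result = PipelineResult(
        bundle=bundle,
        ad_rates=ad_rates,
        constellations=constellations,
        selection=selection,
        comorbidity_estimates=comorbidity_estimates,
        cancer_estimates=cancer_estimates,
        sex_comparison=sex_comparison,
        bmi_comparison=bmi_comparison,
        manifest=manifest,
    )
    if config.out_dir is not None:
        render_tables(result, config.out_dir)
    return result


def _distribution_table(comp: DistributionComparison) -> pd.DataFrame:
    hr = summarize_distribution(comp.high_risk)
    pop = summarize_distribution(comp.population)
    out = pd.DataFrame(
        {
            "group": hr["group"],
            "high_risk_count": hr["count"],
            "high_risk_percent": hr["percent"],
            "population_count": pop["count"],
            "population_percent": pop["percent"],
        }
    )
    out.attrs["chi2_p"] = comp.p_value
    return out


def render_tables(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the four report tables (TSV) plus full-precision companions.

    Rendered tables round RR to 2 decimals, percentages to 1 decimal and
    p-values to 3 significant figures; ``results.json`` keeps everything
    at full precision, and ``manifest.json`` records the run.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _rr_table(estimates: list[RiskEstimate], name: str) -> None:
        if not estimates:
            raise DataError(f"no estimates configured for {name}")
        frame = pd.DataFrame(
            {
                "phenotype": [e.phenotype for e in estimates],
                "relative_risk": [round(e.rr, 2) for e in estimates],
                "ci_95": [
                    f"({e.ci_low:.2f}, {e.ci_high:.2f})" for e in estimates
                ],
                "p_value": [f"{e.p_raw:.3g}" for e in estimates],
                "p_adjusted": [f"{e.p_adjusted:.3g}" for e in estimates],
                "significant": [e.significant for e in estimates],
            }
        )
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = path

    _rr_table(result.comorbidity_estimates, "table1_comorbidities.tsv")
    _rr_table(result.cancer_estimates, "table2_cancers.tsv")

    sex_table = _distribution_table(result.sex_comparison)
    sex_table.to_csv(out_dir / "table3_sex.tsv", sep="\t", index=False)
    paths["table3_sex.tsv"] = out_dir / "table3_sex.tsv"
    if result.bmi_comparison is not None:
        bmi_table = _distribution_table(result.bmi_comparison)
        bmi_table.to_csv(out_dir / "table4_bmi.tsv", sep="\t", index=False)
        paths["table4_bmi.tsv"] = out_dir / "table4_bmi.tsv"

    constellation_report(result.constellations).to_csv(
        out_dir / "constellations.csv", index=False
    )
    paths["constellations.csv"] = out_dir / "constellations.csv"

    full = {
        "comorbidities": estimates_frame(result.comorbidity_estimates).to_dict(
            "records"
        ),
        "cancers": estimates_frame(result.cancer_estimates).to_dict("records"),
        "sex": asdict(result.sex_comparison),
        "bmi": asdict(result.bmi_comparison)
        if result.bmi_comparison is not None
        else None,
    }
    (out_dir / "results.json").write_text(json.dumps(full, indent=2))
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    paths["results.json"] = out_dir / "results.json"
    paths["manifest.json"] = out_dir / "manifest.json"
    return paths
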