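"""Seeded synthetic population generator.

Emulates the statistical structure of a founder-population genealogy with
linked health records: multi-generation outbred pedigrees, sex x 5-year
birth cohort x birth-state structure, familial aggregation of Alzheimer's
disease, ICD-coded comorbidity diagnoses, registry cancer-site records,
and drivers'-license height/weight with partial linkage.  Nothing here is
fit to real data; effect sizes (the familial multipliers ``lambda`` and
the injected phenotype risk ``theta``) exist so downstream estimators can
be tested by parameter recovery.

All randomness flows from one ``numpy`` generator seeded by
``SimConfig.rng_seed``; draws occur in a fixed order (pedigree structure,
linkage flags, vital status, AD status, comorbidities, cancers,
biometrics), so identical configs yield byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohorts import birth_year_bin
from .errors import CohortRateError, ConfigError, DataError, ParseError
from .pedigree import PedigreeGraph, build_pedigree
from .phenotypes import (
    AD_LABEL,
    ANY_CANCER,
    CANCER_SITES,
    CODE_SYSTEMS,
    COMORBIDITIES,
    CancerSiteCatalog,
    PhenotypeCatalog,
    default_phenotype_catalog,
)

#: Age-dependent lifetime AD rates by birth-year band [start, end):
#: members of the oldest cohorts have lived through the ages of peak risk,
#: recent cohorts have not.
DEFAULT_AD_RATES: dict[tuple[int, int], float] = {
    (1700, 1920): 0.050,
    (1920, 1940): 0.040,
    (1940, 1960): 0.010,
    (1960, 2200): 0.002,
}

#: Lifetime ever-diagnosed rates for the comorbid conditions (EMR-linked
#: population) and registry rates for the 15 cancer sites.
DEFAULT_PHENOTYPE_RATES: dict[str, float] = {
    "diabetes": 0.10,
    "hypertension": 0.25,
    "heart disease": 0.18,
    "cerebrovascular disease": 0.05,
    "dementia excluding AD": 0.02,
    "Breast": 0.020,
    "Colorectal": 0.012,
    "Kidney": 0.004,
    "Lung and bronchus": 0.008,
    "Non-Hodgkin lymphoma": 0.005,
    "Pancreas": 0.003,
    "Stomach": 0.003,
    "Bladder": 0.005,
    "Brain": 0.002,
    "Cervix": 0.003,
    "Leukemia": 0.004,
    "Melanoma": 0.010,
    "Ovary": 0.003,
    "Prostate": 0.020,
    "Thyroid": 0.004,
}

#: Two-component normal mixture for adult BMI (weight, mean, sd); tuned to
#: put roughly 47% of mass below 25, the under/over split seen in
#: population drivers'-license data.
DEFAULT_BMI_MIXTURE: tuple[tuple[float, float, float], ...] = (
    (0.42, 22.0, 2.0),
    (0.58, 30.0, 4.5),
)

_BENIGN_CODES = (("ICD9", "V70.0"), ("ICD10", "Z00"), ("ICD9", "780.9"),
                 ("ICD10", "R69"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic population.

    ``familial_ad_multipliers`` are the per-affected-relative risk
    multipliers (lambda1, lambda2, lambda3) for first/second/third-degree
    ancestor-side relatives; ``injected_rr`` maps phenotype labels to the
    risk ratio theta applied to members of a designated elevated set.
    """

    n_founders: int = 300
    n_generations: int = 4
    mean_children: float = 3.0
    birth_year_range: tuple[int, int] = (1850, 2000)
    p_utah_birth: float = 0.85
    p_emr_linked: float = 0.65
    p_dl_linked: float = 0.52
    ad_baseline_rate_by_cohort: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_AD_RATES)
    )
    familial_ad_multipliers: tuple[float, float, float] = (2.5, 1.5, 1.2)
    phenotype_baseline_rates: dict[str, float | dict[int, float]] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_RATES)
    )
    injected_rr: dict[str, float] = field(default_factory=dict)
    bmi_mixture: tuple[tuple[float, float, float], ...] = DEFAULT_BMI_MIXTURE
    allow_consanguinity: bool = False
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_founders < 2:
            raise ConfigError("n_founders: need at least 2 founders")
        if self.n_generations < 2:
            raise ConfigError(
                "n_generations: a pedigree requires at least 2 generations"
            )
        if self.mean_children < 1:
            raise ConfigError(
                "mean_children: must be >= 1 (every couple has a child)"
            )
        y0, y1 = self.birth_year_range
        if y1 <= y0:
            raise ConfigError("birth_year_range: end must exceed start")
        for name in ("p_utah_birth", "p_emr_linked", "p_dl_linked"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}: probability {p} outside [0, 1]")
        for band, r in self.ad_baseline_rate_by_cohort.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigError(
                    f"ad_baseline_rate_by_cohort[{band}]: rate {r} outside [0, 1]"
                )
        if len(self.familial_ad_multipliers) != 3 or any(
            m <= 0 for m in self.familial_ad_multipliers
        ):
            raise ConfigError(
                "familial_ad_multipliers: need three strictly positive values"
            )
        for label, spec in self.phenotype_baseline_rates.items():
            rates = spec.values() if isinstance(spec, dict) else [spec]
            if any(not 0.0 <= r <= 1.0 for r in rates):
                raise ConfigError(
                    f"phenotype_baseline_rates[{label!r}]: rate outside [0, 1]"
                )
        for label, theta in self.injected_rr.items():
            if theta < 0:
                raise ConfigError(f"injected_rr[{label!r}]: theta must be >= 0")
        if abs(sum(w for w, _, _ in self.bmi_mixture) - 1.0) > 1e-9:
            raise ConfigError("bmi_mixture: component weights must sum to 1")

    def ad_rate_for(self, birth_year: int) -> float:
        for (start, end), rate in self.ad_baseline_rate_by_cohort.items():
            if start <= birth_year < end:
                return rate
        raise CohortRateError(
            f"no baseline AD rate covers birth year {birth_year} "
            f"(cohort bin {birth_year_bin(birth_year)})"
        )


@dataclass
class PopulationBundle:
    """The four linked tables one synthetic population comprises."""

    individuals: pd.DataFrame
    diagnoses: pd.DataFrame
    cancer_records: pd.DataFrame
    biometrics: pd.DataFrame

    def validate(self) -> None:
        known = set(self.individuals["person_id"])
        for name, table in (
            ("diagnoses", self.diagnoses),
            ("cancer_records", self.cancer_records),
            ("biometrics", self.biometrics),
        ):
            orphans = set(table["person_id"]) - known
            if orphans:
                raise DataError(
                    f"{name}: {len(orphans)} person ids not in individuals "
                    f"(e.g. {next(iter(orphans))})"
                )
        if self.biometrics["person_id"].duplicated().any():
            dup = self.biometrics.loc[
                self.biometrics["person_id"].duplicated(), "person_id"
            ].iloc[0]
            raise DataError(f"biometrics: person {dup} has more than one row")
        bad = set(self.diagnoses["code_system"]) - set(CODE_SYSTEMS)
        if bad:
            raise ParseError(f"diagnoses: unknown code system {bad.pop()!r}")


# -- pedigree structure ----------------------------------------------------

def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None
                      ) -> pd.DataFrame:
    """Generate a multi-generation individuals table with parent links.

    Founders (generation 0, alternating sex) marry within generation.
    Unless ``allow_consanguinity`` is set, a marriage may only join two
    family clusters not yet connected by blood or marriage (tracked by
    union-find), so every relationship in the pedigree is single-path and
    kinship coefficients sit exactly on the 1/2^(d+1) degree bands; where
    no compatible partner exists, an unrelated spouse 'marries in' (a
    parentless individual of the same generation).  Every couple has
    ``1 + Poisson(mean_children - 1)`` children, so the expected sibship
    size equals ``mean_children`` exactly.  Linkage flags, birth state and
    vital status are drawn afterwards in fixed order.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    y0, y1 = config.birth_year_range
    founder_window = max(1, (y1 - y0) // config.n_generations)

    sex: list[str] = []
    birth: list[int] = []
    mother: list[int | None] = []
    father: list[int | None] = []
    gen: list[int] = []
    comp: list[int] = []  # union-find over family clusters

    def find(x: int) -> int:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    def add_person(s: str, by: int, g: int,
                   m: int | None = None, f: int | None = None) -> int:
        pid = len(sex)
        sex.append(s)
        birth.append(by)
        mother.append(m)
        father.append(f)
        gen.append(g)
        comp.append(pid if m is None else find(m))
        return pid

    for i in range(config.n_founders):
        add_person(
            "M" if i % 2 == 0 else "F",
            int(rng.integers(y0, y0 + founder_window + 1)),
            0,
        )

    for g in range(config.n_generations - 1):
        members = [p for p in range(len(sex)) if gen[p] == g]
        males = [p for p in members if sex[p] == "M"]
        females = [p for p in members if sex[p] == "F"]
        rng.shuffle(males)
        rng.shuffle(females)

        couples: list[tuple[int, int]] = []
        free_females = list(females)
        for m in males:
            match = None
            # scan a bounded window for a partner from an unconnected family
            for j, f in enumerate(free_females[:25]):
                if config.allow_consanguinity or find(m) != find(f):
                    match = j
                    break
            if match is not None:
                partner = free_females.pop(match)
                comp[find(partner)] = find(m)
                couples.append((m, partner))
            else:
                spouse = add_person(
                    "F", birth[m] + int(rng.integers(-3, 4)), g
                )
                comp[find(spouse)] = find(m)
                couples.append((m, spouse))
        for f in free_females:
            spouse = add_person("M", birth[f] + int(rng.integers(-3, 4)), g)
            comp[find(spouse)] = find(f)
            couples.append((spouse, f))

        for m, f in couples:
            n_children = 1 + int(rng.poisson(config.mean_children - 1))
            for _ in range(n_children):
                add_person(
                    "M" if rng.random() < 0.5 else "F",
                    max(birth[m], birth[f]) + int(rng.integers(18, 41)),
                    g + 1,
                    m=f,
                    f=m,
                )

    n = len(sex)
    person_id = np.arange(1, n + 1)
    birth_arr = np.asarray(birth)
    reference_year = int(birth_arr.max())

    utah_born = rng.random(n) < config.p_utah_birth
    emr_linked = rng.random(n) < config.p_emr_linked
    adult = birth_arr <= reference_year - 16
    dl_linked = (rng.random(n) < config.p_dl_linked) & adult
    lifespan = np.maximum(1, rng.normal(78, 12, size=n)).round().astype(int)
    death = birth_arr + lifespan
    death_year = pd.array(
        np.where(death <= reference_year, death, -1), dtype="Int64"
    )
    death_year[np.asarray(death > reference_year)] = pd.NA

    to_id = lambda p: pd.NA if p is None else p + 1  # noqa: E731
    return pd.DataFrame(
        {
            "person_id": person_id,
            "sex": sex,
            "birth_year": birth_arr,
            "utah_born": utah_born,
            "mother_id": pd.array([to_id(m) for m in mother], dtype="Int64"),
            "father_id": pd.array([to_id(f) for f in father], dtype="Int64"),
            "death_year": death_year,
            "generation": gen,
            "emr_linked": emr_linked,
            "dl_linked": dl_linked,
        }
    )


# -- AD status with familial aggregation -----------------------------------

def simulate_ad_status(
    individuals: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    graph: PedigreeGraph | None = None,
) -> pd.Series:
    """Assign AD status person by person in generation order.

    Person ``i`` is affected with probability
    ``min(1, r_cohort(i) * l1^k1 * l2^k2 * l3^k3)`` where ``k_d`` counts
    already-assigned affected degree-``d`` relatives, descendants excluded
    (processing in generation order makes each probability well defined at
    assignment time).  Returns a boolean Series indexed by person_id.
    """
    if graph is None:
        graph = build_pedigree(individuals)
    l1, l2, l3 = config.familial_ad_multipliers
    if "generation" in individuals.columns:
        order = individuals.sort_values(["generation", "person_id"])["person_id"]
    else:
        depths = graph.generation_depths()
        order = pd.Series(sorted(depths, key=lambda p: (depths[p], p)))
    birth = individuals.set_index("person_id")["birth_year"]

    affected: set[int] = set()
    flags: dict[int, bool] = {}
    for pid in order:
        pid = int(pid)
        r = config.ad_rate_for(int(birth[pid]))
        relset = graph.relatives_by_degree(pid, max_degree=3)
        descendants = graph.descendants(pid, max_depth=3)
        k = [
            sum(
                1
                for rel in relset.by_degree.get(d, {})
                if rel in affected and rel not in descendants
            )
            for d in (1, 2, 3)
        ]
        p = min(1.0, r * l1 ** k[0] * l2 ** k[1] * l3 ** k[2])
        hit = bool(rng.random() < p)
        flags[pid] = hit
        if hit:
            affected.add(pid)
    out = pd.Series(flags, name="ad")
    return out.reindex(individuals["person_id"].to_numpy())


# -- phenotypes -------------------------------------------------------------

def _rate_vector(
    individuals: pd.DataFrame, label: str, spec: float | dict[int, float]
) -> np.ndarray:
    if isinstance(spec, dict):
        bins = individuals["birth_year"].map(birth_year_bin)
        missing = sorted(set(bins) - set(spec))
        if missing:
            raise CohortRateError(
                f"{label!r}: no baseline rate for birth bins {missing[:5]}"
            )
        return bins.map(spec).to_numpy(dtype=float)
    return np.full(len(individuals), float(spec))


def _emittable_codes(catalog: PhenotypeCatalog, label: str) -> list[tuple[str, str]]:
    """Concrete (system, code) pairs that classify uniquely to ``label``.

    Tries the bare prefixes and simple one-digit extensions; the dotted
    presentation is reintroduced at emission time to exercise
    normalization downstream.
    """
    out = []
    for system in CODE_SYSTEMS:
        for prefix in catalog.prefixes(system, label):
            for cand in (prefix, prefix + "0", prefix + "1", prefix + "9"):
                if catalog.classify(system, cand) == {label}:
                    out.append((system, cand))
    if not out:
        raise DataError(f"phenotype {label!r}: no unambiguous codes to emit")
    return out


def _with_dot(system: str, code: str, rng: np.random.Generator) -> str:
    if len(code) > 3 and rng.random() < 0.5:
        return code[:3] + "." + code[3:]
    return code


def simulate_phenotypes(
    individuals: pd.DataFrame,
    config: SimConfig,
    elevated_set: set[int],
    rng: np.random.Generator,
    catalog: PhenotypeCatalog | None = None,
    site_catalog: CancerSiteCatalog | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw comorbidity diagnoses and registry cancer records.

    Each person is affected by phenotype ``ph`` with probability
    ``min(1, rate_cohort * theta)`` where ``theta = injected_rr[ph]`` for
    members of ``elevated_set`` and 1 otherwise.  Comorbid diagnoses only
    materialize for EMR-linked persons (no chart, no code); cancer records
    cover the whole population, mirroring registry ascertainment.
    Affected persons receive 1-2 codes from the phenotype's catalog, plus
    occasional benign codes that match nothing.
    """
    catalog = catalog or default_phenotype_catalog()
    site_catalog = site_catalog or CancerSiteCatalog()
    unknown_elevated = elevated_set - set(individuals["person_id"])
    if unknown_elevated:
        raise DataError(
            f"elevated_set contains {len(unknown_elevated)} unknown person ids"
        )
    for label in config.injected_rr:
        if label not in config.phenotype_baseline_rates:
            raise DataError(f"injected_rr names unknown phenotype {label!r}")

    pid_arr = individuals["person_id"].to_numpy()
    elevated_mask = np.isin(pid_arr, sorted(elevated_set))
    emr_mask = individuals["emr_linked"].to_numpy(dtype=bool)
    female = (individuals["sex"] == "F").to_numpy()

    diag_rows: list[tuple[int, str, str]] = []
    cancer_rows: list[tuple[int, str]] = []

    for label in COMORBIDITIES:
        if label not in config.phenotype_baseline_rates:
            raise DataError(f"phenotype {label!r} missing from baseline rates")
        rates = _rate_vector(individuals, label, config.phenotype_baseline_rates[label])
        theta = config.injected_rr.get(label, 1.0)
        p = np.minimum(1.0, rates * np.where(elevated_mask, theta, 1.0))
        hit = (rng.random(len(p)) < p) & emr_mask
        codes = _emittable_codes(catalog, label)
        for pid in pid_arr[hit]:
            for _ in range(1 + int(rng.random() < 0.4)):
                system, code = codes[int(rng.integers(len(codes)))]
                diag_rows.append((int(pid), system, _with_dot(system, code, rng)))

    # benign noise codes on EMR-linked persons
    noise = (rng.random(len(pid_arr)) < 0.2) & emr_mask
    for pid in pid_arr[noise]:
        system, code = _BENIGN_CODES[int(rng.integers(len(_BENIGN_CODES)))]
        diag_rows.append((int(pid), system, code))

    sex_limited = {"Breast": female, "Cervix": female, "Ovary": female,
                   "Prostate": ~female}
    for site in site_catalog.sites:
        if site not in config.phenotype_baseline_rates:
            raise DataError(f"cancer site {site!r} missing from baseline rates")
        rates = _rate_vector(individuals, site, config.phenotype_baseline_rates[site])
        theta = config.injected_rr.get(site, 1.0)
        p = np.minimum(1.0, rates * np.where(elevated_mask, theta, 1.0))
        if site in sex_limited:
            p = p * sex_limited[site]
        hit = rng.random(len(p)) < p
        cancer_rows.extend((int(pid), site) for pid in pid_arr[hit])

    diagnoses = pd.DataFrame(diag_rows, columns=["person_id", "code_system", "code"])
    cancers = pd.DataFrame(cancer_rows, columns=["person_id", "site"])
    return diagnoses, cancers


def simulate_biometrics(
    individuals: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """One height/weight row per drivers'-license-linked person.

    Height is drawn per sex; BMI from the configured mixture (truncated at
    12); weight follows as BMI x height^2.
    """
    linked = individuals[individuals["dl_linked"].astype(bool)]
    n = len(linked)
    female = (linked["sex"] == "F").to_numpy()
    height = np.where(
        female, rng.normal(163.0, 6.5, n), rng.normal(177.0, 7.0, n)
    ).clip(120, 220)
    weights = np.array([w for w, _, _ in config.bmi_mixture])
    comp = rng.choice(len(weights), size=n, p=weights / weights.sum())
    means = np.array([m for _, m, _ in config.bmi_mixture])[comp]
    sds = np.array([s for _, _, s in config.bmi_mixture])[comp]
    bmi_vals = np.maximum(12.0, rng.normal(means, sds))
    weight = bmi_vals * (height / 100.0) ** 2
    return pd.DataFrame(
        {
            "person_id": linked["person_id"].to_numpy(),
            "height_cm": height.round(1),
            "weight_kg": weight.round(1),
        }
    )


# -- end-to-end bundle ------------------------------------------------------

def generate_population(
    config: SimConfig,
    elevated_set: set[int] | None = None,
    catalog: PhenotypeCatalog | None = None,
    site_catalog: CancerSiteCatalog | None = None,
) -> PopulationBundle:
    """Simulate a full linked-record bundle from one config.

    AD-affected persons always receive an AD code row (case ascertainment
    spans death certificates as well as EMR, so it is not gated on EMR
    linkage).  If ``elevated_set`` is None and ``injected_rr`` is set, the
    elevated set defaults to persons with at least one AD-affected parent.
    """
    config.validate()
    catalog = catalog or default_phenotype_catalog()
    site_catalog = site_catalog or CancerSiteCatalog()
    rng = np.random.default_rng(config.rng_seed)

    individuals = simulate_pedigree(config, rng)
    graph = build_pedigree(individuals)
    ad = simulate_ad_status(individuals, config, rng, graph)

    if elevated_set is None:
        affected = set(individuals.loc[ad.to_numpy(), "person_id"])
        elevated_set = {
            int(row.person_id)
            for row in individuals.itertuples(index=False)
            if (not pd.isna(row.mother_id) and int(row.mother_id) in affected)
            or (not pd.isna(row.father_id) and int(row.father_id) in affected)
        }

    diagnoses, cancers = simulate_phenotypes(
        individuals, config, elevated_set, rng, catalog, site_catalog
    )
    ad_codes = _emittable_codes(catalog, AD_LABEL)
    ad_rows = [
        (
            int(pid),
            *ad_codes[int(rng.integers(len(ad_codes)))],
        )
        for pid in individuals.loc[ad.to_numpy(), "person_id"]
    ]
    if ad_rows:
        diagnoses = pd.concat(
            [
                diagnoses,
                pd.DataFrame(ad_rows, columns=["person_id", "code_system", "code"]),
            ],
            ignore_index=True,
        )
    biometrics = simulate_biometrics(individuals, config, rng)

    bundle = PopulationBundle(
        individuals=individuals,
        diagnoses=diagnoses,
        cancer_records=cancers,
        biometrics=biometrics,
    )
    bundle.validate()
    return bundle


# -- CSV interchange --------------------------------------------------------

_FILES = ("individuals", "diagnoses", "cancer_records", "biometrics")


def write_bundle(bundle: PopulationBundle, directory: str | Path) -> None:
    """Write the four bundle tables as CSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _FILES:
        getattr(bundle, name).to_csv(directory / f"{name}.csv", index=False)


def read_bundle(directory: str | Path) -> PopulationBundle:
    """Read a bundle directory, validating headers and foreign keys."""
    directory = Path(directory)
    tables = {}
    dtypes: dict[str, dict] = {
        "individuals": {
            "person_id": "int64",
            "sex": "string",
            "birth_year": "int64",
            "utah_born": "bool",
            "mother_id": "Int64",
            "father_id": "Int64",
            "death_year": "Int64",
            "generation": "int64",
            "emr_linked": "bool",
            "dl_linked": "bool",
        },
        "diagnoses": {"person_id": "int64", "code_system": "string",
                      "code": "string"},
        "cancer_records": {"person_id": "int64", "site": "string"},
        "biometrics": {"person_id": "int64", "height_cm": "float64",
                       "weight_kg": "float64"},
    }
    for name in _FILES:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise ParseError(f"missing bundle file {path}")
        try:
            table = pd.read_csv(path, dtype=dtypes[name])
        except (ValueError, KeyError) as exc:
            raise ParseError(f"{path}: {exc}") from exc
        expected = list(dtypes[name])
        if list(table.columns) != expected:
            raise ParseError(
                f"{path}: malformed header {list(table.columns)} "
                f"(expected {expected})"
            )
        tables[name] = table
    diag = tables["diagnoses"]
    bad = ~diag["code_system"].isin(CODE_SYSTEMS)
    if bad.any():
        row = int(bad.idxmax()) + 2  # header is line 1
        raise ParseError(
            f"diagnoses.csv line {row}: unknown code system "
            f"{diag.loc[bad.idxmax(), 'code_system']!r}"
        )
    for name in ("diagnoses", "cancer_records", "biometrics"):
        for col in tables[name].columns:
            if col in ("code", "code_system", "site"):
                tables[name][col] = tables[name][col].astype(str)
    bundle = PopulationBundle(**tables)
    bundle.validate()
    return bundle


def null_config(**overrides) -> SimConfig:
    """A config with no familial effect and no injected risk (all-null)."""
    base = SimConfig(
        familial_ad_multipliers=(1.0, 1.0, 1.0), injected_rr={}
    )
    return replace(base, **overrides)
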