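"""Phenotype definitions: ICD-9/10 code catalogs, cancer sites, and BMI.

Comorbid conditions are defined by ICD-9 and ICD-10 code prefixes matched
against dot-stripped, uppercased codes, so a three-character stem such as
``250`` captures every ``250.xx`` diabetes code.  Cancer phenotypes are
defined by registry primary-site labels (standing in for SEER site
recodes; the site-code-to-label map is a pluggable table).  BMI categories
use the conventional cut points 18.5 / 25 / 30 / 40 with lower bounds
closed.

Note: the cerebrovascular-disease catalog deliberately includes ICD-9 346
and ICD-10 G43, which are migraine codes.  The default catalog reproduces
the study definition verbatim rather than correcting it; callers needing a
stricter definition can supply their own catalog.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError, ParseError

logger = logging.getLogger(__name__)

CODE_SYSTEMS = ("ICD9", "ICD10")

#: Comorbid phenotype labels, in reporting order.
COMORBIDITIES = (
    "diabetes",
    "hypertension",
    "heart disease",
    "cerebrovascular disease",
    "dementia excluding AD",
)

#: Alzheimer's disease itself — used for case ascertainment and exclusion,
#: never tested as a comorbidity.
AD_LABEL = "alzheimers disease"

#: The 15 registry cancer sites, in reporting order, plus the derived
#: union label.
CANCER_SITES = (
    "Breast",
    "Colorectal",
    "Kidney",
    "Lung and bronchus",
    "Non-Hodgkin lymphoma",
    "Pancreas",
    "Stomach",
    "Bladder",
    "Brain",
    "Cervix",
    "Leukemia",
    "Melanoma",
    "Ovary",
    "Prostate",
    "Thyroid",
)
ANY_CANCER = "Any cancer"


def normalize_code(code_system: str, raw: str) -> str:
    """Normalize a diagnosis code: uppercase, strip whitespace, drop dots.

    Raises :class:`ParseError` for an empty code or unknown code system.
    """
    if code_system not in CODE_SYSTEMS:
        raise ParseError(f"unknown code system {code_system!r}")
    token = str(raw).strip().upper().replace(".", "")
    if not token:
        raise ParseError(f"empty {code_system} code")
    return token


def _expand_range(spec: str) -> list[str]:
    """Expand ``401-404`` or ``I10-I13`` style ranges into member stems.

    Both endpoints must share the alphabetic prefix and numeric width;
    expansion steps through the numeric tail.
    """
    lo, hi = spec.split("-")
    m_lo = re.fullmatch(r"([A-Z]*)(\d+)", lo)
    m_hi = re.fullmatch(r"([A-Z]*)(\d+)", hi)
    if not m_lo or not m_hi or m_lo.group(1) != m_hi.group(1):
        raise DataError(f"malformed code range {spec!r}")
    alpha, width = m_lo.group(1), len(m_lo.group(2))
    return [
        f"{alpha}{n:0{width}d}"
        for n in range(int(m_lo.group(2)), int(m_hi.group(2)) + 1)
    ]


def _prefixes(system: str, specs: str) -> tuple[str, ...]:
    out: list[str] = []
    for spec in specs.split(","):
        spec = normalize_code(system, spec)
        spec = spec.replace("–", "-")
        if "-" in spec:
            out.extend(_expand_range(spec))
        else:
            out.append(spec)
    return tuple(out)


@dataclass(frozen=True)
class PhenotypeCatalog:
    """Maps phenotype labels to ICD-9/ICD-10 code-prefix lists."""

    icd9: dict[str, tuple[str, ...]]
    icd10: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if set(self.icd9) != set(self.icd10):
            raise DataError("ICD9 and ICD10 maps must cover the same phenotypes")
        for label in self.icd9:
            if not self.icd9[label] and not self.icd10[label]:
                raise DataError(f"phenotype {label!r} has an empty code list")

    @property
    def phenotypes(self) -> tuple[str, ...]:
        return tuple(self.icd9)

    def prefixes(self, code_system: str, label: str) -> tuple[str, ...]:
        table = {"ICD9": self.icd9, "ICD10": self.icd10}.get(code_system)
        if table is None:
            raise ParseError(f"unknown code system {code_system!r}")
        if label not in table:
            raise DataError(f"unknown phenotype {label!r}")
        return table[label]

    def classify(self, code_system: str, raw_code: str) -> set[str]:
        """Return every phenotype whose prefix list matches the code."""
        token = normalize_code(code_system, raw_code)
        table = self.icd9 if code_system == "ICD9" else self.icd10
        return {
            label
            for label, prefixes in table.items()
            if any(token.startswith(p) for p in prefixes)
        }


def default_phenotype_catalog() -> PhenotypeCatalog:
    """The study's comorbidity code lists, plus AD codes for exclusion."""
    icd9 = {
        "diabetes": _prefixes("ICD9", "250"),
        "hypertension": _prefixes("ICD9", "401-404"),
        "heart disease": _prefixes(
            "ICD9",
            "391, 393-398, 410-414, 424-425, 427.3, 427.4, 427.5, 428, 440, 443.9",
        ),
        "cerebrovascular disease": _prefixes("ICD9", "346"),
        "dementia excluding AD": _prefixes(
            "ICD9", "290, 292.82, 294, 331.11, 331.82, 331.83, 332"
        ),
        AD_LABEL: _prefixes("ICD9", "331.0"),
    }
    icd10 = {
        "diabetes": _prefixes("ICD10", "E10, E11, E14"),
        "hypertension": _prefixes("ICD10", "I10-I13, I270"),
        "heart disease": _prefixes(
            "ICD10",
            "I01, I02, I05-I09, I21, I22, I24, I34-I37, I45.9, I46-I50, I70, "
            "I110, I130, I132, I25, I250, I251, I255, I420-I422, I425, I428, "
            "I429, I490, I739, Z95.1",
        ),
        "cerebrovascular disease": _prefixes(
            "ICD10", "I63, I67.2, I67.89, I67.9, I69, G43, G46, Z86.73"
        ),
        "dementia excluding AD": _prefixes(
            "ICD10", "F01-F03, F18.97, F19.17, F19.97, G20, G31.0, G31.83, G31.84"
        ),
        AD_LABEL: _prefixes("ICD10", "G30"),
    }
    return PhenotypeCatalog(icd9=icd9, icd10=icd10)


classify_diagnosis = PhenotypeCatalog.classify


def person_phenotype_flags(
    catalog: PhenotypeCatalog, diagnoses: pd.DataFrame
) -> pd.DataFrame:
    """Collapse a diagnosis table to ever/never phenotype flags per person.

    Parameters
    ----------
    diagnoses
        Columns ``person_id``, ``code_system``, ``code``.  Codes matching no
        catalog phenotype are ignored (counted in a log summary); dates are
        never used — one qualifying row flags the person for life.

    Returns
    -------
    DataFrame indexed by ``person_id`` with one boolean column per catalog
    phenotype.  Persons with no qualifying rows are absent; treat missing
    as False.
    """
    flags: dict[str, set] = {label: set() for label in catalog.phenotypes}
    unknown = 0
    for system, group in diagnoses.groupby("code_system"):
        if system not in CODE_SYSTEMS:
            raise ParseError(f"unknown code system {system!r}")
        # classify each distinct code once, then fan out to persons
        for code, sub in group.groupby("code"):
            labels = catalog.classify(str(system), str(code))
            if not labels:
                unknown += len(sub)
                continue
            persons = set(sub["person_id"])
            for label in labels:
                flags[label] |= persons
    if unknown:
        logger.info("person_phenotype_flags: %d rows with unmapped codes", unknown)
    persons = sorted(set().union(*flags.values())) if any(flags.values()) else []
    out = pd.DataFrame(index=pd.Index(persons, name="person_id"))
    for label in catalog.phenotypes:
        out[label] = [p in flags[label] for p in persons]
    return out


@dataclass(frozen=True)
class CancerSiteCatalog:
    """Registry site-code → site-label map.

    By default each of the 15 study sites maps to itself, i.e. the
    synthetic registry records carry site labels directly.  Real SEER
    primary-site recodes can be dropped in by supplying a different
    ``code_to_label`` table.
    """

    sites: tuple[str, ...] = CANCER_SITES
    code_to_label: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sites)) != len(self.sites):
            raise DataError("cancer site labels must be distinct")

    def label_for(self, site_code: str) -> str | None:
        if self.code_to_label:
            return self.code_to_label.get(site_code)
        return site_code if site_code in self.sites else None

    def site_flags(self, cancer_records: pd.DataFrame) -> pd.DataFrame:
        """Ever/never flags per person per site, plus the any-cancer union."""
        persons = sorted(set(cancer_records["person_id"]))
        out = pd.DataFrame(index=pd.Index(persons, name="person_id"))
        labels = cancer_records["site"].map(lambda s: self.label_for(str(s)))
        unknown = int(labels.isna().sum())
        if unknown:
            logger.info("site_flags: %d records with unmapped site codes", unknown)
        by_site = {
            label: set(cancer_records.loc[labels == label, "person_id"])
            for label in self.sites
        }
        for label in self.sites:
            out[label] = [p in by_site[label] for p in persons]
        out[ANY_CANCER] = out[list(self.sites)].any(axis=1)
        return out


# --- BMI -----------------------------------------------------------------

#: Ordered category labels with half-open boundaries [lo, hi).
BMI_CATEGORIES = (
    ("underweight", 0.0, 18.5),
    ("normal", 18.5, 25.0),
    ("overweight", 25.0, 30.0),
    ("obese", 30.0, 40.0),
    ("morbidly obese", 40.0, float("inf")),
)

BMI_BINARY_LOW = "underweight/normal"
BMI_BINARY_HIGH = "overweight/obese/morbidly obese"


def bmi(height_cm: float, weight_kg: float) -> float:
    """Body-mass index: weight (kg) / height (m) squared."""
    if height_cm <= 0 or weight_kg <= 0:
        raise DataError(
            f"height and weight must be positive (got {height_cm}, {weight_kg})"
        )
    h = height_cm / 100.0
    return weight_kg / (h * h)


def bmi_category(value: float) -> str:
    """Five-level BMI category; lower bound of each interval is closed."""
    if value <= 0:
        raise DataError(f"BMI must be positive (got {value})")
    for label, lo, hi in BMI_CATEGORIES:
        if lo <= value < hi:
            return label
    raise AssertionError("unreachable: categories partition (0, inf)")


def collapse_bmi(label: str) -> str:
    """Collapse the five categories into the binary under/over-25 split."""
    if label in ("underweight", "normal"):
        return BMI_BINARY_LOW
    if label in ("overweight", "obese", "morbidly obese"):
        return BMI_BINARY_HIGH
    raise DataError(f"unknown BMI category {label!r}")


def imperial_to_metric(height_in: float, weight_lb: float) -> tuple[float, float]:
    """Convert self-reported imperial height/weight to (cm, kg)."""
    return height_in * 2.54, weight_lb * 0.45359237
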