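# Methods

This note documents the models, conventions and numerical choices behind
`famrisk`, in the order the pipeline runs them.

## Study design in brief

The design estimates disease rates in people at high *familial* risk for
Alzheimer's disease (AD) but not diagnosed with it.  Each person carries
a family-history constellation — a signature of counts of AD-affected
relatives by degree of relatedness and lineage.  Constellations whose AD
relative risk (observed/expected over their probands) exceeds 2.0 define
the high-risk group; already-diagnosed members are removed.  Comorbidity
and cancer rates in this group are then compared against whole-population
cohort rates by indirect standardization.  All rates are lifetime
ever/never proportions; there is no person-time, survival or competing
risk modelling anywhere in the pipeline, by design.

## Synthetic population generator

The generator (`famrisk.simulate`) emulates the statistical structure of
a founder-population genealogy with linked records.  It is a study-bed
for the estimators, not a demographic model.

**Pedigree structure.**  Founders form generation 0 with alternating
sex.  Within each generation, males and females are paired; unless
`allow_consanguinity` is set, a marriage may only join two family
clusters not yet connected by blood *or* marriage, tracked by union-find.
This is deliberately stronger than merely forbidding shared ancestors:
it excludes double-first-cousin and affinal multi-path configurations,
so every pair of relatives is connected through a single ancestral
couple and kinship coefficients sit exactly on the 1/2^(d+1) degree
bands — the property the classification oracle tests rely on.  When no
compatible partner exists in the scanned window, an unrelated spouse
"marries in" as a parentless individual of the same generation (so
founder counts exceed `n_founders`).  Each couple has
`1 + Poisson(mean_children − 1)` children; the +1 makes the expected
sibship size equal `mean_children` exactly and keeps every couple
observable in the emitted table.  Child birth years are the later parent
birth year plus Uniform{18..40}.

**Defaults.**  `n_founders=300`, `n_generations=4`, `mean_children=3`
(large historical families), founder births 1850–1887 within a
1850–2000 range, 85% in-state births, EMR linkage 0.65 and
drivers'-license linkage 0.52 (the approximate linked fractions of a
genealogy-wide registry), license rows restricted to persons aged ≥ 16
by the latest observed birth year.  Lifespans are Normal(78, 12) years,
recorded as a death year only when it falls before the reference year.

**Familial AD model.**  Persons are processed in generation order.
Person *i* is affected with probability
`min(1, r_cohort(i) · λ₁^k₁ · λ₂^k₂ · λ₃^k₃)`, where `k_d` counts
*already assigned* affected degree-d relatives, descendants excluded, so
each probability is well defined at assignment time.  This multiplicative
ancestor-side model is a simulator convention chosen for testability —
the study design being emulated only *measures* familial aggregation and
implies no particular generative mechanism.  Default multipliers
(2.5, 1.5, 1.2) give first-degree aggregation in the range familial-risk
studies of dementia typically report.  Baseline AD rates are
age-banded by birth year (5% for pre-1920 births falling to 0.2% after
1960) because recent cohorts have not lived through the ages of peak
risk.  With all multipliers 1 the model reduces to independent draws at
the cohort rate — the null used for calibration tests.

**Phenotypes.**  Each comorbidity/cancer site has a baseline rate
(scalar or per-birth-bin); person *i*'s probability is
`min(1, rate · θ)` with `θ = injected_rr[phenotype]` for members of a
designated elevated set, 1 otherwise.  Comorbid diagnoses only
materialize for EMR-linked persons (no chart, no code); cancer records
cover everyone, mirroring registry ascertainment; AD code rows are
emitted for every affected person regardless of EMR linkage, standing in
for the death-certificate ascertainment that covers the whole genealogy.
Affected persons receive one or two codes drawn from the subset of
catalog codes that classify *uniquely* to their phenotype (so injected
effects stay independent across phenotypes despite the genuinely
overlapping code lists); 20% of EMR-linked persons also receive a benign
code that matches nothing, exercising the unknown-code path.  BMI comes
from a two-component normal mixture with ~47% of mass below 25,
matching the under/over-25 split seen in population license data.

**What the generator does not emulate:** record-linkage errors,
longitudinal/dated EMR streams, mortality-differential ascertainment,
assortative mating, migration, or secular trends in diagnosis coding.
Tests passing on this generator validate the *estimators* under the
stated statistical structure; they say nothing about robustness to those
real-data complications.

## Pedigree classification

Degrees follow the standard genetic-epidemiology convention: degree 1 =
parents, full siblings, children; degree 2 = grandparents,
grandchildren, half-siblings, aunts/uncles, nieces/nephews; degree 3 =
great-grandparents, great-grandchildren, first cousins,
great-aunts/-uncles, half-aunts/-uncles, grand-nieces/-nephews.  A
relative reachable several ways keeps its minimal degree.  Lineage is
the side of the first parental step from the proband: ancestors and
collateral kin are maternal or paternal; siblings and descendants —
reachable through both parents or through neither — are `none`.
Consanguineous pedigrees are classified by shortest-path degree with a
logged warning; the kinship-band equivalence (degree d ⇔ kinship
1/2^(d+1)) is asserted only for outbred pedigrees, against an
independent recursive kinship implementation that shares no code with
the classifier.

The ancestral-completeness filter (both parents, all four grandparents,
and ≥ 6 of 8 great-grandparent slots) is available but **off by default
in the pipeline**: in a four-generation synthetic pedigree only the last
generation can satisfy it, and married-in spouses make even that sparse,
so applying it by default would leave almost no eligible probands at
simulation scale.  It is a one-flag switch for deeper pedigrees.

## Phenotype catalogs

Comorbidities are defined by ICD-9/ICD-10 code-prefix lists matched
against dot-stripped uppercased codes; ranges (401–404, I10–I13,
I420–I422) are expanded over their numeric tails.  Two deliberate
verbatim quirks of the source definitions are preserved rather than
corrected: ICD-9 346 and ICD-10 G43 (migraine codes) sit in the
cerebrovascular-disease list, and I110/I130/I132 appear under heart
disease while the I10–I13 stems define hypertension, so a code like
I11.0 legitimately maps to both.  AD itself is carried as a catalog
entry (ICD-9 331.0, ICD-10 G30 — the standard codes; the source lists
none explicitly) for case ascertainment and exclusion only.  Cancer
phenotypes are registry site labels; the site-code→label map is a
pluggable table so real SEER primary-site recodes could be dropped in.
Unknown codes are counted and logged, never fatal.

BMI categories use cut points 18.5/25/30/40, each lower bound closed,
with the binary collapse at 25.  Heights/weights are stored metric; an
imperial conversion helper is provided.

## Cohorts and rates

Cohorts are sex × 5-year birth bin (anchored at multiples of 5,
half-open) × birth-state flag.  Rates are `affected/total` per cohort;
zero-member cohorts are omitted, and a lookup for a missing cohort
raises rather than imputes — a high-risk member whose cohort has no rate
is a data problem to surface, not smooth over.  Denominators follow the
design being emulated: EMR-linked subpopulation for comorbidities, full
genealogy population for AD and cancer; both are explicit arguments.
High-risk members are *not* excluded from denominators (the comparison
is against the whole population, overlap included), which biases RRs
slightly toward 1 when the high-risk fraction is large; parameter
recovery therefore uses a 5% elevated fraction where the attenuation is
well under the test tolerance.  Cancer sites enter the analysis only
with ≥ `min_cancer_cases` observed cases (100 at registry scale;
configurable because synthetic populations are orders of magnitude
smaller).

## Constellations and selection

Signatures count affected relatives in five strata — first-degree
pooled, second- and third-degree split maternal/paternal — capped at 3+,
giving ≤ 4⁵ = 1024 possible signatures.  Affected degree-2/3 relatives
with lineage `none` (grandchildren, nieces/nephews, and descendant-side
kin generally) are not counted: the stratification is by inheritance
side, which descendant-side kin do not have.  Each person has exactly
one signature, so high-risk membership cannot double-count.  Selection
takes constellations with RR strictly > 2.0 and at least `min_probands`
probands (default 10 — small constellations give unstable RRs; the
threshold is configurable and the published-count worked examples do not
depend on it), then removes already-diagnosed persons.  The manifest
records identified, excluded and analyzed counts and asserts
`identified − excluded = analyzed`.

## Association statistics

"Agresti method" inference is implemented as the Agresti–Coull
adjusted-Wald interval for the binomial proportion `O/n` (z²/2
pseudo-successes, z² pseudo-trials), rescaled to the RR axis by `n/E`,
with the lower bound clipped at 0; the two-sided p-value is the binomial
score statistic `z = (O − E)/√(E(1 − E/n))`.  The exact variant the
original design used is not recoverable from its description, so the
choice is isolated behind `agresti_rr_ci`/`two_sided_p` where exact
Poisson or mid-P alternatives could be swapped in.  Validation: the
interval matches an independent transcription of the formulas to
1e-12, achieves 93.5–96.5% coverage over 1,000 replicates at n=10,000,
and the score p tracks the exact binomial test within a factor of 1.5
for moderate counts (E ≥ 100, p ≥ 0.01).  In deep tails the normal
approximation deviates multiplicatively from the exact test, as normal
approximations do; reported p-values below ~1e-3 should be read as
orders of magnitude.

Bonferroni correction uses `m` = the number of estimates in the run
(5 comorbidities + eligible cancer sites + the any-cancer union = 21 in
a full run); the any-cancer test counts toward `m`, and `m` is always
recorded in the manifest and reports since the choice is consequential.
Degenerate inputs (empty member set, zero expected count) yield an
explicit undefined estimate (NaN RR, never significant) that is carried
through reports rather than dropped.

The 2×2 sex and BMI contrasts use Pearson's chi-squared with the Yates
continuity correction on by default: on the published counts the
corrected statistic reproduces the printed BMI p-value (2.625 × 10⁻⁸)
where the uncorrected one gives 2.55 × 10⁻⁸; both are exposed via a
flag.

## Reproducibility and problem sizes

All randomness flows from seeded `numpy` generators in a fixed draw
order; identical configs produce byte-identical bundles and reports.
The validation suite uses populations of roughly 45,000–52,000 persons
(2,500–2,800 founders, four generations) for pipeline-level checks —
large enough that 3-standard-error bands on recovered parameters are a
few percent — 1,000 replicates for interval coverage, and 200
small pedigrees for the exhaustive kinship-band cross-check.  The
per-constellation null exceedance check compares the observed count of
RR > 2 constellations against exact binomial tail probabilities at each
constellation's own size and expected count.

## Known limitations

* Ever/never rates ignore diagnosis timing; the design argues this away
  for lifetime risk, but it is an assumption, not a theorem.
* The discrete cap at 3+ affected relatives and the pooling of
  first-degree lineage are one of several defensible signature schemes;
  the scheme is pluggable (`signature_fn`).
* Self-standardization means small populations shrink constellation RRs
  toward 1 (the cases inflate their own cohorts' rates); constellation
  selection needs populations in the tens of thousands to behave as at
  registry scale.
* The score-test p and the adjusted-Wald interval can disagree near
  significance boundaries; the interval is the authoritative uncertainty
  statement.
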