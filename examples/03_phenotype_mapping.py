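"""Map ICD-9/10 codes to comorbid phenotypes and compute BMI categories.

Phenotypes are defined by code-prefix lists on dot-stripped codes, so the
three-character stem 250 captures every 250.xx diabetes code.  BMI uses
the conventional 18.5 / 25 / 30 / 40 cut points with closed lower bounds,
collapsed to the binary under/over-25 split for reporting.
"""

from famrisk import bmi, bmi_category, collapse_bmi, default_phenotype_catalog

catalog = default_phenotype_catalog()

for system, code in [
    ("ICD9", "250.01"), ("ICD10", "I10"), ("ICD9", "427.3"),
    ("ICD10", "I11.0"), ("ICD10", "G43"), ("ICD10", "Z99"),
]:
    labels = catalog.classify(system, code)
    print(f"{system:5s} {code:7s} -> {sorted(labels) or '(no phenotype)'}")

print()
for height, weight in [(170, 53), (170, 65), (170, 73), (170, 90), (170, 120)]:
    value = bmi(height, weight)
    label = bmi_category(value)
    print(f"{height} cm, {weight:3d} kg -> BMI {value:5.1f} -> {label:15s} "
          f"({collapse_bmi(label)})")

# Note I11.0 maps to both hypertension (stem range I10-I13) and heart
# disease (listed as I110): the defining code lists genuinely overlap.
# G43 (migraine) appears under cerebrovascular disease because the
# catalog reproduces the study definition verbatim.
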