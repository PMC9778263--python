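"""Classify a proband's relatives by degree and lineage.

Degree 1-3 classification (parents/siblings/children; grandparents,
half-siblings, aunts/uncles; cousins, great-grandparents, ...) with
maternal/paternal lineage judged by the first parental step, validated
against the recursive kinship coefficient: degree d kin have kinship
exactly 1/2^(d+1) in outbred pedigrees.
"""

from famrisk import SimConfig, build_pedigree, kinship, simulate_pedigree

individuals = simulate_pedigree(SimConfig(n_founders=6, n_generations=4,
                                          rng_seed=11))
graph = build_pedigree(individuals)

# pick a last-generation proband (has ancestors on both sides)
proband = int(individuals.loc[individuals["generation"] == 3, "person_id"].iloc[0])
relset = graph.relatives_by_degree(proband)

print(f"proband {proband}: relatives by degree")
for degree in (1, 2, 3):
    rels = relset.by_degree[degree]
    print(f"  degree {degree}: {len(rels)} relatives")
    for rel, lineage in sorted(rels.items())[:4]:
        phi = kinship(graph, proband, rel)
        print(f"    person {rel:4d}  lineage={lineage:8s}  kinship={phi}")

# Each degree-d relative sits exactly on the 1/2^(d+1) kinship band
# (0.25, 0.125, 0.0625); 'none' lineage marks siblings and descendants,
# reachable through both parents or through neither.
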