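#!/usr/bin/env python
"""Co-segregation validation and expression comparison: Mendelian
goodness-of-fit tests (1:3 in an F2, 1:1 among F6 RILs), bulked-
segregant expectations for the candidate SNP, genotype–phenotype
concordance under the recessive model, and 40−ΔCT relative expression
with ANOVA/Tukey.

Reads results/phenotypes.csv and results/population_truth.json; writes
results/cosegregation.json and results/expression.csv.
"""
import json
from pathlib import Path

import pandas as pd

from eflmap import coseg, io, simpop

SEED = 4
OUT = Path(__file__).resolve().parents[1] / "results"

phenotype = io.read_phenotypes(OUT / "phenotypes.csv")
truth = json.loads((OUT / "population_truth.json").read_text())
means = simpop.phenotype_means(phenotype)
cats = coseg.categorize(means)

counts = cats["category"].value_counts()
ril_test = coseg.gof_test((counts.get("efl_like", 0),
                           counts.get("Efl_like", 0)), (1, 1))
print(f"F6 RILs: {counts.get('efl_like', 0)} early : "
      f"{counts.get('Efl_like', 0)} late; 1:1 χ²[df=1] = "
      f"{ril_test.chi2:.3f}, P = {ril_test.P:.3f}")

f2 = simpop.simulate_population(
    simpop.MapSpec([("LG1", 100.0)], {"SNP": 0.1}),
    simpop.CrossDesign("F2", 200), simpop.LocusSpec("LG1", 40.0), seed=SEED)
f2_means = simpop.phenotype_means(f2.phenotype)
f2_cats = coseg.categorize(f2_means, early_range=(68.0, 81.0),
                           late_range=(81.5, 96.0))
f2_counts = f2_cats["category"].value_counts()
f2_test = coseg.gof_test((f2_counts.get("efl_like", 0),
                          f2_counts.get("Efl_like", 0)), (1, 3))
print(f"F2: {f2_counts.get('efl_like', 0)} early : "
      f"{f2_counts.get('Efl_like', 0)} late; 1:3 χ²[df=1] = "
      f"{f2_test.chi2:.3f}, P = {f2_test.P:.3f}")

# candidate-SNP genotypes from the simulated locus
geno = pd.Series(truth["locus_genotype"]).map(
    {"A": "AA", "H": "AB", "B": "BB"})
cat_map = cats.set_index("individual")["category"]
early_bulk = [geno[i] for i in geno.index if cat_map.get(i) == "efl_like"]
late_bulk = [geno[i] for i in geno.index if cat_map.get(i) == "Efl_like"]
print(f"bulked segregants at the candidate SNP: early bulk → "
      f"{coseg.bulk_expectation(early_bulk)} allele only, late bulk → "
      f"{coseg.bulk_expectation(late_bulk)}")

conc = coseg.concordance(geno, cats)
print(f"recessive-model concordance over {conc['n_informative']} "
      f"informative lines: perfect={conc['perfect']} "
      f"({len(conc['discordant'])} discordant)")

expr = simpop.simulate_expression(target_offsets=(4.0, 3.5), seed=SEED + 1)
rel = coseg.relative_expression(expr)
rel["per_sample"].to_csv(OUT / "expression.csv", index=False)
fold = rel["fold_differences"]["wildtype/mutant"]
print(f"expression (40−ΔCT): genotype means "
      f"{ {k: round(v, 2) for k, v in rel['group_means']['genotype'].items()} }, "
      f"fold difference {fold:.2f}; ANOVA P: "
      f"{ {k: round(v, 4) for k, v in rel['p_values'].items()} }")

io.write_summary({
    "ril_1to1": {"chi2": ril_test.chi2, "P": ril_test.P},
    "f2_1to3": {"chi2": f2_test.chi2, "P": f2_test.P},
    "bulks": {"early": coseg.bulk_expectation(early_bulk),
              "late": coseg.bulk_expectation(late_bulk)},
    "concordance": {"perfect": conc["perfect"],
                    "n_informative": conc["n_informative"],
                    "discordant": conc["discordant"]},
    "expression": {"fold_wildtype_vs_mutant": fold,
                   "p_values": rel["p_values"]},
}, OUT / "cosegregation.json")
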