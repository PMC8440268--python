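#!/usr/bin/env python
"""Marker quality control and phasing: retain markers with > 50% call
rate, homozygous allele frequency 0.2–0.8 (SNPs), distortion P > 1e−5
and ≤ 15% heterozygosity (SNPs); phase against the parents and
mirror-expand phase-ambiguous markers. Appends the qualitative
phenotype-derived locus marker used for mapping.

Reads results/genotypes_raw.csv (+parents, phenotypes); writes
results/genotypes_phased.csv, results/filter_report.tsv.
"""
from pathlib import Path

import pandas as pd

from eflmap import coseg, io, markerqc, simpop
from eflmap.pipeline import append_marker

OUT = Path(__file__).resolve().parents[1] / "results"

matrix = io.read_genotypes(OUT / "genotypes_raw.csv")
parents = pd.read_csv(OUT / "parents.csv", index_col=0, dtype=str)
phenotype = io.read_phenotypes(OUT / "phenotypes.csv")

kept, report = markerqc.filter_markers(matrix)
report.to_csv(OUT / "filter_report.tsv", sep="\t", index=False)
phased = markerqc.phase_and_mirror(kept, parents[kept.marker_ids])

means = simpop.phenotype_means(phenotype)
cats = coseg.categorize(means)
marker = coseg.phenotype_marker(cats)
mapping = append_marker(phased.mapping, "PHEN_efl_locus", marker)
io.write_genotypes(mapping, OUT / "genotypes_phased.csv")
cats.to_csv(OUT / "phenotype_categories.csv", index=False)

n_fail = int((~report["pass"]).sum())
n_ambig = int((phased.mapping.marker_info["phase"] == "ambiguous").sum()) // 2
print(f"{matrix.n_markers} markers in → {kept.n_markers} retained "
      f"({n_fail} failed QC: "
      f"{report.loc[~report['pass'], 'reasons'].value_counts().to_dict()})")
print(f"{n_ambig} phase-ambiguous markers mirror-expanded → "
      f"{phased.mapping.n_markers} columns for mapping")
print("phenotype categories:",
      cats["category"].value_counts().to_dict(),
      "(early 71–78 d, late 84–95 d, gap → missing)")
print(f"wrote {OUT / 'genotypes_phased.csv'}")
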