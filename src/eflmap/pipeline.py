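"""End-to-end orchestration: simulate (or ingest) → marker QC → linkage
map → QTL scan → candidate cascade → co-segregation and expression.

The run is fully reproducible from (config, seed): per-stage random
streams are spawned deterministically from the one seed. The summary is
a machine-readable dict (schema-versioned); when ``out_dir`` is set,
every intermediate artifact is also written in its standard format.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import candidates as cand
from . import coseg, markerqc, qtlscan, refmap, simpop
from .linkmap import build_map
from .matrix import MarkerGenotypeMatrix

SCHEMA_VERSION = 1


def _default_population(cfg: dict) -> tuple:
    groups = cfg.get("linkage_groups") or [("LG1", 100.0), ("LG2", 80.0),
                                           ("LG3", 60.0)]
    map_spec = simpop.MapSpec(
        linkage_groups=[tuple(g) for g in groups],
        marker_densities=cfg.get("marker_densities", {"SNP": 1.0, "PAV": 1.0}),
    )
    design = simpop.CrossDesign(
        generation=cfg.get("generation", "F6_SSD"),
        n_individuals=cfg.get("n_individuals", refmap.N_RILS_PHENOTYPED),
    )
    locus = simpop.LocusSpec(
        linkage_group=cfg.get("locus_group", groups[0][0]),
        position_cM=cfg.get("locus_position_cM", 40.0),
    )
    return map_spec, design, locus


def append_marker(matrix: MarkerGenotypeMatrix, marker_id: str,
                   calls: pd.Series, mtype: str = "PHEN") -> MarkerGenotypeMatrix:
    col = calls.reindex(matrix.individuals).fillna("U").to_numpy(dtype="<U1")
    info = matrix.marker_info.copy()
    info.loc[marker_id] = {"type": mtype, "phase": "maternal",
                           "mirror_partner": None}
    return MarkerGenotypeMatrix(
        list(matrix.individuals), info,
        np.column_stack([matrix.calls, col]),
    )


def run_pipeline(config) -> dict:
    """Execute the full mapping-and-candidate chain on simulated inputs.

    Returns the summary bundle; raises ``ValueError`` from config
    validation before any stage runs. Stage errors propagate annotated
    with the stage name.
    """
    from .io import PipelineConfig, write_fasta, write_genotypes, write_gff3, \
        write_map_csv, write_phenotypes, write_summary, write_vcf

    if not isinstance(config, PipelineConfig):
        config = PipelineConfig(**config)
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(4)]
    summary: dict = {"schema_version": SCHEMA_VERSION, "seed": config.seed}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    stage = "simulate_population"
    try:
        map_spec, design, locus = _default_population(config.population)
        sim = simpop.simulate_population(
            map_spec, design, locus,
            error_rate=config.population.get("error_rate", 0.01),
            missing_rate=config.population.get("missing_rate", 0.05),
            ambiguous_phase_fraction=config.population.get(
                "ambiguous_phase_fraction", 0.15),
            seed=seeds[0],
        )
        summary["population"] = {
            "n_individuals": design.n_individuals,
            "generation": design.generation,
            "n_markers_raw": sim.matrix.n_markers,
            "map_length_cM": map_spec.total_length_cm,
        }

        stage = "marker_qc"
        kept, report = markerqc.filter_markers(sim.matrix, **config.qc)
        phased = markerqc.phase_and_mirror(kept, sim.parents[kept.marker_ids])
        summary["marker_qc"] = {
            "n_input": sim.matrix.n_markers,
            "n_retained": kept.n_markers,
            "n_after_mirroring": phased.mapping.n_markers,
            "fail_reasons": report.loc[~report["pass"], "reasons"]
            .value_counts().to_dict(),
        }

        stage = "phenotype_categories"
        means = simpop.phenotype_means(sim.phenotype)
        cats = coseg.categorize(means, **config.categorize)
        phen_marker = coseg.phenotype_marker(cats)
        mapping = append_marker(phased.mapping, "PHEN_locus", phen_marker)
        summary["phenotype"] = {
            "categories": cats["category"].value_counts().to_dict(),
        }

        stage = "linkage_map"
        gmap, work = build_map(
            mapping,
            p_threshold=config.linkage.get("p_threshold", 1e-18),
            max_cm=config.linkage.get("max_cm", 15.0),
            min_cluster_size=config.linkage.get("min_cluster_size", 5),
            similarity_merge=config.linkage.get("similarity_merge", 0.98),
        )
        summary["linkage_map"] = {
            "n_groups": len(gmap.groups),
            "total_cM": gmap.total_cm,
            "n_markers": gmap.n_markers,
            "n_pruning_actions": len(gmap.provenance),
        }

        stage = "qtl_scan"
        grid = qtlscan.genotype_probabilities(
            gmap, work, step_cm=config.qtl.get("step_cm", 1.0))
        scan = qtlscan.em_scan(grid, means)
        threshold, _ = qtlscan.permutation_threshold(
            grid, means, n_perm=config.qtl.get("n_perm", 200),
            alpha=config.qtl.get("alpha", 0.05), seed=seeds[1])
        qtl_report = qtlscan.summarize_qtl(scan, threshold, gmap,
                                           matrix=work, phenotype=means)
        summary["qtl"] = {
            "lod_max": scan.lod_max,
            "peak": scan.peak,
            "threshold": threshold,
            "n_permutations": config.qtl.get("n_perm", 200),
            "report": qtl_report,
        }

        stage = "candidate_cascade"
        region_spec = simpop.VariantRegionSpec(**config.region)
        region = simpop.simulate_variant_region(region_spec, seed=seeds[2])
        panel = [a for a in region.variants.accessions
                 if a not in ("mutant", "wildtype")]
        cascade = cand.run_cascade(region.variants, "mutant", "wildtype",
                                   panel, region.models, region.reference)
        causal = region.truth["causal"]
        planted_found = any(
            e.pos == causal["pos"] and e.alt == causal["alt"]
            for e in cascade["effects"])
        model = next(m for m in region.models
                     if m.gene_id == causal["orf_id"])
        haps = cand.build_haplotypes(region.variants, model, region.reference)

        protein = model.translate(region.reference)
        msa = simpop.simulate_ortholog_msa(
            protein, n_taxa=20, conserved_residues=[causal["codon_index"]],
            seed=seeds[3])
        profile = cand.conservation_profile(msa)
        planted_effect = next(
            (e for e in cascade["effects"] if e.pos == causal["pos"]), None)
        overlap = None
        if planted_effect is not None:
            overlap = cand.check_motif_domain(
                planted_effect, profile,
                motifs=refmap.MOTIF_X, domains={"SAM_MTase": refmap.DOMAINS["SAM_MTase"]})
        summary["candidates"] = {
            "counts": cascade["counts"],
            "planted_in_candidates": bool(planted_found),
            "planted_effect": None if planted_effect is None else {
                "pos": planted_effect.pos,
                "residue": planted_effect.residue_index,
                "substitution": f"{planted_effect.ref_aa}{planted_effect.residue_index}"
                                f"{planted_effect.alt_aa}",
                "class": planted_effect.effect_class,
            },
            "haplotypes": haps.counts,
            "conserved_site": overlap,
        }

        stage = "co_segregation"
        locus_geno = pd.Series(sim.truth["locus_genotype"])
        diplo = locus_geno.map({"A": "AA", "H": "AB", "B": "BB"})
        cat_map = cats.set_index("individual")["category"]
        early_bulk = [diplo[i] for i in diplo.index if cat_map.get(i) == "efl_like"]
        late_bulk = [diplo[i] for i in diplo.index if cat_map.get(i) == "Efl_like"]
        conc = coseg.concordance(diplo, cats)
        summary["co_segregation"] = {
            "early_bulk": coseg.bulk_expectation(early_bulk) if early_bulk else None,
            "late_bulk": coseg.bulk_expectation(late_bulk) if late_bulk else None,
            "perfect_concordance": conc["perfect"],
            "n_discordant": len(conc["discordant"]),
        }

        stage = "expression"
        expr_cfg = dict(config.expression)
        expr = simpop.simulate_expression(seed=seeds[3] ^ 0x5A5A, **expr_cfg)
        rel = coseg.relative_expression(expr)
        summary["expression"] = {
            "group_means": {f: gm.to_dict() for f, gm in rel["group_means"].items()},
            "fold_differences": rel["fold_differences"],
            "p_values": rel["p_values"],
        }
    except ValueError as exc:
        raise ValueError(f"pipeline stage {stage!r}: {exc}") from exc

    if out_dir:
        write_genotypes(sim.matrix, out_dir / "genotypes_raw.csv")
        write_genotypes(phased.mapping, out_dir / "genotypes_phased.csv")
        write_phenotypes(sim.phenotype, out_dir / "phenotypes.csv")
        write_map_csv(gmap, out_dir / "map.csv")
        scan.frame.to_csv(out_dir / "lod_scan.csv", index=False)
        write_vcf(region.variants, out_dir / "region_variants.vcf")
        write_gff3(region.models, out_dir / "region_orfs.gff3")
        write_fasta([("region", region.reference)], out_dir / "region.fasta")
        write_summary(summary, out_dir / "summary.json")
    return summary
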