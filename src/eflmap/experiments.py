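"""Reusable study-scale experiments: the published-map null permutation
threshold, the closed-form LOD identity check, locus-recovery power and
candidate-cascade recovery. These are the computations the analysis
drivers and the acceptance checks run.
"""
from __future__ import annotations

import numpy as np

from . import markerqc, qtlscan, refmap, simpop
from . import candidates as cand
from .matrix import MarkerGenotypeMatrix
from .qtlscan import GenoProbGrid


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# LOD identity at a fully informative marker
# ---------------------------------------------------------------------------

def exact_r2_dataset(n: int = refmap.N_RILS_MAPPED,
                     r2: float = refmap.PEAK_R2) -> tuple[np.ndarray, np.ndarray]:
    """Two-class genotype/phenotype data with exactly the requested
    proportion of variance explained (MLE R² = SSB/SST).

    Class sizes split n as evenly as possible; within-class residuals
    are a centred integer ramp rescaled so that SSB/(SSB+SSW) = r2.
    """
    n_a = n // 2
    n_b = n - n_a
    geno = np.array(["A"] * n_a + ["B"] * n_b)
    # offsets ±(other class size) keep the overall mean at zero
    mu = np.where(geno == "A", float(n_b), -float(n_a))
    resid = np.concatenate([
        np.arange(1, n_a + 1) - (n_a + 1) / 2.0,
        np.arange(1, n_b + 1) - (n_b + 1) / 2.0,
    ])
    ssb = float((mu ** 2).sum())
    ssw_unit = float((resid ** 2).sum())
    scale = np.sqrt(ssb * (1.0 - r2) / (r2 * ssw_unit))
    return geno, mu + scale * resid


def marker_grid(genotypes: np.ndarray) -> GenoProbGrid:
    """Degenerate one-position grid at a fully typed marker."""
    w = (genotypes == "A").astype(float)
    individuals = [f"ind_{i:03d}" for i in range(len(genotypes))]
    return GenoProbGrid(individuals, {"LG1": np.array([0.0])},
                        {"LG1": w[:, None]})


def lod_identity_check(n: int = refmap.N_RILS_MAPPED,
                       r2: float = refmap.PEAK_R2) -> dict:
    """Peak LOD implied by a printed R² and sample size, three ways:
    the closed form (n/2)·log10(1/(1−R²)), the ANOVA marker oracle on a
    constructed exact-R² data set, and the EM scan on the same data."""
    geno, y = exact_r2_dataset(n, r2)
    scan = qtlscan.em_scan(marker_grid(geno), y)
    return {
        "closed_form": float(qtlscan.lod_from_r2(n, r2)),
        "marker_oracle": float(qtlscan.marker_lod_oracle(geno, y)),
        "em_scan": float(scan.lod_max),
        "em_r2": float(scan.peak["r2"]),
        "n": n,
    }


# ---------------------------------------------------------------------------
# published-dimension null threshold
# ---------------------------------------------------------------------------

def published_scale_population(seed: int, n_individuals: int = refmap.N_RILS_MAPPED,
                               locus: simpop.LocusSpec | None = None,
                               error_rate: float = 0.01,
                               missing_rate: float = 0.05):
    """Simulated F6 RIL genotypes on the 23 published linkage-group
    lengths with ~2314 markers, phased against the parents."""
    map_spec = simpop.MapSpec(
        linkage_groups=refmap.group_lengths(),
        marker_counts=refmap.marker_counts(),
    )
    if locus is None:
        locus = simpop.LocusSpec(linkage_group="CxG_LG14", position_cM=60.0)
    sim = simpop.simulate_population(
        map_spec, simpop.CrossDesign("F6_SSD", n_individuals), locus,
        error_rate=error_rate, missing_rate=missing_rate,
        ambiguous_phase_fraction=0.0, seed=seed)
    phased = markerqc.phase_and_mirror(sim.matrix, sim.parents)
    return sim, phased.mapping


def null_permutation_threshold(seed: int, n_perm: int = 200,
                               alpha: float = 0.05,
                               step_cm: float = 1.0) -> dict:
    """Genome-wide 95% permutation LOD threshold on a simulated null
    data set with the published map dimensions (23 groups, ~2314
    markers, 181 RILs) and a bimodal phenotype unlinked to genotype."""
    s_pop, s_phen, s_perm = _spawn_seeds(seed, 3)
    sim, mapping = published_scale_population(s_pop)
    gmap = simpop.truth_map(sim)
    grid = qtlscan.genotype_probabilities(gmap, mapping, step_cm=step_cm)
    y = simpop.simulate_null_phenotype(mapping.n_individuals,
                                       sim.truth["locus"], seed=s_phen)
    threshold, maxlod = qtlscan.permutation_threshold(
        grid, y, n_perm=n_perm, alpha=alpha, seed=s_perm)
    return {"threshold": float(threshold), "n": mapping.n_individuals,
            "n_perm": n_perm, "n_markers": mapping.n_markers,
            "map_cM": gmap.total_cm, "max_lods": maxlod}


# ---------------------------------------------------------------------------
# locus recovery power
# ---------------------------------------------------------------------------

def locus_recovery(n_seeds: int = 100, seed: int = 0,
                   n_individuals: int = refmap.N_RILS_PHENOTYPED,
                   n_perm: int = 100, step_cm: float = 1.0) -> dict:
    """Repeated-simulation power study at the study design scale: one
    recessive locus (R² ≈ 0.85 at the default phenotype model), n=185
    F6 RILs, three ~0.8-marker/cM chromosomes. For each replicate the
    scan runs on the true map and the peak is compared with the
    simulated locus position and the per-replicate permutation
    threshold."""
    map_spec = simpop.MapSpec(
        linkage_groups=[("LG1", 100.0), ("LG2", 80.0), ("LG3", 60.0)],
        marker_densities={"SNP": 0.4, "PAV": 0.4})
    locus = simpop.LocusSpec(linkage_group="LG1", position_cM=40.0)
    seeds = _spawn_seeds(seed, 3 * n_seeds)
    results = []
    for k in range(n_seeds):
        s_pop, s_perm = seeds[3 * k], seeds[3 * k + 1]
        sim = simpop.simulate_population(
            map_spec, simpop.CrossDesign("F6_SSD", n_individuals), locus,
            error_rate=0.01, missing_rate=0.05,
            ambiguous_phase_fraction=0.0, seed=s_pop)
        mapping = markerqc.phase_and_mirror(sim.matrix, sim.parents).mapping
        gmap = simpop.truth_map(sim)
        grid = qtlscan.genotype_probabilities(gmap, mapping, step_cm=step_cm)
        y = simpop.phenotype_means(sim.phenotype)
        scan = qtlscan.em_scan(grid, y)
        threshold, _ = qtlscan.permutation_threshold(grid, y, n_perm=n_perm,
                                                     seed=s_perm)
        peak = scan.peak
        results.append({
            "on_group": peak["group_id"] == locus.linkage_group,
            "distance_cM": abs(peak["position_cM"] - locus.position_cM),
            "lod": peak["lod"], "threshold": threshold, "r2": peak["r2"],
        })
    hits = sum(r["on_group"] and r["distance_cM"] <= 2.0
               and r["lod"] >= r["threshold"] for r in results)
    return {
        "n_seeds": n_seeds,
        "n_recovered": int(hits),
        "recovery_rate": hits / n_seeds,
        "mean_r2": float(np.mean([r["r2"] for r in results])),
        "mean_lod": float(np.mean([r["lod"] for r in results])),
        "results": results,
    }


# ---------------------------------------------------------------------------
# cascade recovery
# ---------------------------------------------------------------------------

def cascade_recovery(n_seeds: int = 100, seed: int = 0,
                     spec: simpop.VariantRegionSpec | None = None) -> dict:
    """Repeated variant-region simulations: in each replicate the
    planted causal transition must survive the full screen and be
    flagged non-synonymous at a conserved site inside the configured
    domain/motif intervals."""
    if spec is None:
        spec = simpop.VariantRegionSpec()
    seeds = _spawn_seeds(seed, 2 * n_seeds)
    n_survived = n_flagged = 0
    co_survivors = []
    for k in range(n_seeds):
        region = simpop.simulate_variant_region(spec, seed=seeds[2 * k])
        panel = [a for a in region.variants.accessions
                 if a not in ("mutant", "wildtype")]
        res = cand.run_cascade(region.variants, "mutant", "wildtype", panel,
                               region.models, region.reference)
        causal = region.truth["causal"]
        hit = next((e for e in res["effects"] if e.pos == causal["pos"]
                    and e.alt == causal["alt"]), None)
        if hit is not None:
            n_survived += 1
            if hit.effect_class == causal["class"]:
                protein = next(m for m in region.models
                               if m.gene_id == causal["orf_id"]
                               ).translate(region.reference)
                msa = simpop.simulate_ortholog_msa(
                    protein, n_taxa=20,
                    conserved_residues=[causal["codon_index"]],
                    seed=seeds[2 * k + 1])
                profile = cand.conservation_profile(msa)
                chk = cand.check_motif_domain(
                    hit, profile, motifs=refmap.MOTIF_X,
                    domains={"SAM_MTase": refmap.DOMAINS["SAM_MTase"]})
                if chk["conserved_site_hit"]:
                    n_flagged += 1
        co_survivors.append(res["counts"]["unique_vs_panel"] - 1)
    return {
        "n_seeds": n_seeds,
        "n_survived": n_survived,
        "n_flagged_conserved_nonsyn": n_flagged,
        "mean_false_co_survivors": float(np.mean(co_survivors)),
    }
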