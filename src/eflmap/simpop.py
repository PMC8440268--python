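"""Simulators for every input the mapping pipeline consumes.

A bi-parental cross between a recessive early-flowering mutant (maternal
parent) and a late-flowering wild type is advanced either to F2 or, by
single seed descent, to F6 (five selfing meioses from the F1). Meioses
follow a no-interference model: crossover counts are Poisson in the map
length in Morgans with uniform positions. Marker panels mix codominant
SNPs with dominant presence/absence (PAV) markers, with configurable
genotyping error, missingness and phase ambiguity. The days-to-flowering
phenotype is bimodal and controlled by the single simulated locus:
homozygous-mutant lines draw from the early distribution, all others
(including heterozygotes) from the late one.

A separate generator emulates a resequencing-style variant table over a
~267-kb candidate region: shared background substitutions across a
diversity panel plus exactly one planted causal transition private to
the mutant lineage, inside an annotated ORF, producing a non-synonymous
change. Small generators for qPCR CT tables and ortholog protein
alignments complete the input set.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkmap import GeneticMap, LinkageGroup
from .matrix import MarkerGenotypeMatrix
from .candidates import GeneModel, VariantTable

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = np.array(list("ACGT"))
_AA = list("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class MapSpec:
    """Genome dimensions for the simulated cross.

    ``linkage_groups`` is a list of (id, length in cM); ``marker_densities``
    gives markers per cM per marker type; ``marker_counts`` optionally
    overrides the per-group, per-type counts exactly.
    """
    linkage_groups: list[tuple[str, float]]
    marker_densities: dict[str, float] = field(
        default_factory=lambda: {"SNP": 1.5, "PAV": 1.5})
    map_function_name: str = "kosambi"
    marker_counts: dict[str, dict[str, int]] | None = None

    def __post_init__(self):
        if not self.linkage_groups:
            raise ValueError("zero-length genome: no linkage groups")
        for gid, length in self.linkage_groups:
            if length <= 0:
                raise ValueError(f"linkage group {gid!r} has non-positive length")

    @property
    def total_length_cm(self) -> float:
        return float(sum(length for _, length in self.linkage_groups))


_GENERATION_MEIOSES = {"F1": 0, "F2": 1, "F6_SSD": 5}


@dataclass
class CrossDesign:
    generation: str = "F6_SSD"
    n_individuals: int = 185

    def __post_init__(self):
        if self.generation not in _GENERATION_MEIOSES:
            raise ValueError(f"unknown generation {self.generation!r}")
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")

    @property
    def n_meioses(self) -> int:
        """Selfing meioses from the F1 (F2 = 1, F6 by SSD = 5)."""
        return _GENERATION_MEIOSES[self.generation]


@dataclass
class LocusSpec:
    """The single recessive flowering-time locus.

    Means/SDs are in days; defaults reproduce early/late categories of
    roughly 71–81 and 82–93 mean days to flowering. ``sd_early``/``sd_late``
    describe between-line variation of the latent line mean;
    ``sd_replicate`` the within-line replicate scatter.
    """
    linkage_group: str = "LG1"
    position_cM: float = 40.0
    inheritance: str = "recessive_early"
    mean_early_days: float = 75.0
    mean_late_days: float = 87.0
    sd_early_days: float = 2.0
    sd_late_days: float = 2.5
    n_replicates: int = 3
    sd_replicate: float = 1.0

    def __post_init__(self):
        if self.mean_early_days >= self.mean_late_days:
            raise ValueError("early mean must be below late mean")
        if min(self.sd_early_days, self.sd_late_days) <= 0:
            raise ValueError("phenotype SDs must be positive")


# ---------------------------------------------------------------------------
# meiosis machinery
# ---------------------------------------------------------------------------
# a haplotype is (breakpoints ascending within (0, L), origins of the
# len(breakpoints)+1 segments; origin 0 = maternal founder, 1 = paternal)

def _founder(origin: int):
    return (np.empty(0), np.array([origin], dtype=np.int8))


def _meiosis(h1, h2, length_cm: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a pair of homologs: Poisson(L/100) crossovers at
    uniform positions, no interference, random start strand."""
    n_x = rng.poisson(length_cm / 100.0)
    xpos = np.sort(rng.uniform(0.0, length_cm, n_x))
    cur = int(rng.integers(2))
    haps = (h1, h2)
    bounds = np.concatenate(([0.0], xpos, [length_cm]))
    ends: list[float] = []
    origins: list[int] = []
    for s in range(bounds.size - 1):
        a, b = bounds[s], bounds[s + 1]
        hb, ho = haps[(cur + s) % 2]
        i0 = np.searchsorted(hb, a, side="right")
        i1 = np.searchsorted(hb, b, side="left")
        seg_ends = list(hb[i0:i1]) + [b]
        for o, e in zip(ho[i0:i1 + 1], seg_ends):
            if origins and origins[-1] == o:
                ends[-1] = e
            else:
                origins.append(int(o))
                ends.append(float(e))
    return np.array(ends[:-1]), np.array(origins, dtype=np.int8)


def _origin_at(hap, positions: np.ndarray) -> np.ndarray:
    bp, orig = hap
    return orig[np.searchsorted(bp, positions, side="right")]


def _simulate_lineage(lengths: list[float], n_meioses: int, rng):
    """Advance one selfing lineage; returns the final individual's
    homolog pair per chromosome and the crossover-point record."""
    pair = [(_founder(0), _founder(1)) for _ in lengths]
    for _ in range(n_meioses):
        pair = [
            (_meiosis(h1, h2, L, rng), _meiosis(h1, h2, L, rng))
            for (h1, h2), L in zip(pair, lengths)
        ]
    return pair


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

@dataclass
class PopulationSim:
    matrix: MarkerGenotypeMatrix      # offspring calls, column phase as observed
    parents: pd.DataFrame             # 2 × markers parental calls (U = unscored)
    phenotype: pd.DataFrame           # individual, replicate, days_to_flowering
    truth: dict


def simulate_population(map_spec: MapSpec, design: CrossDesign,
                        locus: LocusSpec, error_rate: float = 0.01,
                        missing_rate: float = 0.05,
                        ambiguous_phase_fraction: float = 0.15,
                        seed: int | None = None) -> PopulationSim:
    """Simulate a bi-parental mapping population with its marker panel
    and phenotype, returning observed data plus a truth record.

    Genotyping error flips homozygous calls symmetrically; missingness
    is independent per cell. A fraction of markers lose their
    parental-origin label (parents unscored) and are emitted in a random
    column orientation; half of the remaining phased markers are emitted
    in the swapped orientation together with swapped parental calls, so
    phasing against the parents restores a common coding.
    """
    for name, p in (("error_rate", error_rate), ("missing_rate", missing_rate),
                    ("ambiguous_phase_fraction", ambiguous_phase_fraction)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be a probability")
    gids = [gid for gid, _ in map_spec.linkage_groups]
    if locus.linkage_group not in gids:
        raise ValueError(f"locus linkage group {locus.linkage_group!r} "
                         "not in the map")
    rng = np.random.default_rng(seed)
    lengths = [length for _, length in map_spec.linkage_groups]

    # --- marker panel
    rows = []
    for gid, length in map_spec.linkage_groups:
        for mtype in sorted(map_spec.marker_densities):
            if map_spec.marker_counts is not None:
                count = map_spec.marker_counts.get(gid, {}).get(mtype, 0)
            else:
                count = max(2, int(round(map_spec.marker_densities[mtype] * length)))
            pos = np.sort(rng.uniform(0.0, length, count))
            for p in pos:
                rows.append({"group": gid, "position_cM": float(p), "type": mtype})
    mk = pd.DataFrame(rows).sort_values(["group", "position_cM"],
                                        kind="stable").reset_index(drop=True)
    mk["marker_id"] = [
        f"{g}_{t}{i:05d}" for i, (g, t) in enumerate(zip(mk["group"], mk["type"]))
    ]
    n_mark = len(mk)
    mk["pav_present_parent"] = rng.integers(0, 2, n_mark)  # 0 = maternal allele scored
    mk["phase_known"] = rng.random(n_mark) >= ambiguous_phase_fraction
    mk["flipped"] = rng.random(n_mark) < 0.5  # emitted column orientation

    # --- genotypes from per-lineage meioses
    n = design.n_individuals
    individuals = [f"RIL_{i + 1:03d}" if design.generation == "F6_SSD"
                   else f"{design.generation}_{i + 1:03d}" for i in range(n)]
    calls = np.full((n, n_mark), "U", dtype="<U1")
    locus_geno = []
    crossover_points: dict[str, dict[str, list[float]]] = {}
    group_index = {gid: k for k, gid in enumerate(gids)}
    mk_by_group = {gid: mk.index[mk["group"] == gid].to_numpy() for gid in gids}
    locus_gi = group_index[locus.linkage_group]

    for i, ind in enumerate(individuals):
        pair = _simulate_lineage(lengths, design.n_meioses, rng)
        crossover_points[ind] = {
            gid: sorted(set(pair[k][0][0]).union(pair[k][1][0]))
            for gid, k in group_index.items()
        }
        for gid, k in group_index.items():
            idx = mk_by_group[gid]
            if idx.size == 0:
                continue
            pos = mk.loc[idx, "position_cM"].to_numpy()
            o1 = _origin_at(pair[k][0], pos)
            o2 = _origin_at(pair[k][1], pos)
            dose = o1 + o2  # paternal allele count
            snp = np.where(dose == 0, "A", np.where(dose == 2, "B", "H"))
            present = mk.loc[idx, "pav_present_parent"].to_numpy()
            carries = np.where(present == 0, dose < 2, dose > 0)  # ≥1 scored allele
            pav = np.where(carries, np.where(present == 0, "A", "B"),
                           np.where(present == 0, "B", "A"))
            is_snp = (mk.loc[idx, "type"] == "SNP").to_numpy()
            calls[i, idx] = np.where(is_snp, snp, pav)
        lp = np.array([locus.position_cM])
        g1 = _origin_at(pair[locus_gi][0], lp)[0]
        g2 = _origin_at(pair[locus_gi][1], lp)[0]
        locus_geno.append("A" if g1 + g2 == 0 else ("B" if g1 + g2 == 2 else "H"))

    # --- error, missingness, phase scrambling
    hom = np.isin(calls, ("A", "B"))
    flip = hom & (rng.random(calls.shape) < error_rate)
    flipped_vals = np.where(calls == "A", "B", "A")
    calls[flip] = flipped_vals[flip]
    calls[rng.random(calls.shape) < missing_rate] = "U"

    flip_col = mk["flipped"].to_numpy()
    swap = np.where(calls == "A", "B", np.where(calls == "B", "A", calls))
    calls[:, flip_col] = swap[:, flip_col]

    parents = pd.DataFrame(
        np.array([np.where(flip_col, "B", "A"), np.where(flip_col, "A", "B")]),
        index=["parent1", "parent2"], columns=mk["marker_id"],
    )
    unknown = ~mk["phase_known"].to_numpy()
    parents.loc[:, unknown] = "U"

    info = pd.DataFrame({
        "type": mk["type"].to_numpy(),
        "phase": np.where(mk["phase_known"], "maternal", "ambiguous"),
        "mirror_partner": None,
    }, index=pd.Index(mk["marker_id"], name="marker"))
    matrix = MarkerGenotypeMatrix(individuals, info, calls)

    # --- phenotype
    geno = np.array(locus_geno)
    early = geno == "A"  # homozygous mutant
    latent = np.where(
        early,
        rng.normal(locus.mean_early_days, locus.sd_early_days, n),
        rng.normal(locus.mean_late_days, locus.sd_late_days, n),
    )
    phen_rows = []
    for i, ind in enumerate(individuals):
        for rep in range(1, locus.n_replicates + 1):
            phen_rows.append({
                "individual": ind, "replicate": rep,
                "days_to_flowering": latent[i] + rng.normal(0, locus.sd_replicate),
            })
    phenotype = pd.DataFrame(phen_rows)

    truth = {
        "markers": mk,
        "locus_genotype": dict(zip(individuals, locus_geno)),
        "locus": locus,
        "map_spec": map_spec,
        "design": design,
        "crossover_points": crossover_points,
        "latent_mean": dict(zip(individuals, latent)),
    }
    return PopulationSim(matrix=matrix, parents=parents, phenotype=phenotype,
                         truth=truth)


def truth_map(sim: PopulationSim) -> GeneticMap:
    """The simulated (true) genetic map, for oracle comparisons and for
    scans that bypass map construction."""
    mk = sim.truth["markers"]
    groups = []
    for gid, length in sim.truth["map_spec"].linkage_groups:
        sub = mk[mk["group"] == gid].sort_values("position_cM")
        if len(sub) == 0:
            continue
        groups.append(LinkageGroup(
            group_id=gid, markers=list(sub["marker_id"]),
            positions_cm=sub["position_cM"].to_numpy(dtype=float),
        ))
    return GeneticMap(groups=groups)


def phenotype_means(phenotype: pd.DataFrame) -> pd.Series:
    """Per-individual mean days to flowering over replicates."""
    return phenotype.groupby("individual")["days_to_flowering"].mean()


def simulate_null_phenotype(n: int, locus: LocusSpec,
                            seed: int | None = None) -> np.ndarray:
    """Bimodal phenotype means unlinked to any genotype (for null
    permutation studies): class tossed fairly, latent line mean normal
    within class, averaged over the locus's replicate number."""
    rng = np.random.default_rng(seed)
    early = rng.random(n) < 0.5
    latent = np.where(
        early,
        rng.normal(locus.mean_early_days, locus.sd_early_days, n),
        rng.normal(locus.mean_late_days, locus.sd_late_days, n),
    )
    return latent + rng.normal(0, locus.sd_replicate / np.sqrt(locus.n_replicates), n)


# ---------------------------------------------------------------------------
# variant-region simulation
# ---------------------------------------------------------------------------

@dataclass
class CausalSpec:
    """The planted causal change: a single-base transition inside the
    designated ORF, as a ref→alt codon replacement."""
    orf_index: int = 19
    codon_index: int = 534            # 1-based residue in the ORF's protein
    ref_codon: str = "GCA"            # alanine
    alt_codon: str = "ACA"            # threonine

    def __post_init__(self):
        diffs = [i for i in range(3) if self.ref_codon[i] != self.alt_codon[i]]
        if len(diffs) != 1:
            raise ValueError("causal codons must differ at exactly one base")
        i = diffs[0]
        if _TRANSITION[self.ref_codon[i]] != self.alt_codon[i]:
            raise ValueError("causal change must be a transition")
        self.codon_pos = i + 1  # 1-based within codon
        self.ref_base = self.ref_codon[i]
        self.alt_base = self.alt_codon[i]


@dataclass
class VariantRegionSpec:
    region_length_bp: int = 267_160
    n_orfs: int = 40
    n_panel_accessions: int = 43
    background_transition_rate: float = 0.05    # variant sites per bp
    background_transversion_rate: float = 0.025
    causal: CausalSpec = field(default_factory=CausalSpec)
    causal_cds_length: int = 1815
    causal_n_exons: int = 9
    coding_retention: float = 0.1   # purifying selection thins exonic variants
    chrom: str = "region"

    def __post_init__(self):
        if self.region_length_bp <= 0:
            raise ValueError("region length must be positive")
        if not 0 <= self.causal.orf_index < self.n_orfs:
            raise ValueError("causal ORF index outside the ORF count")
        if self.causal_cds_length % 3:
            raise ValueError("causal CDS length must be a codon multiple")
        if self.causal.codon_index > self.causal_cds_length // 3:
            raise ValueError("causal codon outside the causal CDS")


@dataclass
class RegionSim:
    variants: VariantTable
    models: list[GeneModel]
    reference: str
    truth: dict


def _split_exons(total: int, n_exons: int, start: int, intron: int,
                 ) -> list[tuple[int, int]]:
    base, extra = divmod(total, n_exons)
    sizes = [base + (1 if i < extra else 0) for i in range(n_exons)]
    exons = []
    s = start
    for size in sizes:
        exons.append((s, s + size - 1))
        s += size + intron
    return exons


def simulate_variant_region(spec: VariantRegionSpec,
                            seed: int | None = None) -> RegionSim:
    """Simulate the resequencing inputs of the candidate-region screen.

    Background substitutions are shared among random subsets of the
    accessions (mutant parent, wild-type parent, diversity panel) with
    Beta(1,3) carrier frequencies; exactly one causal transition is
    planted, carried by the mutant parent alone, inside an exon of the
    designated ORF, replacing its reference codon so the substitution is
    non-synonymous by construction. Same seed → identical output.
    """
    rng = np.random.default_rng(seed)
    L = spec.region_length_bp
    seq = _BASES[rng.integers(0, 4, L)]

    # --- gene layout: one ORF per equal slot, centred
    slot = L // spec.n_orfs
    intron = 150
    models: list[GeneModel] = []
    for k in range(spec.n_orfs):
        slot_start = k * slot + 1
        if k == spec.causal.orf_index:
            n_ex, cds_len = spec.causal_n_exons, spec.causal_cds_length
            strand = "+"
        else:
            n_ex = int(rng.integers(1, 5))
            cds_len = 3 * int(rng.integers(60, 220))
            strand = "+" if rng.random() < 0.5 else "-"
        span = cds_len + (n_ex - 1) * intron
        margin = max(1, (slot - span) // 2)
        gstart = slot_start + min(margin, slot - span - 1 if slot > span else 0)
        exons = _split_exons(cds_len, n_ex, gstart, intron)
        if exons[-1][1] > L:
            raise ValueError("ORF layout exceeds region bounds; "
                             "region too short for the ORF count")
        models.append(GeneModel(gene_id=f"ORF{k + 1:02d}", strand=strand,
                                exons=exons, chrom=spec.chrom))

    causal_model = models[spec.causal.orf_index]
    cau = spec.causal
    # genomic coordinates of the causal codon (plus strand by construction)
    cds_off0 = (cau.codon_index - 1) * 3  # 0-based CDS offset of codon start
    cds_positions = causal_model.cds_genomic_positions()
    codon_genomic = cds_positions[cds_off0:cds_off0 + 3]
    seq[[p - 1 for p in codon_genomic]] = list(cau.ref_codon)
    causal_pos = int(codon_genomic[cau.codon_pos - 1])

    accessions = ["mutant", "wildtype"] + [
        f"panel_{i + 1:02d}" for i in range(spec.n_panel_accessions)
    ]
    n_acc = len(accessions)

    # --- background variant sites
    n_ts = rng.binomial(L, spec.background_transition_rate)
    n_tv = rng.binomial(L, spec.background_transversion_rate)
    pool = rng.choice(L, size=min(L - 1, n_ts + n_tv), replace=False) + 1
    pool = pool[pool != causal_pos]
    # purifying selection: exonic background variants are rarer
    exonic_mask = np.zeros(L + 1, dtype=bool)
    for m in models:
        for s, e in m.exons:
            exonic_mask[s:e + 1] = True
    drop = exonic_mask[pool] & (rng.random(pool.size) >= spec.coding_retention)
    n_ts = int(n_ts - drop[:n_ts].sum())
    pool = pool[~drop]
    ts_pos, tv_pos = pool[:n_ts], pool[n_ts:]

    refs = seq[pool - 1]
    alts = np.empty(pool.size, dtype="<U1")
    alts[:ts_pos.size] = [_TRANSITION[b] for b in refs[:ts_pos.size]]
    for j in range(ts_pos.size, pool.size):
        choices = [b for b in "ACGT" if b != refs[j] and _TRANSITION[refs[j]] != b]
        alts[j] = choices[int(rng.integers(2))]

    freq = rng.beta(1.0, 3.0, pool.size)
    carriers = rng.random((pool.size, n_acc)) < freq[:, None]
    empty = ~carriers.any(axis=1)
    carriers[empty, rng.integers(0, n_acc, int(empty.sum()))] = True

    pos_all = np.concatenate((pool, [causal_pos]))
    ref_all = np.concatenate((refs, [cau.ref_base]))
    alt_all = np.concatenate((alts, [cau.alt_base]))
    carr_all = np.vstack((carriers, np.zeros((1, n_acc), dtype=bool)))
    carr_all[-1, 0] = True  # mutant parent only
    order = np.argsort(pos_all, kind="stable")

    vt = VariantTable(
        chrom=spec.chrom,
        region=(1, L),
        df=pd.DataFrame({"pos": pos_all[order].astype(int),
                         "ref": ref_all[order], "alt": alt_all[order]}),
        carriers=carr_all[order],
        accessions=accessions,
    )
    reference = "".join(seq)
    ref_aa = GeneModel.translate_codon(cau.ref_codon)
    alt_aa = GeneModel.translate_codon(cau.alt_codon)
    truth = {
        "causal": {
            "pos": causal_pos, "ref": cau.ref_base, "alt": cau.alt_base,
            "orf_id": causal_model.gene_id, "codon_index": cau.codon_index,
            "codon_pos": cau.codon_pos, "ref_aa": ref_aa, "alt_aa": alt_aa,
            "class": "synonymous" if ref_aa == alt_aa else
                     ("nonsense" if alt_aa == "*" else "nonsynonymous"),
        },
        "n_background": int(pool.size),
        "n_background_transitions": int(ts_pos.size),
    }
    return RegionSim(variants=vt, models=models, reference=reference, truth=truth)


# ---------------------------------------------------------------------------
# expression and alignment generators
# ---------------------------------------------------------------------------

def simulate_expression(n_genotypes: int = 2, n_stages: int = 5,
                        n_reps: int = 3,
                        target_offsets=(4.0, 3.5),
                        reference_ct: float = 24.0, noise_sd: float = 0.2,
                        seed: int | None = None, n_treatments: int = 2,
                        primer_pairs=("pp1", "pp2")) -> pd.DataFrame:
    """Long-format qPCR CT table: target gene (two primer pairs) and
    reference gene per sample, over genotype × treatment × stage ×
    replicate. ``target_offsets`` is the true ΔCT (target − reference)
    per genotype."""
    if n_reps < 2:
        raise ValueError("need at least two biological replicates")
    if len(target_offsets) != n_genotypes:
        raise ValueError("one target offset per genotype required")
    if reference_ct <= 0 or any(reference_ct + o <= 0 for o in target_offsets):
        raise ValueError("requested CT values must be positive")
    rng = np.random.default_rng(seed)
    genotypes = ["mutant", "wildtype"][:n_genotypes] + [
        f"geno_{k}" for k in range(3, n_genotypes + 1)
    ]
    treatments = ["vernalised", "control"][:max(1, n_treatments)]
    rows = []
    for gi, g in enumerate(genotypes):
        for trt in treatments:
            for stage in range(1, n_stages + 1):
                for rep in range(1, n_reps + 1):
                    ct_ref = reference_ct + rng.normal(0, noise_sd)
                    for pp in primer_pairs:
                        rows.append({
                            "genotype": g, "treatment": trt,
                            "stage": f"S{stage}", "replicate": rep,
                            "primer_pair": pp,
                            "ct_target": reference_ct + target_offsets[gi]
                            + rng.normal(0, noise_sd),
                            "ct_reference": ct_ref,
                        })
    return pd.DataFrame(rows)


def simulate_ortholog_msa(protein: str, n_taxa: int = 20,
                          conserved_residues=(), sub_rate: float = 0.08,
                          seed: int | None = None,
                          reference_id: str = "reference") -> list[tuple[str, str]]:
    """Gap-free ortholog alignment around a reference protein: each
    taxon substitutes non-conserved residues independently at
    ``sub_rate``; listed 1-based residues stay invariant."""
    rng = np.random.default_rng(seed)
    conserved = set(conserved_residues)
    out = [(reference_id, protein)]
    for t in range(n_taxa - 1):
        chars = list(protein)
        for i in range(len(chars)):
            if (i + 1) in conserved or chars[i] == "*":
                continue
            if rng.random() < sub_rate:
                chars[i] = _AA[int(rng.integers(len(_AA)))]
        out.append((f"taxon_{t + 1:02d}", "".join(chars)))
    return out
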