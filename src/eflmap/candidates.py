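"""Mutagenesis-aware candidate-variant cascade.

Alkylating mutagens (such as ethylene imine) predominantly induce
transition SNPs (G/A and C/T), so the screen over the mapped candidate
region keeps transitions that are carried by the mutagenised parent,
absent from the wild-type parent and absent from every accession of a
diversity panel, then intersects survivors with annotated ORFs and
classifies their coding effect. Supporting operations build CDS
haplotypes across accessions, profile column conservation in an
ortholog protein alignment, test overlap with configured motif/domain
intervals, construct a neighbour-joining tree on uncorrected identity
distances, and type known promoter-deletion alleles.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# basic classification
# ---------------------------------------------------------------------------

def classify_substitution(ref: str, alt: str) -> str:
    """``transition`` for purine↔purine or pyrimidine↔pyrimidine
    substitutions ({A,G}, {C,T} as unordered pairs), else
    ``transversion``."""
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"bases must be A/C/G/T, got {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt bases are identical")
    pair = {ref, alt}
    return "transition" if pair in (_PURINES, _PYRIMIDINES) else "transversion"


# ---------------------------------------------------------------------------
# variant table
# ---------------------------------------------------------------------------

@dataclass
class VariantTable:
    """Single-nucleotide substitutions over a region, with the accession
    set carrying each alt allele held as a boolean matrix
    (variants × accessions). Coordinates are 1-based."""
    chrom: str
    region: tuple[int, int]
    df: pd.DataFrame                     # pos, ref, alt
    carriers: np.ndarray = field(repr=False)
    accessions: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.carriers = np.asarray(self.carriers, dtype=bool)
        if self.carriers.shape != (len(self.df), len(self.accessions)):
            raise ValueError("carriers shape must be (n_variants, n_accessions)")
        if (self.df["ref"] == self.df["alt"]).any():
            raise ValueError("ref and alt must differ")
        lo, hi = self.region
        if ((self.df["pos"] < lo) | (self.df["pos"] > hi)).any():
            raise ValueError("variant position outside region bounds")
        self.df = self.df.reset_index(drop=True)

    def __len__(self):
        return len(self.df)

    def acc_index(self, accession: str) -> int:
        try:
            return self.accessions.index(accession)
        except ValueError:
            raise KeyError(f"accession {accession!r} not in the table")

    def carried_by(self, accession: str) -> np.ndarray:
        return self.carriers[:, self.acc_index(accession)]

    def subset(self, mask) -> "VariantTable":
        mask = np.asarray(mask)
        return VariantTable(self.chrom, self.region,
                           self.df.loc[mask].reset_index(drop=True),
                           self.carriers[mask], list(self.accessions))

    def substitution_classes(self) -> np.ndarray:
        return np.array([classify_substitution(r, a)
                         for r, a in zip(self.df["ref"], self.df["alt"])])


def unique_mutant_transitions(vt: VariantTable, mutant: str, wildtype: str,
                              panel: list[str]) -> tuple[VariantTable, dict]:
    """Cascade filter: transitions carried by the mutant, absent from
    the wild type and from every panel accession.

    Uncalled genotypes count as reference (alt absent). Returns the
    surviving table plus stage-wise counts
    (total → transitions → unique vs wild type → unique vs panel).
    """
    if mutant in panel:
        raise ValueError("mutant accession must not be in the panel")
    vt.acc_index(mutant)  # raises if absent
    counts = {"total": len(vt)}
    is_ts = vt.substitution_classes() == "transition"
    step = vt.subset(is_ts)
    counts["transitions"] = len(step)
    keep = step.carried_by(mutant) & ~step.carried_by(wildtype)
    step = step.subset(keep)
    counts["unique_vs_wildtype"] = len(step)
    panel_any = np.zeros(len(step), dtype=bool)
    for acc in panel:
        panel_any |= step.carried_by(acc)
    step = step.subset(~panel_any)
    counts["unique_vs_panel"] = len(step)
    return step, counts


# ---------------------------------------------------------------------------
# gene models and coding effects
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A protein-coding ORF: non-overlapping exons in ascending genomic
    order, 1-based inclusive; spliced CDS length must be a codon
    multiple."""
    gene_id: str
    strand: str
    exons: list[tuple[int, int]]
    chrom: str = "region"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        for s, e in ex:
            if s > e or s < 1:
                raise ValueError(f"bad exon ({s}, {e}) in {self.gene_id}")
        self.exons = ex
        if self.cds_length % 3:
            raise ValueError(f"CDS length of {self.gene_id} not a codon multiple")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def cds_genomic_positions(self) -> list[int]:
        """Genomic positions in CDS (5'→3') order; descending for the
        minus strand."""
        pos = [p for s, e in self.exons for p in range(s, e + 1)]
        return pos if self.strand == "+" else pos[::-1]

    def cds_offset_of(self, pos: int) -> int | None:
        """1-based CDS offset of a genomic position, or None if the
        position is not exonic. Strand-aware."""
        off = 0
        for s, e in self.exons:
            if s <= pos <= e:
                plus_off = off + (pos - s) + 1
                if self.strand == "+":
                    return plus_off
                return self.cds_length - plus_off + 1
            off += e - s + 1
        return None

    def context_of(self, pos: int) -> str:
        lo, hi = self.span
        if pos < lo or pos > hi:
            return "intergenic"
        return "exonic" if self.cds_offset_of(pos) is not None else "intronic"

    def extract_cds(self, reference: str) -> str:
        raw = "".join(reference[s - 1:e] for s, e in self.exons)
        if self.strand == "-":
            raw = "".join(_COMPLEMENT[b] for b in reversed(raw))
        return raw

    @staticmethod
    def translate_codon(codon: str) -> str:
        return str(Seq(codon).translate())

    def translate(self, reference: str) -> str:
        return str(Seq(self.extract_cds(reference)).translate())


def overlap_orfs(vt: VariantTable, models: list[GeneModel]) -> pd.DataFrame:
    """Tag each variant exonic/intronic/intergenic against a set of gene
    models, with gene id and strand-aware CDS offset for exonic hits."""
    rows = []
    for k in range(len(vt)):
        pos = int(vt.df.loc[k, "pos"])
        context, gene_id, cds_off = "intergenic", None, None
        for m in models:
            ctx = m.context_of(pos)
            if ctx == "exonic":
                context, gene_id, cds_off = "exonic", m.gene_id, m.cds_offset_of(pos)
                break
            if ctx == "intronic" and context == "intergenic":
                context, gene_id = "intronic", m.gene_id
        rows.append({"pos": pos, "ref": vt.df.loc[k, "ref"],
                     "alt": vt.df.loc[k, "alt"], "context": context,
                     "gene_id": gene_id, "cds_offset": cds_off})
    return pd.DataFrame(rows, columns=["pos", "ref", "alt", "context",
                                       "gene_id", "cds_offset"])


@dataclass
class CodingEffect:
    pos: int
    ref: str
    alt: str
    gene_id: str
    codon_index: int          # 1-based codon (= residue) index
    residue_index: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect_class: str         # synonymous / nonsynonymous / nonsense
    motif_overlaps: list[str] = field(default_factory=list)
    domain_overlaps: list[str] = field(default_factory=list)


def annotate_effect(variant, model: GeneModel, reference: str) -> CodingEffect:
    """Coding effect of an exonic substitution: ref/alt codons are built
    from the spliced CDS, translated with the standard genetic code;
    class is synonymous/nonsynonymous/nonsense (alt = stop).

    ``variant`` is (pos, ref, alt) in genome coordinates/strand. Raises
    if the variant is not exonic in the model or its ref base disagrees
    with the reference sequence.
    """
    pos, ref, alt = int(variant[0]), variant[1], variant[2]
    if reference[pos - 1] != ref:
        raise ValueError(
            f"ref base mismatch at {pos}: variant {ref!r} vs sequence "
            f"{reference[pos - 1]!r}")
    off = model.cds_offset_of(pos)
    if off is None:
        raise ValueError(f"position {pos} is not exonic in {model.gene_id}")
    cds = model.extract_cds(reference)
    codon_index = (off - 1) // 3 + 1
    within = (off - 1) % 3
    ref_codon = cds[(codon_index - 1) * 3: codon_index * 3]
    alt_cds_base = alt if model.strand == "+" else _COMPLEMENT[alt]
    alt_codon = ref_codon[:within] + alt_cds_base + ref_codon[within + 1:]
    ref_aa = GeneModel.translate_codon(ref_codon)
    alt_aa = GeneModel.translate_codon(alt_codon)
    if ref_aa == alt_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "nonsense"
    else:
        effect = "nonsynonymous"
    return CodingEffect(pos=pos, ref=ref, alt=alt, gene_id=model.gene_id,
                        codon_index=codon_index, residue_index=codon_index,
                        ref_codon=ref_codon, alt_codon=alt_codon,
                        ref_aa=ref_aa, alt_aa=alt_aa, effect_class=effect)


def run_cascade(vt: VariantTable, mutant: str, wildtype: str,
                panel: list[str], models: list[GeneModel],
                reference: str) -> dict:
    """Full screen: unique mutant transitions → ORF overlap → coding
    effects of exonic survivors. Returns the stage counts, the
    annotated survivor table and the exonic candidates' effects."""
    survivors, counts = unique_mutant_transitions(vt, mutant, wildtype, panel)
    ann = overlap_orfs(survivors, models)
    counts["in_orf_exon"] = int((ann["context"] == "exonic").sum())
    by_id = {m.gene_id: m for m in models}
    effects = [
        annotate_effect((row.pos, row.ref, row.alt), by_id[row.gene_id], reference)
        for row in ann.itertuples()
        if row.context == "exonic"
    ]
    return {"counts": counts, "survivors": survivors, "annotated": ann,
            "effects": effects}


# ---------------------------------------------------------------------------
# CDS haplotypes
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeSet:
    snp_positions: list[int]
    table: pd.DataFrame          # accession, haplotype_id, protein_id
    haplotypes: dict[str, str]   # haplotype_id → allele string
    proteins: dict[str, str]     # protein_id → sequence
    counts: dict

    def haplotype_of(self, accession: str) -> str:
        return self.table.set_index("accession").loc[accession, "haplotype_id"]


def build_haplotypes(vt: VariantTable, model: GeneModel,
                     reference: str) -> HaplotypeSet:
    """Per-accession CDS SNP haplotypes for one gene and the proteins
    they translate to, both deduplicated.

    Keeps the variants of ``vt`` falling in the model's exons; counts
    report SNPs, unique haplotypes, unique proteins and non-synonymous
    SNPs. Unique proteins can never exceed unique haplotypes.
    """
    exonic = np.array([model.cds_offset_of(int(p)) is not None
                       for p in vt.df["pos"]], dtype=bool)
    sub = vt.subset(exonic)
    sub = sub.subset(np.argsort(sub.df["pos"].to_numpy(), kind="stable"))
    positions = [int(p) for p in sub.df["pos"]]
    effects = [annotate_effect((p, r, a), model, reference)
               for p, r, a in zip(sub.df["pos"], sub.df["ref"], sub.df["alt"])]
    n_nonsyn = sum(e.effect_class != "synonymous" for e in effects)

    cds = model.extract_cds(reference)
    offsets = [model.cds_offset_of(p) for p in positions]
    alt_cds = [a if model.strand == "+" else _COMPLEMENT[a] for a in sub.df["alt"]]

    hap_ids: dict[str, str] = {}
    prot_ids: dict[str, str] = {}
    rows = []
    for j, acc in enumerate(sub.accessions):
        alleles = "".join("1" if sub.carriers[i, j] else "0"
                          for i in range(len(sub)))
        if alleles not in hap_ids:
            hap_ids[alleles] = f"H{len(hap_ids) + 1:02d}"
        seq = list(cds)
        for i, (off, ab) in enumerate(zip(offsets, alt_cds)):
            if sub.carriers[i, j]:
                seq[off - 1] = ab
        prot = str(Seq("".join(seq)).translate())
        if prot not in prot_ids:
            prot_ids[prot] = f"P{len(prot_ids) + 1:02d}"
        rows.append({"accession": acc, "haplotype_id": hap_ids[alleles],
                     "protein_id": prot_ids[prot]})
    table = pd.DataFrame(rows)
    counts = {"n_snps": len(sub), "n_haplotypes": len(hap_ids),
              "n_proteins": len(prot_ids), "n_nonsynonymous": int(n_nonsyn)}
    return HaplotypeSet(
        snp_positions=positions, table=table,
        haplotypes={v: k for k, v in hap_ids.items()},
        proteins={v: k for k, v in prot_ids.items()},
        counts=counts,
    )


# ---------------------------------------------------------------------------
# conservation, motifs, domains
# ---------------------------------------------------------------------------

def _as_pairs(msa) -> list[tuple[str, str]]:
    if hasattr(msa, "__iter__") and not isinstance(msa, (str, bytes)):
        pairs = []
        for rec in msa:
            if isinstance(rec, tuple):
                pairs.append((rec[0], str(rec[1])))
            else:  # Bio SeqRecord
                pairs.append((rec.id, str(rec.seq)))
        return pairs
    raise TypeError("alignment must be iterable of (id, seq) or SeqRecords")


@dataclass
class ConservationProfile:
    frame: pd.DataFrame           # per column: consensus, fraction, class
    reference_id: str
    residue_to_column: dict[int, int]   # 1-based residue → 0-based column

    def class_at_residue(self, residue: int) -> str:
        return self.frame.loc[self.residue_to_column[residue], "class"]


def conservation_profile(msa, reference_id: str | None = None,
                         gap_chars: str = "-.", high_threshold: float = 0.5,
                         ) -> ConservationProfile:
    """Per-column conservation of an aligned protein set.

    Consensus fraction is taken over non-gap residues; columns are
    ``perfect`` (fraction 1), ``high`` (≥ ``high_threshold``) or
    ``variable``. All-gap columns are ``variable`` with fraction 0. A
    column↔residue index map is kept for the designated reference row
    (default: the first row).
    """
    pairs = _as_pairs(msa)
    if not pairs:
        raise ValueError("empty alignment")
    lengths = {len(s) for _, s in pairs}
    if len(lengths) != 1:
        raise ValueError("aligned rows must have equal length")
    if reference_id is None:
        reference_id = pairs[0][0]
    ref_seq = dict(pairs).get(reference_id)
    if ref_seq is None:
        raise ValueError(f"reference row {reference_id!r} not in alignment")
    arr = np.array([list(s) for _, s in pairs])
    gaps = np.isin(arr, list(gap_chars))
    rows = []
    for c in range(arr.shape[1]):
        col = arr[~gaps[:, c], c]
        if col.size == 0:
            rows.append({"consensus": "-", "fraction": 0.0, "class": "variable"})
            continue
        vals, counts = np.unique(col, return_counts=True)
        k = int(np.argmax(counts))
        frac = counts[k] / col.size
        cls = ("perfect" if counts[k] == col.size
               else "high" if frac >= high_threshold else "variable")
        rows.append({"consensus": str(vals[k]), "fraction": float(frac),
                     "class": cls})
    res_to_col = {}
    res = 0
    for c, ch in enumerate(ref_seq):
        if ch not in gap_chars:
            res += 1
            res_to_col[res] = c
    return ConservationProfile(frame=pd.DataFrame(rows),
                               reference_id=reference_id,
                               residue_to_column=res_to_col)


def check_motif_domain(effect, profile: ConservationProfile,
                       motifs: dict[str, tuple[int, int]] | None = None,
                       domains: dict[str, tuple[int, int]] | None = None) -> dict:
    """Overlap report for a substitution's residue against named motif
    and domain residue intervals (inclusive), plus the alignment
    column's conservation class. ``conserved_site_hit`` is set when the
    class is perfect/high AND at least one interval contains the
    residue."""
    residue = effect.residue_index if isinstance(effect, CodingEffect) else int(effect)
    if residue not in profile.residue_to_column:
        raise ValueError(f"residue {residue} beyond the reference protein length")
    motifs = motifs or {}
    domains = domains or {}
    motif_hits = [n for n, (a, b) in motifs.items() if a <= residue <= b]
    domain_hits = [n for n, (a, b) in domains.items() if a <= residue <= b]
    cls = profile.class_at_residue(residue)
    return {
        "residue": residue,
        "motif_overlaps": motif_hits,
        "domain_overlaps": domain_hits,
        "conservation_class": cls,
        "conserved_site_hit": bool((motif_hits or domain_hits)
                                   and cls in ("perfect", "high")),
    }


# ---------------------------------------------------------------------------
# neighbour-joining tree on uncorrected identity distances
# ---------------------------------------------------------------------------

def identity_distance(s1: str, s2: str, gap_chars: str = "-.") -> float:
    """1 − (identical aligned positions / compared positions); gaps are
    excluded from both numerator and denominator (no correction)."""
    a = np.array(list(s1))
    b = np.array(list(s2))
    if a.size != b.size:
        raise ValueError("sequences must be aligned to equal length")
    ok = ~(np.isin(a, list(gap_chars)) | np.isin(b, list(gap_chars)))
    if not ok.any():
        raise ValueError("no comparable (non-gap) positions")
    return float(1.0 - (a[ok] == b[ok]).mean())


def _clamp_negative_branches(tree) -> None:
    """Zero out negative branch lengths, moving the deficit onto the
    sister branch so path lengths through the parent are preserved."""
    for clade in tree.get_nonterminals():
        kids = clade.clades
        for i, kid in enumerate(kids):
            bl = kid.branch_length or 0.0
            if bl < 0:
                deficit = -bl
                kid.branch_length = 0.0
                for j, sib in enumerate(kids):
                    if j != i:
                        sib.branch_length = (sib.branch_length or 0.0) + deficit
                        break


def nj_tree(msa):
    """Unrooted neighbour-joining tree (Bio.Phylo) from pairwise
    uncorrected identity distances of an aligned protein set."""
    pairs = _as_pairs(msa)
    if len(pairs) < 3:
        raise ValueError("need at least three sequences")
    names = [n for n, _ in pairs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sequence labels")
    matrix = []
    for i in range(len(pairs)):
        matrix.append([identity_distance(pairs[i][1], pairs[j][1])
                       for j in range(i)] + [0.0])
    dm = DistanceMatrix(names, matrix)
    tree = DistanceTreeConstructor().nj(dm)
    _clamp_negative_branches(tree)
    for clade in tree.get_nonterminals():
        clade.name = None  # drop the constructor's internal labels
    return tree


def tree_topology(tree) -> frozenset:
    """Unrooted topology as the set of non-trivial bipartitions (leaf
    name splits); used to compare trees irrespective of rooting."""
    leaves = frozenset(t.name for t in tree.get_terminals())
    splits = set()
    for clade in tree.get_nonterminals():
        side = frozenset(t.name for t in clade.get_terminals())
        if 1 < len(side) < len(leaves) - 1:
            splits.add(frozenset((side, leaves - side)))
    return frozenset(splits)


# ---------------------------------------------------------------------------
# promoter-deletion allele typing
# ---------------------------------------------------------------------------

DEFAULT_PROMOTER_DELETIONS = {"1208-del": 1208, "Ku": 1423, "Jul": 5162}


def classify_promoter_allele(promoter_sequence: str, wildtype_length: int,
                             deletions: dict | None = None) -> str:
    """Type a promoter sequence against known large-deletion alleles.

    ``deletions`` maps allele name → deletion size in bp (or (start,
    end) breakpoints, 1-based inclusive). A full-length sequence is the
    wild-type (``ku``) allele; a sequence shorter by exactly one known
    deletion size gets that allele name; anything else is ``unknown``.
    """
    dels = deletions if deletions is not None else DEFAULT_PROMOTER_DELETIONS
    sizes = {}
    for name, v in dels.items():
        sizes[name] = (v[1] - v[0] + 1) if isinstance(v, (tuple, list)) else int(v)
    n = len(promoter_sequence)
    if n < wildtype_length - max(sizes.values()):
        raise ValueError("sequence shorter than the largest known deletion "
                         "allele; cannot type")
    if n == wildtype_length:
        return "ku"
    missing = wildtype_length - n
    for name, size in sizes.items():
        if missing == size:
            return name
    return "unknown"
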