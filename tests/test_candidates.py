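"""Candidate cascade: transition screen, ORF overlap, coding effects,
haplotypes, conservation, motif/domain overlap, NJ tree and promoter
alleles."""
import itertools

import numpy as np
import pandas as pd
import pytest

from eflmap import candidates as cand
from eflmap import simpop
from eflmap.candidates import GeneModel, VariantTable


def _vt(records, accessions, carriers, region=(1, 1000)):
    return VariantTable(chrom="region", region=region,
                        df=pd.DataFrame(records, columns=["pos", "ref", "alt"]),
                        carriers=np.array(carriers, dtype=bool),
                        accessions=accessions)


# ---------------------------------------------------------------------------
# substitution classes
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ref,alt,expected", [
    ("G", "A", "transition"), ("A", "G", "transition"),
    ("C", "T", "transition"), ("T", "C", "transition"),
    ("A", "C", "transversion"), ("G", "T", "transversion"),
    ("G", "C", "transversion"), ("A", "T", "transversion"),
])
def test_classify_substitution(ref, alt, expected):
    assert cand.classify_substitution(ref, alt) == expected


def test_classify_rejects_bad_bases():
    with pytest.raises(ValueError, match="identical"):
        cand.classify_substitution("A", "A")
    with pytest.raises(ValueError, match="A/C/G/T"):
        cand.classify_substitution("N", "A")


# ---------------------------------------------------------------------------
# uniqueness screen
# ---------------------------------------------------------------------------

def test_unique_screen_stages_and_counts():
    acc = ["mut", "wt", "p1", "p2"]
    records = [
        (10, "G", "A"),   # transition, mutant-only → survives
        (20, "C", "T"),   # transition, shared with panel → panel stage
        (30, "A", "C"),   # transversion → first stage
        (40, "G", "A"),   # transition, also in wild type → wt stage
    ]
    carriers = [
        [1, 0, 0, 0],
        [1, 0, 1, 0],
        [1, 0, 0, 0],
        [1, 1, 0, 0],
    ]
    out, counts = cand.unique_mutant_transitions(
        _vt(records, acc, carriers), "mut", "wt", ["p1", "p2"])
    assert counts == {"total": 4, "transitions": 3,
                      "unique_vs_wildtype": 2, "unique_vs_panel": 1}
    assert list(out.df["pos"]) == [10]
    # cascade monotonicity
    vals = list(counts.values())
    assert all(b <= a for a, b in zip(vals, vals[1:]))


def test_unique_screen_empty_and_errors():
    acc = ["mut", "wt"]
    empty = _vt([], acc, np.zeros((0, 2)))
    out, counts = cand.unique_mutant_transitions(empty, "mut", "wt", [])
    assert len(out) == 0 and counts["total"] == 0
    with pytest.raises(KeyError):
        cand.unique_mutant_transitions(empty, "nope", "wt", [])
    with pytest.raises(ValueError, match="panel"):
        cand.unique_mutant_transitions(empty, "mut", "wt", ["mut"])


def test_planted_variant_survives_cascade(region_sim):
    panel = [a for a in region_sim.variants.accessions
             if a not in ("mutant", "wildtype")]
    res = cand.run_cascade(region_sim.variants, "mutant", "wildtype", panel,
                           region_sim.models, region_sim.reference)
    causal = region_sim.truth["causal"]
    hit = [e for e in res["effects"] if e.pos == causal["pos"]]
    assert len(hit) == 1
    assert hit[0].effect_class == "nonsynonymous"
    assert hit[0].residue_index == causal["codon_index"]
    assert hit[0].ref_aa == causal["ref_aa"] and hit[0].alt_aa == causal["alt_aa"]


# ---------------------------------------------------------------------------
# ORF overlap and coding effects
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_gene():
    #        exon1 10-15   intron   exon2 20-22
    # CDS (+): positions 10..15,20..22 → 9 nt
    ref = list("N" * 30)
    ref[9:15] = list("ATGGCA")   # M A
    ref[19:22] = list("TGG")     # W
    return GeneModel("g1", "+", [(10, 15), (20, 22)]), "".join(ref)


def test_overlap_contexts(toy_gene):
    model, ref = toy_gene
    vt = _vt([(10, "A", "G"), (17, "N", "A"), (25, "N", "A"), (21, "G", "A")],
             ["x"], [[1]] * 4, region=(1, 30))
    ann = cand.overlap_orfs(vt, [model])
    assert list(ann["context"]) == ["exonic", "intronic", "intergenic",
                                    "exonic"]
    assert ann.loc[0, "cds_offset"] == 1
    assert ann.loc[3, "cds_offset"] == 8


def test_minus_strand_offset():
    model = GeneModel("g2", "-", [(10, 12), (20, 22)])
    # last base of the last genomic exon is CDS position 1 on minus strand
    assert model.cds_offset_of(22) == 1
    assert model.cds_offset_of(10) == 6


@pytest.mark.parametrize("codon,alt_codon,aa,cls", [
    ("GCA", "ACA", ("A", "T"), "nonsynonymous"),
    ("CTG", "TTG", ("L", "L"), "synonymous"),
    ("TGG", "TGA", ("W", "*"), "nonsense"),
])
def test_annotate_effect_classes(codon, alt_codon, aa, cls):
    diff = next(i for i in range(3) if codon[i] != alt_codon[i])
    ref = "NNN" + codon + "NNN"
    model = GeneModel("g", "+", [(4, 6)])
    eff = cand.annotate_effect((4 + diff, codon[diff], alt_codon[diff]),
                               model, ref)
    assert (eff.ref_aa, eff.alt_aa) == aa
    assert eff.effect_class == cls
    assert eff.ref_codon == codon and eff.alt_codon == alt_codon
    assert eff.residue_index == 1


def test_annotate_effect_minus_strand():
    # minus-strand gene: genomic TGC at 4..6 → CDS GCA → Ala; genomic
    # C→T at position 4 is CDS G→A at codon position 1 → Thr
    ref = "NNNTGCNNN"
    model = GeneModel("gm", "-", [(4, 6)])
    eff = cand.annotate_effect((6, "C", "T"), model, ref)
    assert eff.ref_aa == "A" and eff.alt_aa == "T"
    assert eff.effect_class == "nonsynonymous"


def test_annotate_effect_errors(toy_gene):
    model, ref = toy_gene
    with pytest.raises(ValueError, match="ref base mismatch"):
        cand.annotate_effect((10, "C", "G"), model, ref)
    with pytest.raises(ValueError, match="not exonic"):
        cand.annotate_effect((17, "N", "A"), model, ref)
    with pytest.raises(ValueError, match="codon multiple"):
        GeneModel("bad", "+", [(1, 4)])


def test_effects_agree_with_whole_cds_retranslation(region_sim):
    """Oracle: rebuild the full mutant CDS with each variant applied and
    diff the translated proteins."""
    causal = region_sim.truth["causal"]
    model = next(m for m in region_sim.models
                 if m.gene_id == causal["orf_id"])
    ref = region_sim.reference
    base_prot = model.translate(ref)
    vt = region_sim.variants
    exonic = [k for k in range(len(vt))
              if model.cds_offset_of(int(vt.df.loc[k, "pos"])) is not None]
    assert exonic
    for k in exonic:
        pos, r, a = (int(vt.df.loc[k, "pos"]), vt.df.loc[k, "ref"],
                     vt.df.loc[k, "alt"])
        eff = cand.annotate_effect((pos, r, a), model, ref)
        mutated = ref[:pos - 1] + a + ref[pos:]
        prot = model.translate(mutated)
        diffs = [i + 1 for i, (x, y) in enumerate(zip(base_prot, prot))
                 if x != y]
        if eff.effect_class == "synonymous":
            assert diffs == []
        else:
            assert diffs == [eff.residue_index]
            assert prot[eff.residue_index - 1] == eff.alt_aa


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

def test_haplotype_dedup():
    model = GeneModel("g", "+", [(1, 6)])
    ref = "ATGGCA"
    vt = _vt([(3, "G", "A"), (6, "A", "G")], ["a", "b", "c", "d"],
             [[0, 0, 0, 1], [0, 1, 1, 1]], region=(1, 6))
    hs = cand.build_haplotypes(vt, model, ref)
    assert hs.counts["n_snps"] == 2
    assert hs.counts["n_haplotypes"] == 3      # 00, 01, 01, 11 → 3 unique
    assert hs.counts["n_proteins"] <= hs.counts["n_haplotypes"]
    assert hs.haplotype_of("b") == hs.haplotype_of("c")


def test_all_reference_single_haplotype():
    model = GeneModel("g", "+", [(1, 6)])
    vt = _vt([], ["a", "b"], np.zeros((0, 2)), region=(1, 6))
    hs = cand.build_haplotypes(vt, model, "ATGGCA")
    assert hs.counts["n_haplotypes"] == 1
    assert hs.counts["n_proteins"] == 1


def test_mutant_haplotype_differs_only_by_causal_snp():
    spec = simpop.VariantRegionSpec(background_transition_rate=0.0,
                                    background_transversion_rate=0.0)
    reg = simpop.simulate_variant_region(spec, seed=2)
    causal = reg.truth["causal"]
    model = next(m for m in reg.models if m.gene_id == causal["orf_id"])
    hs = cand.build_haplotypes(reg.variants, model, reg.reference)
    hm = hs.haplotypes[hs.haplotype_of("mutant")]
    hw = hs.haplotypes[hs.haplotype_of("wildtype")]
    assert sum(a != b for a, b in zip(hm, hw)) == 1
    pm = hs.proteins[hs.table.set_index("accession").loc["mutant", "protein_id"]]
    pw = hs.proteins[hs.table.set_index("accession").loc["wildtype", "protein_id"]]
    diffs = [i + 1 for i, (x, y) in enumerate(zip(pm, pw)) if x != y]
    assert diffs == [causal["codon_index"]]


# ---------------------------------------------------------------------------
# conservation and motif/domain overlap
# ---------------------------------------------------------------------------

def test_conservation_classes():
    msa = [("ref", "AAAR")] + [(f"t{k}", "AATR") for k in range(9)]
    prof = cand.conservation_profile(msa)
    # column 1: 10/10 A → perfect; column 3: 9 T + 1 A → high (0.9)
    assert prof.frame.loc[0, "class"] == "perfect"
    assert prof.frame.loc[2, "class"] == "high"
    assert prof.frame.loc[2, "fraction"] == pytest.approx(0.9)


def test_conservation_variable_below_half():
    col = ["A"] * 14 + ["C"] * 8 + ["G"] * 8
    msa = [(f"t{k}", c) for k, c in enumerate(col)]
    prof = cand.conservation_profile(msa)
    assert prof.frame.loc[0, "fraction"] == pytest.approx(14 / 30)
    assert prof.frame.loc[0, "class"] == "variable"


def test_conservation_gap_handling():
    msa = [("ref", "A-C"), ("t1", "A--"), ("t2", "A--")]
    prof = cand.conservation_profile(msa)
    assert prof.frame.loc[1, "class"] == "variable"
    assert prof.frame.loc[1, "fraction"] == 0.0
    # reference residue map skips the gap column
    assert prof.residue_to_column == {1: 0, 2: 2}
    with pytest.raises(ValueError, match="equal length"):
        cand.conservation_profile([("a", "AA"), ("b", "A")])


def test_motif_domain_overlap_rules():
    prot = "A" * 700
    msa = [("ref", prot)] + [(f"t{k}", prot) for k in range(5)]
    prof = cand.conservation_profile(msa)
    domains = {"SAM_MTase": (503, 660)}
    hit = cand.check_motif_domain(534, prof, domains=domains)
    assert hit["domain_overlaps"] == ["SAM_MTase"]
    assert hit["conserved_site_hit"]
    outside = cand.check_motif_domain(502, prof, domains=domains)
    assert outside["domain_overlaps"] == []
    assert not outside["conserved_site_hit"]
    with pytest.raises(ValueError, match="beyond"):
        cand.check_motif_domain(701, prof)


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def test_identity_distance_counts():
    assert cand.identity_distance("AAAA", "AAAT") == pytest.approx(0.25)
    assert cand.identity_distance("A-AA", "AAA-") == pytest.approx(0.0)
    with pytest.raises(ValueError, match="comparable"):
        cand.identity_distance("--", "AA")


def _tree_sequences(edges, length):
    """Sequences whose pairwise Hamming distances are additive on a
    known topology: each edge mutates its own disjoint position set."""
    taxa = sorted({t for side, _ in edges for t in side})
    seqs = {t: list("A" * length) for t in taxa}
    pos = 0
    for side, n_mut in edges:
        for _ in range(n_mut):
            for t in side:
                seqs[t][pos] = "C"
            pos += 1
    assert pos <= length
    return [(t, "".join(seqs[t])) for t in taxa]


@pytest.mark.parametrize("internal", [
    (("t1", "t2"), ("t4", "t5")),             # balanced
    (("t1", "t2"), ("t1", "t2", "t3")),       # caterpillar
])
def test_nj_recovers_additive_topology_five_taxa(internal):
    """For additive distances the generating topology is the unique
    zero-deviation tree among all 15 five-taxon topologies, so NJ must
    return both of its internal splits."""
    taxa = ["t1", "t2", "t3", "t4", "t5"]
    edges = [((t,), 3 + i) for i, t in enumerate(taxa)]
    edges += [(side, 4 + k) for k, side in enumerate(internal)]
    msa = _tree_sequences(edges, 60)
    tree = cand.nj_tree(msa)
    splits = cand.tree_topology(tree)
    leaves = frozenset(taxa)
    want = {frozenset((frozenset(side), leaves - frozenset(side)))
            for side in internal}
    assert want <= set(splits)
    assert all((c.branch_length or 0) >= 0 for c in tree.find_clades())


def test_nj_recovers_quartet_against_four_point_oracle():
    edges = [(("a",), 2), (("b",), 3), (("c",), 4), (("d",), 2),
             (("a", "b"), 6)]
    msa = _tree_sequences(edges, 40)
    # four-point oracle
    d = {frozenset(p): cand.identity_distance(dict(msa)[p[0]], dict(msa)[p[1]])
         for p in itertools.combinations([t for t, _ in msa], 2)}
    sums = {
        "ab|cd": d[frozenset(("a", "b"))] + d[frozenset(("c", "d"))],
        "ac|bd": d[frozenset(("a", "c"))] + d[frozenset(("b", "d"))],
        "ad|bc": d[frozenset(("a", "d"))] + d[frozenset(("b", "c"))],
    }
    assert min(sums, key=sums.get) == "ab|cd"
    tree = cand.nj_tree(msa)
    leaves = frozenset("abcd")
    split = frozenset((frozenset(("a", "b")), frozenset(("c", "d"))))
    assert split in cand.tree_topology(tree)


def test_nj_three_identical_star():
    msa = [("a", "AAAA"), ("b", "AAAA"), ("c", "AAAA")]
    tree = cand.nj_tree(msa)
    assert sum(c.branch_length or 0 for c in tree.find_clades()) == \
        pytest.approx(0.0)


def test_nj_input_validation():
    with pytest.raises(ValueError, match="three"):
        cand.nj_tree([("a", "AA"), ("b", "AA")])
    with pytest.raises(ValueError, match="duplicate"):
        cand.nj_tree([("a", "AA"), ("a", "AT"), ("b", "AA")])


# ---------------------------------------------------------------------------
# promoter alleles
# ---------------------------------------------------------------------------

def test_promoter_allele_typing():
    wt_len = 6000
    full = "A" * wt_len
    assert cand.classify_promoter_allele(full, wt_len) == "ku"
    assert cand.classify_promoter_allele("A" * (wt_len - 1423), wt_len) == "Ku"
    assert cand.classify_promoter_allele("A" * (wt_len - 5162), wt_len) == "Jul"
    assert cand.classify_promoter_allele("A" * (wt_len - 1208), wt_len) == \
        "1208-del"
    assert cand.classify_promoter_allele("A" * (wt_len - 300), wt_len) == \
        "unknown"
    with pytest.raises(ValueError, match="shorter"):
        cand.classify_promoter_allele("A" * 100, wt_len)
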