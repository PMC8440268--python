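"""Readers/writers for every format the pipeline touches.

Genotype matrices travel as CSV (rows = individuals, columns = markers,
cells in {A, B, H, U}, with ``-`` accepted as a missing alias); variant
tables as VCF v4.2 (1-based, via pysam); gene models as GFF3 (1-based
inclusive, read via gffutils); sequences as FASTA/aligned FASTA (via
Biopython, wrapped at 60 columns); trees as newick (via Bio.Phylo);
genetic maps as a three-column CSV. All genomic coordinates are 1-based
inclusive internally.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import gffutils
import yaml
from Bio import AlignIO, Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .candidates import GeneModel, VariantTable
from .linkmap import GeneticMap, LinkageGroup
from .matrix import MarkerGenotypeMatrix, VALID_CALLS, default_marker_info

# ---------------------------------------------------------------------------
# genotype CSV
# ---------------------------------------------------------------------------

_DEFAULT_ALIASES = {"-": "U"}


def read_genotypes(path, aliases: dict | None = None,
                   marker_info: pd.DataFrame | None = None,
                   ) -> MarkerGenotypeMatrix:
    """Read a genotype CSV (header row of marker ids, first column
    individual ids). Unknown symbols are rejected with their location."""
    aliases = _DEFAULT_ALIASES if aliases is None else aliases
    df = pd.read_csv(path, index_col=0, dtype=str)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate individual or marker ids")
    arr = df.to_numpy(dtype="<U8")
    for old, new in aliases.items():
        arr[arr == old] = new
    bad = ~np.isin(arr, list(VALID_CALLS))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid call {str(arr[i, j])!r} at individual "
            f"{str(df.index[i])!r}, marker {str(df.columns[j])!r}")
    if marker_info is None:
        marker_info = default_marker_info(df.columns)
    return MarkerGenotypeMatrix(list(df.index), marker_info,
                                arr.astype("<U1"))


def write_genotypes(m: MarkerGenotypeMatrix, path) -> None:
    m.to_frame().to_csv(path)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"individual", "replicate", "days_to_flowering"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: phenotype CSV needs columns {sorted(need)}")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(vt: VariantTable, path) -> None:
    """VCF v4.2 with one diploid homozygous genotype column per
    accession (1/1 carriers, 0/0 otherwise)."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={vt.chrom},length={vt.region[1]}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for acc in vt.accessions:
        header.add_sample(acc)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for k in range(len(vt)):
            rec = out.new_record(
                contig=vt.chrom, start=int(vt.df.loc[k, "pos"]) - 1,
                stop=int(vt.df.loc[k, "pos"]),
                alleles=(str(vt.df.loc[k, "ref"]), str(vt.df.loc[k, "alt"])),
            )
            for j, acc in enumerate(vt.accessions):
                rec.samples[acc]["GT"] = (1, 1) if vt.carriers[k, j] else (0, 0)
            out.write(rec)


def read_vcf(path) -> VariantTable:
    with pysam.VariantFile(str(path)) as vf:
        accessions = list(vf.header.samples)
        contigs = {c: vf.header.contigs[c].length for c in vf.header.contigs}
        rows, carr = [], []
        chrom = None
        for rec in vf:
            chrom = rec.chrom
            rows.append({"pos": rec.pos, "ref": rec.ref, "alt": rec.alts[0]})
            carr.append([any(a == 1 for a in (rec.samples[acc]["GT"] or ()))
                         for acc in accessions])
    if not rows:
        raise ValueError(f"{path}: VCF contains no records")
    length = contigs.get(chrom) or max(r["pos"] for r in rows)
    return VariantTable(chrom=chrom, region=(1, int(length)),
                        df=pd.DataFrame(rows), carriers=np.array(carr),
                        accessions=accessions)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(models: list[GeneModel], path, source: str = "eflmap") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo, hi = m.span
            fh.write(f"{m.chrom}\t{source}\tgene\t{lo}\t{hi}\t.\t{m.strand}\t."
                     f"\tID={m.gene_id}\n")
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(f"{m.chrom}\t{source}\tCDS\t{s}\t{e}\t.\t{m.strand}\t0"
                         f"\tID={m.gene_id}.cds{i};Parent={m.gene_id}\n")


def read_gff3(path) -> list[GeneModel]:
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models = []
    for gene in db.features_of_type("gene"):
        exons = sorted((c.start, c.end) for c in db.children(gene, featuretype="CDS"))
        if not exons:
            continue
        models.append(GeneModel(gene_id=gene.id, strand=gene.strand,
                                exons=exons, chrom=gene.seqid))
    return models


# ---------------------------------------------------------------------------
# FASTA / alignments / trees
# ---------------------------------------------------------------------------

def write_fasta(records, path) -> None:
    """``records``: iterable of (id, sequence)."""
    seqs = [SeqRecord(Seq(s), id=str(n), description="") for n, s in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_alignment(path) -> list[tuple[str, str]]:
    aln = AlignIO.read(str(path), "fasta")
    return [(rec.id, str(rec.seq)) for rec in aln]


def write_newick(tree, path) -> None:
    Phylo.write(tree, str(path), "newick")


def read_newick(path):
    return Phylo.read(str(path), "newick")


# ---------------------------------------------------------------------------
# map CSV
# ---------------------------------------------------------------------------

def write_map_csv(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, index=False)


def read_map_csv(path) -> GeneticMap:
    df = pd.read_csv(path)
    groups = []
    for gid, sub in df.groupby("group_id", sort=False):
        pos = sub["position_cM"].to_numpy(dtype=float)
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"{path}: positions not monotone in group {gid}")
        groups.append(LinkageGroup(group_id=str(gid),
                                   markers=list(sub["marker_id"]),
                                   positions_cm=pos))
    return GeneticMap(groups=groups)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All stage parameters of the end-to-end run. Threshold defaults
    match the filtering and mapping rules baked into the stage modules."""
    seed: int = 1
    out_dir: str | None = None
    population: dict = field(default_factory=dict)
    qc: dict = field(default_factory=lambda: {
        "min_call_rate": 0.5, "hom_freq_range": (0.2, 0.8),
        "distortion_p_min": 1e-5, "max_het": 0.15})
    linkage: dict = field(default_factory=lambda: {
        "p_threshold": 1e-18, "max_cm": 15.0, "min_cluster_size": 5,
        "similarity_merge": 0.98})
    qtl: dict = field(default_factory=lambda: {
        "step_cm": 1.0, "n_perm": 200, "alpha": 0.05})
    region: dict = field(default_factory=dict)
    categorize: dict = field(default_factory=lambda: {
        "early_range": (71.0, 78.0), "late_range": (84.0, 95.0)})
    expression: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("min_call_rate", "max_het"):
            v = self.qc.get(name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"qc.{name} must be a probability, got {v}")
        lo, hi = self.qc.get("hom_freq_range", (0.2, 0.8))
        if not (0 <= lo < hi <= 1):
            raise ValueError("qc.hom_freq_range must be an increasing "
                             "sub-interval of [0, 1]")
        if not 0 < self.qtl.get("alpha", 0.05) < 1:
            raise ValueError("qtl.alpha must lie in (0, 1)")
        if self.qtl.get("n_perm", 200) < 100:
            raise ValueError("qtl.n_perm must be at least 100")
        for name in ("error_rate", "missing_rate", "ambiguous_phase_fraction"):
            v = self.population.get(name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"population.{name} must be a probability")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def write_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(summary), indent=2) + "\n")


# re-export: the orchestrator lives in pipeline.py but belongs to this surface
from .pipeline import run_pipeline  # noqa: E402,F401
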