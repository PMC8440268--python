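"""Published summary of the Chittick × Geebung F6 linkage map and its
QTL peak, used to dimension simulations and to check arithmetic
consistency of the reported map.

The map comprises 23 linkage groups built from 181 F6 RILs; marker
counts below include the qualitative flowering-phenotype marker in its
group (one of the 2315 mapped markers; 2314 are molecular DArTseq
markers).
"""
from __future__ import annotations

#: (linkage group id, size in cM, number of mapped markers)
LINKAGE_GROUPS: list[tuple[str, float, int]] = [
    ("CxG_LG01", 27.7, 43),
    ("CxG_LG02", 0.6, 10),
    ("CxG_LG03", 80.7, 227),
    ("CxG_LG04", 1.7, 12),
    ("CxG_LG05", 86.3, 188),
    ("CxG_LG06", 41.5, 80),
    ("CxG_LG07", 23.3, 43),
    ("CxG_LG08", 26.4, 86),
    ("CxG_LG09", 6.4, 21),
    ("CxG_LG10", 44.3, 342),
    ("CxG_LG11", 17.5, 84),
    ("CxG_LG12", 8.0, 24),
    ("CxG_LG13", 77.2, 92),
    ("CxG_LG14", 131.8, 403),
    ("CxG_LG15", 4.4, 12),
    ("CxG_LG16", 12.5, 55),
    ("CxG_LG17", 7.1, 27),
    ("CxG_LG18", 75.0, 198),
    ("CxG_LG19", 26.4, 72),
    ("CxG_LG20", 5.5, 36),
    ("CxG_LG21", 0.7, 8),
    ("CxG_LG22", 67.1, 222),
    ("CxG_LG23", 9.1, 30),
]

#: printed totals of the published map
TOTAL_MAP_CM = 781.2
TOTAL_MAPPED_MARKERS = 2315          # incl. the phenotype-derived marker
TOTAL_MOLECULAR_MARKERS = 2314       # DArTseq SNP + PAV markers

#: RILs retained in the final map and the QTL peak statistics
N_RILS_MAPPED = 181
PEAK_R2 = 0.8195
PEAK_LOD = 67.25
FLANK_INTERVAL_CM = 1.26

#: pre-QC marker panel and phenotyped population sizes
N_SNP_RAW = 2503
N_PAV_RAW = 17_710
N_RILS_PHENOTYPED = 185
N_F2 = 200

#: candidate-region screen dimensions
REGION_LENGTH_BP = 267_160
N_REGION_ORFS = 40
N_PANEL_ACCESSIONS = 43

#: candidate protein annotation (residue intervals, 1-based inclusive)
CAUSAL_RESIDUE = 534
DOMAINS = {
    "WW": (297, 326),
    "RNA_cap_MTase": (541, 695),
    "SAM_MTase": (503, 660),
}
MOTIF_X = {"motif_X": (528, 540)}    # motif X window around the causal residue


def total_length_cm() -> float:
    """Sum of the 23 printed linkage-group sizes."""
    return round(sum(size for _, size, _ in LINKAGE_GROUPS), 1)


def total_markers(include_phenotype_marker: bool = True) -> int:
    """Sum of the printed per-group marker counts; subtracting the one
    phenotype-derived marker leaves the molecular markers."""
    n = sum(count for _, _, count in LINKAGE_GROUPS)
    return n if include_phenotype_marker else n - 1


def group_lengths() -> list[tuple[str, float]]:
    return [(gid, size) for gid, size, _ in LINKAGE_GROUPS]


def marker_counts(total: int = TOTAL_MOLECULAR_MARKERS,
                  snp_fraction: float = 0.5) -> dict[str, dict[str, int]]:
    """Per-group SNP/PAV counts proportional to the published per-group
    totals, for simulations that reproduce the map's dimensions."""
    published_total = total_markers(include_phenotype_marker=False)
    out: dict[str, dict[str, int]] = {}
    for gid, _, count in LINKAGE_GROUPS:
        scaled = max(2, round(count / published_total * total))
        n_snp = int(round(scaled * snp_fraction))
        out[gid] = {"SNP": n_snp, "PAV": scaled - n_snp}
    return out
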