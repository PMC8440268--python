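"""Marker quality control and phasing.

Filters follow the standard genotyping-by-sequencing rules for a
bi-parental RIL panel: retain markers with > 50% call rate, a
homozygous allele frequency between 0.2 and 0.8 (SNPs only), a
segregation-distortion chi-square P value > 1e−5, and (SNPs only)
heterozygosity ≤ 15%. Markers are then phased against the parental
genotypes; markers whose parental origin cannot be determined are
mirror-expanded into both phases.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .matrix import MarkerGenotypeMatrix


def distortion_test(calls) -> tuple[float, float]:
    """Segregation-distortion chi-square of a marker column against the
    expected 1:1 ratio of homozygous A:B calls (df = 1, no continuity
    correction): chi2 = (a−b)²/(a+b).

    Heterozygous calls are excluded (they are recoded missing for map
    construction). Raises on an all-missing column.
    """
    arr = np.asarray(calls)
    if not np.isin(arr, ("A", "B", "H")).any():
        raise ValueError("all calls missing; distortion test undefined")
    a = int(np.sum(arr == "A"))
    b = int(np.sum(arr == "B"))
    if a + b == 0:
        return np.nan, np.nan
    chi2 = (a - b) ** 2 / (a + b)
    return float(chi2), float(chi2_dist.sf(chi2, 1))


def filter_markers(m: MarkerGenotypeMatrix, min_call_rate: float = 0.5,
                   hom_freq_range: tuple[float, float] = (0.2, 0.8),
                   distortion_p_min: float = 1e-5, max_het: float = 0.15,
                   ) -> tuple[MarkerGenotypeMatrix, pd.DataFrame]:
    """Apply all marker QC rules; a marker failing several rules reports
    every reason.

    Call rate counts any non-missing call. The homozygous allele
    frequency is count(A)/(count(A)+count(B)); it and the
    heterozygosity rule apply to SNP markers only (PAV markers are
    dominant and carry no H calls). Returns the retained matrix and a
    per-marker report.
    """
    if m.n_markers == 0:
        raise ValueError("empty marker matrix")
    calls = m.calls
    n = m.n_individuals
    nA = (calls == "A").sum(axis=0)
    nB = (calls == "B").sum(axis=0)
    nH = (calls == "H").sum(axis=0)
    called = nA + nB + nH
    call_rate = called / n
    with np.errstate(divide="ignore", invalid="ignore"):
        hom_freq = np.where(nA + nB > 0, nA / np.maximum(nA + nB, 1), np.nan)
        het_rate = np.where(called > 0, nH / np.maximum(called, 1), np.nan)
    chi2 = np.where(nA + nB > 0, (nA - nB) ** 2 / np.maximum(nA + nB, 1), np.nan)
    pval = chi2_dist.sf(chi2, 1)
    is_snp = (m.marker_info["type"] == "SNP").to_numpy()

    reasons = [[] for _ in range(m.n_markers)]
    lo, hi = hom_freq_range
    for j in range(m.n_markers):
        if call_rate[j] <= min_call_rate:
            reasons[j].append("call_rate")
        if nA[j] + nB[j] == 0:
            reasons[j].append("no_homozygous_calls")
        else:
            if is_snp[j] and not (lo <= hom_freq[j] <= hi):
                reasons[j].append("hom_freq")
            if pval[j] <= distortion_p_min:
                reasons[j].append("distortion")
        if is_snp[j] and het_rate[j] > max_het:
            reasons[j].append("het_rate")
    ok = np.array([not r for r in reasons])
    report = pd.DataFrame({
        "marker": m.marker_ids,
        "type": m.marker_info["type"].to_numpy(),
        "call_rate": call_rate,
        "hom_allele_freq": hom_freq,
        "het_rate": het_rate,
        "distortion_chi2": chi2,
        "distortion_P": pval,
        "pass": ok,
        "reasons": [";".join(r) for r in reasons],
    })
    kept = m.subset_markers([mid for mid, k in zip(m.marker_ids, ok) if k])
    return kept, report


@dataclass
class PhasedMatrices:
    """Output of phasing: the map-construction matrix (H recoded
    missing, ambiguous markers mirror-expanded) and the validation
    matrix (heterozygous calls retained, no mirroring)."""
    mapping: MarkerGenotypeMatrix
    validation: MarkerGenotypeMatrix


def phase_and_mirror(m: MarkerGenotypeMatrix, parents: pd.DataFrame,
                     mirror_suffix: str = "_mir") -> PhasedMatrices:
    """Phase marker columns to the parental genotypes and mirror-expand
    phase-ambiguous markers.

    ``parents`` has two rows (maternal first) over the same marker
    columns, calls in {A, B, U}. A column whose maternal parent reads A
    keeps its coding (phase ``maternal``); one whose maternal parent
    reads B is flipped (phase ``paternal``); a column with any missing
    or non-discriminating parent call is duplicated into two
    complementary mirror-partner markers. H calls are recoded U in the
    mapping matrix but preserved in the validation matrix.
    """
    if parents is None or len(parents) < 2:
        raise ValueError("parental genotype rows are required for phasing")
    missing_cols = [c for c in m.marker_ids if c not in parents.columns]
    if missing_cols:
        raise ValueError(f"parents lack columns for markers: {missing_cols[:5]}")
    p1 = parents.iloc[0]
    p2 = parents.iloc[1]

    def flip(col):
        return np.where(col == "A", "B", np.where(col == "B", "A", col))

    ids: list[str] = []
    cols: list[np.ndarray] = []
    info_rows: list[dict] = []
    for j, mid in enumerate(m.marker_ids):
        col = m.calls[:, j]
        mtype = m.marker_info.iloc[j]["type"]
        a, b = p1[mid], p2[mid]
        if a == "A" and b == "B":
            ids.append(mid)
            cols.append(col)
            info_rows.append({"type": mtype, "phase": "maternal",
                              "mirror_partner": None})
        elif a == "B" and b == "A":
            ids.append(mid)
            cols.append(flip(col))
            info_rows.append({"type": mtype, "phase": "paternal",
                              "mirror_partner": None})
        else:  # ambiguous parental origin → both phases
            mid2 = mid + mirror_suffix
            ids.extend([mid, mid2])
            cols.extend([col, flip(col)])
            info_rows.append({"type": mtype, "phase": "ambiguous",
                              "mirror_partner": mid2})
            info_rows.append({"type": mtype, "phase": "ambiguous",
                              "mirror_partner": mid})
    info = pd.DataFrame(info_rows, index=pd.Index(ids, name="marker"))
    calls = np.column_stack(cols)
    validation = MarkerGenotypeMatrix(list(m.individuals), info, calls)
    return PhasedMatrices(mapping=validation.mapping_view(),
                          validation=validation)
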