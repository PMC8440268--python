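"""Shared container for individuals × markers genotype calls.

Calls use the single-character codes of a phased bi-parental RIL panel:
``A`` (homozygous maternal allele), ``B`` (homozygous paternal allele),
``H`` (heterozygous, SNP markers only) and ``U`` (missing / uncalled).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_CALLS = frozenset("ABHU")

#: columns always present in ``marker_info``
_INFO_COLUMNS = ("type", "phase", "mirror_partner")


def default_marker_info(marker_ids, marker_type: str = "SNP") -> pd.DataFrame:
    """Metadata table for markers with no special phase/mirror structure."""
    return pd.DataFrame(
        {
            "type": marker_type,
            "phase": "maternal",
            "mirror_partner": None,
        },
        index=pd.Index(list(marker_ids), name="marker"),
    )


@dataclass
class MarkerGenotypeMatrix:
    """Genotype calls for a mapping population.

    Parameters
    ----------
    individuals
        Ordered individual ids (rows of ``calls``).
    marker_info
        Per-marker metadata indexed by marker id, with columns ``type``
        (``SNP`` or ``PAV``), ``phase`` (``maternal`` / ``paternal`` /
        ``ambiguous``) and ``mirror_partner`` (partner marker id for
        mirror-expanded ambiguous markers, else ``None``).
    calls
        ``(n_individuals, n_markers)`` array of single characters in
        ``{A, B, H, U}``.
    """

    individuals: list[str]
    marker_info: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.individuals = list(self.individuals)
        self.calls = np.asarray(self.calls, dtype="<U1")
        if self.calls.shape != (len(self.individuals), len(self.marker_info)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals × {len(self.marker_info)} markers"
            )
        bad = ~np.isin(self.calls, list(VALID_CALLS))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call {str(self.calls[i, j])!r} for individual "
                f"{str(self.individuals[i])!r}, marker "
                f"{str(self.marker_info.index[j])!r}"
            )
        if self.marker_info.index.has_duplicates:
            raise ValueError("duplicate marker ids")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        for col in _INFO_COLUMNS:
            if col not in self.marker_info.columns:
                raise ValueError(f"marker_info missing column {col!r}")

    # -- accessors ---------------------------------------------------------
    @property
    def marker_ids(self) -> list[str]:
        return list(self.marker_info.index)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.marker_info)

    def column(self, marker_id: str) -> np.ndarray:
        j = self.marker_info.index.get_loc(marker_id)
        return self.calls[:, j]

    def encoded(self) -> np.ndarray:
        """Signed int8 encoding: A=+1, B=-1, H/U=0 (uninformative)."""
        out = np.zeros(self.calls.shape, dtype=np.int8)
        out[self.calls == "A"] = 1
        out[self.calls == "B"] = -1
        return out

    # -- transforms --------------------------------------------------------
    def mapping_view(self) -> "MarkerGenotypeMatrix":
        """Copy with heterozygous calls recoded missing, as used for map
        construction and QTL scanning (H is uninformative between two
        homozygous parental phases)."""
        calls = self.calls.copy()
        calls[calls == "H"] = "U"
        return MarkerGenotypeMatrix(list(self.individuals), self.marker_info.copy(), calls)

    def subset_markers(self, marker_ids) -> "MarkerGenotypeMatrix":
        idx = [self.marker_info.index.get_loc(m) for m in marker_ids]
        return MarkerGenotypeMatrix(
            list(self.individuals),
            self.marker_info.iloc[idx].copy(),
            self.calls[:, idx].copy(),
        )

    def subset_individuals(self, ids) -> "MarkerGenotypeMatrix":
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        idx = [pos[i] for i in ids]
        return MarkerGenotypeMatrix(list(ids), self.marker_info.copy(), self.calls[idx].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls, index=pd.Index(self.individuals, name="individual"),
            columns=self.marker_info.index,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, marker_info: pd.DataFrame | None = None,
                   marker_type: str = "SNP") -> "MarkerGenotypeMatrix":
        if marker_info is None:
            marker_info = default_marker_info(df.columns, marker_type)
        return cls(list(df.index), marker_info, df.to_numpy(dtype="<U1"))
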