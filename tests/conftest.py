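import numpy as np
import pandas as pd
import pytest

from eflmap import markerqc, simpop
from eflmap.matrix import MarkerGenotypeMatrix, default_marker_info


@pytest.fixture(scope="session")
def small_population():
    """Error-free three-chromosome F6 RIL population (n=150)."""
    map_spec = simpop.MapSpec([("LG1", 80.0), ("LG2", 60.0), ("LG3", 50.0)],
                              {"SNP": 0.5, "PAV": 0.5})
    locus = simpop.LocusSpec(linkage_group="LG1", position_cM=30.0)
    return simpop.simulate_population(
        map_spec, simpop.CrossDesign("F6_SSD", 150), locus,
        error_rate=0.0, missing_rate=0.0, ambiguous_phase_fraction=0.0, seed=42)


@pytest.fixture(scope="session")
def phased_small(small_population):
    return markerqc.phase_and_mirror(small_population.matrix,
                                     small_population.parents)


@pytest.fixture(scope="session")
def region_sim():
    return simpop.simulate_variant_region(simpop.VariantRegionSpec(), seed=11)


def matrix_from_columns(columns: dict[str, list[str]],
                        types: dict[str, str] | None = None) -> MarkerGenotypeMatrix:
    """Build a genotype matrix from explicit call columns."""
    ids = list(columns)
    n = len(next(iter(columns.values())))
    info = default_marker_info(ids)
    if types:
        for m, t in types.items():
            info.loc[m, "type"] = t
    calls = np.column_stack([np.array(columns[m], dtype="<U1") for m in ids])
    return MarkerGenotypeMatrix([f"i{k}" for k in range(n)], info, calls)
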