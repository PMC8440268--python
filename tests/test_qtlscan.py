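"""Interval-mapping EM scan: genotype probabilities, EM/oracle
agreement, the LOD–R² identity, permutation thresholds and QTL
summaries."""
import numpy as np
import pandas as pd
import pytest

from eflmap import markerqc, qtlscan, simpop
from eflmap.experiments import exact_r2_dataset, marker_grid
from eflmap.linkmap import GeneticMap, LinkageGroup
from eflmap.qtlscan import GenoProbGrid, _em_mixture


def _two_marker_grid(calls_left, calls_right, length=20.0, step=10.0,
                     kind="haldane", ril_expand_r=False):
    n = len(calls_left)
    inds = [f"i{k}" for k in range(n)]
    gmap = GeneticMap(groups=[LinkageGroup("LG1", ["mL", "mR"],
                                           np.array([0.0, length]))])
    info = pd.DataFrame({"type": "SNP", "phase": "maternal",
                         "mirror_partner": None}, index=["mL", "mR"])
    from eflmap.matrix import MarkerGenotypeMatrix
    mat = MarkerGenotypeMatrix(
        inds, info, np.column_stack([np.array(calls_left, dtype="<U1"),
                                     np.array(calls_right, dtype="<U1")]))
    return qtlscan.genotype_probabilities(gmap, mat, step_cm=step, kind=kind,
                                          ril_expand_r=ril_expand_r)


def test_prob_one_at_typed_marker():
    grid = _two_marker_grid(["A", "B"], ["A", "B"])
    P = grid.prob_A["LG1"]
    assert P[0, 0] == 1.0 and P[1, 0] == 0.0


def test_prob_half_at_midpoint_between_opposite_flanks():
    grid = _two_marker_grid(["A"], ["B"])
    assert grid.prob_A["LG1"][0, 1] == pytest.approx(0.5)


def test_prob_haldane_midpoint_same_flanks():
    """A…A flanks 20 cM apart, Haldane, no RIL expansion: with
    r = 0.5(1−e^(−0.2)) the conditional P(A) at the midpoint is
    (1−r)²/((1−r)²+r²) ≈ 0.990."""
    r = 0.5 * (1 - np.exp(-0.2))
    expect = (1 - r) ** 2 / ((1 - r) ** 2 + r ** 2)
    grid = _two_marker_grid(["A"], ["A"])
    assert grid.prob_A["LG1"][0, 1] == pytest.approx(expect, abs=1e-12)
    assert expect == pytest.approx(0.990, abs=5e-3)


def test_prob_uninformative_individual_is_half():
    grid = _two_marker_grid(["U"], ["U"])
    assert np.allclose(grid.prob_A["LG1"][0], 0.5)


def test_em_matches_anova_oracle_at_typed_markers(small_population,
                                                  phased_small):
    """With 0/1 weights the EM degenerates to group means; its LOD must
    equal the closed-form ANOVA LOD to 1e−6."""
    mat = phased_small.mapping
    y = simpop.phenotype_means(small_population.phenotype)
    rng = np.random.default_rng(1)
    for j in rng.choice(mat.n_markers, size=15, replace=False):
        col = mat.calls[:, j]
        keep = np.isin(col, ("A", "B"))
        if keep.sum() < 10 or len(set(col[keep])) < 2:
            continue
        scan = qtlscan.em_scan(marker_grid(col[keep]),
                               y.to_numpy()[keep])
        oracle = qtlscan.marker_lod_oracle(col[keep], y.to_numpy()[keep])
        assert scan.lod_max == pytest.approx(oracle, abs=1e-6)


def test_lod_r2_identity_at_typed_marker():
    geno, y = exact_r2_dataset(n=100, r2=0.5)
    scan = qtlscan.em_scan(marker_grid(geno), y)
    assert scan.lod_max == pytest.approx(50 * np.log10(2), abs=1e-9)
    assert scan.peak["r2"] == pytest.approx(0.5, abs=1e-12)
    assert qtlscan.lod_from_r2(100, 0.5) == pytest.approx(15.0514997, abs=1e-6)


def test_oracle_edge_cases():
    y = np.arange(10.0)
    assert qtlscan.marker_lod_oracle(np.array(["A"] * 10), y) == 0.0
    same = np.array(["A", "B"] * 5)
    y_eq = np.tile([1.0, 1.0], 5)
    assert qtlscan.marker_lod_oracle(same, y_eq) == pytest.approx(0.0)
    # permuted phenotype ≈ no signal
    rng = np.random.default_rng(2)
    col = np.array(["A"] * 500 + ["B"] * 500)
    lod = qtlscan.marker_lod_oracle(col, rng.permutation(np.r_[np.zeros(500),
                                                               np.ones(500)]))
    assert lod < 0.5


def test_em_loglik_monotone_in_iterations():
    rng = np.random.default_rng(3)
    w = rng.random(60)
    y = np.r_[rng.normal(0, 1, 30), rng.normal(2, 1, 30)]
    lls = [_em_mixture(w, y[None, :], tol=0.0, max_iter=k)[0][0]
           for k in range(1, 15)]
    assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


def test_scan_rejects_bad_phenotype():
    grid = marker_grid(np.array(["A", "B"] * 5))
    with pytest.raises(ValueError, match="non-finite"):
        qtlscan.em_scan(grid, np.array([np.inf] + [1.0] * 9))
    with pytest.raises(ValueError, match="fewer than four"):
        qtlscan.em_scan(marker_grid(np.array(["A", "B"])), np.array([1.0, 2.0]))


# ---------------------------------------------------------------------------
# permutation thresholds
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def null_setup():
    sim = simpop.simulate_population(
        simpop.MapSpec([("LG1", 100.0)], {"SNP": 1.0}),
        simpop.CrossDesign("F6_SSD", 200), simpop.LocusSpec("LG1", 40.0),
        error_rate=0.0, missing_rate=0.0, ambiguous_phase_fraction=0.0,
        seed=11)
    mat = markerqc.phase_and_mirror(sim.matrix, sim.parents).mapping
    grid = qtlscan.genotype_probabilities(simpop.truth_map(sim), mat)
    rng = np.random.default_rng(3)
    return grid, rng.normal(80, 5, 200)


def test_alpha_one_returns_minimum(null_setup):
    grid, y = null_setup
    thr, mx = qtlscan.permutation_threshold(grid, y, n_perm=100, alpha=1.0,
                                            seed=4)
    assert thr == pytest.approx(float(mx.min()))


def test_single_group_threshold_band(null_setup):
    """One 100 cM group, n=200, normal phenotype: the genome-wide 95%
    threshold sits near 2 LOD (simulation-derived band) and the median
    null maximum stays below 2."""
    grid, y = null_setup
    thr, mx = qtlscan.permutation_threshold(grid, y, n_perm=500, seed=1)
    assert 1.6 < thr < 2.4
    assert float(np.median(mx)) < 2.0


def test_threshold_grows_with_map_length(null_setup):
    grid1, y = null_setup
    sim = simpop.simulate_population(
        simpop.MapSpec([(f"LG{k}", 100.0) for k in range(1, 6)], {"SNP": 1.0}),
        simpop.CrossDesign("F6_SSD", 200), simpop.LocusSpec("LG1", 40.0),
        error_rate=0.0, missing_rate=0.0, ambiguous_phase_fraction=0.0,
        seed=12)
    mat = markerqc.phase_and_mirror(sim.matrix, sim.parents).mapping
    grid5 = qtlscan.genotype_probabilities(simpop.truth_map(sim), mat)
    t1, _ = qtlscan.permutation_threshold(grid1, y, n_perm=200, seed=5)
    t5, _ = qtlscan.permutation_threshold(grid5, y, n_perm=200, seed=5)
    assert t5 > t1


def test_permutation_threshold_requires_enough_perms(null_setup):
    grid, y = null_setup
    with pytest.raises(ValueError, match="100 permutations"):
        qtlscan.permutation_threshold(grid, y, n_perm=50)


# ---------------------------------------------------------------------------
# QTL summary
# ---------------------------------------------------------------------------

def test_summarize_no_qtl_above_threshold(null_setup):
    grid, y = null_setup
    scan = qtlscan.em_scan(grid, y)
    report = qtlscan.summarize_qtl(scan, threshold=scan.lod_max + 1.0,
                                   gmap=None)
    assert report["qtl"] == []


def test_summary_flanking_interval(small_population, phased_small):
    mat = phased_small.mapping
    gmap = simpop.truth_map(small_population)
    # restrict map to markers present after phasing
    keep = set(mat.marker_ids)
    gmap = GeneticMap(groups=[
        LinkageGroup(g.group_id,
                     [m for m in g.markers if m in keep],
                     g.positions_cm[[m in keep for m in g.markers]])
        for g in gmap.groups])
    y = simpop.phenotype_means(small_population.phenotype)
    grid = qtlscan.genotype_probabilities(gmap, mat)
    scan = qtlscan.em_scan(grid, y)
    report = qtlscan.summarize_qtl(scan, threshold=3.0, gmap=gmap,
                                   matrix=mat, phenotype=y)
    assert len(report["qtl"]) == 1
    q = report["qtl"][0]
    assert q["group_id"] == "LG1"
    # peak near the simulated locus at 30 cM
    assert abs(q["position_cM"] - 30.0) <= 3.0
    flanks = q["flanking_markers"]
    assert len(flanks) == 2
    assert flanks[0]["position_cM"] <= q["position_cM"] <= flanks[1]["position_cM"]
    assert q["flank_interval_cM"] == pytest.approx(
        flanks[1]["position_cM"] - flanks[0]["position_cM"])
    assert all(f["lod"] > 3.0 for f in flanks)
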