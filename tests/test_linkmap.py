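"""Map functions, RIL correction, recombination estimation, clustering,
ordering and map assembly."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eflmap import linkmap, markerqc, simpop
from eflmap.matrix import MarkerGenotypeMatrix, default_marker_info

from conftest import matrix_from_columns


# ---------------------------------------------------------------------------
# map functions and RIL correction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kind,r,expected", [
    ("kosambi", 0.0, 0.0),
    ("kosambi", 0.25, 25 * np.log(3)),        # 27.465 cM
    ("haldane", 0.1, -50 * np.log(0.8)),      # 11.157 cM
])
def test_map_function_values(kind, r, expected):
    assert linkmap.map_function(r, "r_to_cM", kind) == pytest.approx(expected)


def test_map_function_round_trip():
    r = np.linspace(0.0, 0.49, 200)
    for kind in ("kosambi", "haldane"):
        d = linkmap.map_function(r, "r_to_cM", kind)
        back = linkmap.map_function(d, "cM_to_r", kind)
        assert np.max(np.abs(back - r)) < 1e-10


def test_kosambi_shorter_than_haldane():
    r = np.linspace(0.01, 0.49, 50)
    assert (linkmap.kosambi_cm(r) < linkmap.haldane_cm(r)).all()


def test_map_function_rejects_invalid():
    with pytest.raises(ValueError):
        linkmap.kosambi_cm(0.5)
    with pytest.raises(ValueError):
        linkmap.haldane_cm(-0.1)
    with pytest.raises(ValueError):
        linkmap.map_function(0.1, "r_to_cM", "carter_falconer")


@pytest.mark.parametrize("R,r", [(0.0, 0.0), (0.5, 0.5), (1 / 6, 0.1)])
def test_ril_correct_inverts_selfing_formula(R, r):
    assert linkmap.ril_correct(R) == pytest.approx(r)


@given(st.floats(0.0, 0.5))
@settings(deadline=None, max_examples=50)
def test_ril_correct_round_trip(r):
    R = float(linkmap.ril_expand(r))
    assert float(linkmap.ril_correct(R)) == pytest.approx(r, abs=1e-12)
    assert R >= r  # observed RIL recombination exceeds meiotic


# ---------------------------------------------------------------------------
# recombination estimation
# ---------------------------------------------------------------------------

def test_estimate_rf_examples():
    a = np.array(["A"] * 50 + ["B"] * 50)
    est = linkmap.estimate_rf(a, a)
    assert est.R_obs == 0.0 and est.r_hat == 0.0
    est = linkmap.estimate_rf(a, np.where(a == "A", "B", "A"))
    assert est.R_obs == 1.0 and est.r_hat == 0.5
    col1 = np.array(["A"] * 181)
    col2 = np.array(["B"] * 15 + ["A"] * 166)
    est = linkmap.estimate_rf(col1, col2)
    assert est.n_informative == 181
    assert est.R_obs == pytest.approx(15 / 181)
    assert est.r_hat == pytest.approx((15 / 181) / (2 * (1 - 15 / 181)))
    assert est.r_hat <= est.R_obs
    with pytest.raises(ValueError, match="no informative"):
        linkmap.estimate_rf(np.array(["U", "A"]), np.array(["A", "U"]))


def test_pairwise_matches_single_estimates(phased_small):
    mat = phased_small.mapping.subset_markers(phased_small.mapping.marker_ids[:12])
    pw = linkmap.pairwise_rf(mat)
    for i in (0, 3, 7):
        for j in (1, 5, 11):
            est = linkmap.estimate_rf(mat.calls[:, i], mat.calls[:, j])
            assert pw["R_obs"][i, j] == pytest.approx(est.R_obs)
            assert pw["P"][i, j] == pytest.approx(est.independence_P)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_clusters_separate_chromosomes(phased_small, small_population):
    clusters = linkmap.cluster_markers(phased_small.mapping)
    mk = small_population.truth["markers"].set_index("marker_id")
    big = [c for c in clusters if len(c) > 5]
    assert len(big) == 3
    for c in big:
        assert mk.loc[c, "group"].nunique() == 1


def test_identical_markers_one_cluster():
    col = ["A"] * 40 + ["B"] * 40
    m = matrix_from_columns({f"m{j}": col for j in range(4)})
    assert len(linkmap.cluster_markers(m)) == 1


def test_mirror_partners_never_co_cluster():
    sim = simpop.simulate_population(
        simpop.MapSpec([("LG1", 50.0)], {"SNP": 1.0}),
        simpop.CrossDesign("F6_SSD", 120), simpop.LocusSpec("LG1", 10.0),
        error_rate=0.0, missing_rate=0.0, ambiguous_phase_fraction=0.4, seed=6)
    mat = markerqc.phase_and_mirror(sim.matrix, sim.parents).mapping
    clusters = linkmap.cluster_markers(mat)
    assign = {m: k for k, c in enumerate(clusters) for m in c}
    info = mat.marker_info
    for mid in info.index[info["mirror_partner"].notna()]:
        assert assign[mid] != assign[info.loc[mid, "mirror_partner"]]


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------

def test_order_three_markers_by_recombination_counts():
    """Adjacent counts 5 (A–B), 9 (A–C), 4 (B–C): order A-B-C costs 9,
    beating A-C-B (13) and B-A-C (14)."""
    D = np.array([[0, 5, 9], [5, 0, 4], [9, 4, 0]], dtype=float)
    m = matrix_from_columns({"A": ["A"], "B": ["A"], "C": ["A"]})
    order = linkmap.order_markers(["A", "B", "C"], m, disc=D)
    assert order in (["A", "B", "C"], ["C", "B", "A"])


def test_order_recovers_truth_noiseless(small_population, phased_small):
    mk = small_population.truth["markers"].set_index("marker_id")
    clusters = linkmap.cluster_markers(phased_small.mapping)
    c = max(clusters, key=len)
    got = linkmap.order_markers(c, phased_small.mapping)
    true = mk.loc[c].sort_values("position_cM").index.tolist()
    # compare up to reversal and up to exchanges of co-segregating
    # markers: check rank correlation of true positions along the order
    pos = mk.loc[got, "position_cM"].to_numpy()
    rho = abs(pd.Series(pos).corr(pd.Series(np.arange(len(pos))), method="spearman"))
    assert rho > 0.99
    assert linkmap.ordering_cost(got, phased_small.mapping) <= \
        linkmap.ordering_cost(true, phased_small.mapping)


def test_two_marker_order_trivial():
    m = matrix_from_columns({"b": ["A", "B"], "a": ["A", "B"]})
    assert sorted(linkmap.order_markers(["b", "a"], m)) == ["a", "b"]


def test_heuristic_matches_exact_small_clusters():
    sim = simpop.simulate_population(
        simpop.MapSpec([("LG1", 30.0)], marker_counts={"LG1": {"SNP": 8}},
                       marker_densities={"SNP": 0.0}),
        simpop.CrossDesign("F6_SSD", 150), simpop.LocusSpec("LG1", 10.0),
        error_rate=0.01, missing_rate=0.05, ambiguous_phase_fraction=0.0,
        seed=5)
    m = markerqc.phase_and_mirror(sim.matrix, sim.parents).mapping
    ids = m.marker_ids
    exact = linkmap.order_markers(ids, m, exact_max=9)
    heur = linkmap.order_markers(ids, m, exact_max=2)
    assert linkmap.ordering_cost(heur, m) == \
        pytest.approx(linkmap.ordering_cost(exact, m))


# ---------------------------------------------------------------------------
# crossover counting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("calls,total,doubles", [
    ("AAAABBBB", 1, 0),
    ("AAABAAAA", 2, 1),
    ("AUUUB", 1, 0),
    ("ABAB", 3, 2),
    ("AAAA", 0, 0),
    ("A", 0, 0),
])
def test_count_crossovers(calls, total, doubles):
    assert linkmap.count_crossovers(np.array(list(calls))) == (total, doubles)


# ---------------------------------------------------------------------------
# map assembly
# ---------------------------------------------------------------------------

def test_assemble_drops_small_and_merges_duplicates():
    rng = np.random.default_rng(0)
    cols = {f"g{j:02d}": list(rng.choice(["A", "B"], size=30))
            for j in range(20)}
    cols |= {f"s{j}": list(rng.choice(["A", "B"], size=30)) for j in range(5)}
    m = matrix_from_columns(cols)
    # duplicate of individual 0 differing only at an unmapped marker
    calls = np.vstack([m.calls, m.calls[0]])
    j_s0 = m.marker_info.index.get_loc("s0")
    calls[-1, j_s0] = "B" if calls[-1, j_s0] == "A" else "A"
    m2 = MarkerGenotypeMatrix(m.individuals + ["dup"],
                              m.marker_info.copy(), calls)
    clusters = [[f"g{j:02d}" for j in range(20)],
                [f"s{j}" for j in range(5)]]
    gmap, work = linkmap.assemble_map(clusters, m2, similarity_merge=0.98)
    assert len(gmap.groups) == 1            # 5-marker cluster discarded
    actions = [e["action"] for e in gmap.provenance]
    assert "drop_small_cluster" in actions
    assert "merge_individuals" in actions
    assert any("+dup" in i for i in work.individuals)
    assert work.n_individuals == 30
    # consensus keeps the unanimous calls of the merged pair
    cons = work.calls[[("+dup" in i) for i in work.individuals].index(True)]
    orig = m2.calls[0][[m2.marker_info.index.get_loc(mk)
                        for mk in work.marker_ids]]
    assert (cons == orig).all()


def test_assemble_raises_when_everything_pruned():
    m = matrix_from_columns({"a": ["A", "B"], "b": ["A", "B"]})
    with pytest.raises(ValueError, match="pruned"):
        linkmap.assemble_map([["a", "b"]], m, min_cluster_size=5)


def test_map_recovery_three_chromosomes():
    """Error-free simulation at the study scale: assembled group count
    equals the simulated chromosome count, total length within 15% and
    per-group lengths within 25% (adjacent-pair estimation variance)."""
    ms = simpop.MapSpec([("LG1", 100.0), ("LG2", 100.0), ("LG3", 100.0)],
                        {"SNP": 1.0, "PAV": 1.0})
    for seed in (1, 2):
        sim = simpop.simulate_population(
            ms, simpop.CrossDesign("F6_SSD", 185),
            simpop.LocusSpec("LG1", 40.0), error_rate=0.0, missing_rate=0.05,
            ambiguous_phase_fraction=0.0, seed=seed)
        mat = markerqc.phase_and_mirror(sim.matrix, sim.parents).mapping
        gmap, _ = linkmap.build_map(mat)
        assert len(gmap.groups) == 3
        assert abs(gmap.total_cm - 300.0) / 300.0 < 0.15
        for g in gmap.groups:
            assert abs(g.length_cm - 100.0) / 100.0 < 0.25
            assert np.all(np.diff(g.positions_cm) >= 0)


def test_mirror_only_groups_dropped():
    sim = simpop.simulate_population(
        simpop.MapSpec([("LG1", 60.0)], {"SNP": 1.0}),
        simpop.CrossDesign("F6_SSD", 150), simpop.LocusSpec("LG1", 20.0),
        error_rate=0.0, missing_rate=0.0, ambiguous_phase_fraction=0.3,
        seed=12)
    mat = markerqc.phase_and_mirror(sim.matrix, sim.parents).mapping
    gmap, _ = linkmap.build_map(mat)
    assert len(gmap.groups) == 1
    placed = set(gmap.groups[0].markers)
    # every ambiguous marker is represented by exactly one of its phases
    info = mat.marker_info
    for mid in info.index[info["mirror_partner"].notna()]:
        partner = info.loc[mid, "mirror_partner"]
        assert (mid in placed) ^ (partner in placed)
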