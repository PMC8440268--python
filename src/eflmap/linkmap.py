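"""Genetic-map construction for selfed RIL populations.

Implements the map functions (Kosambi, Haldane), the selfing-RIL
correction between the meiotic recombination fraction r and the observed
RIL recombination fraction R = 2r/(1+2r), pairwise recombination
estimation with an independence test, threshold clustering into linkage
groups, recombination-count marker ordering, and the pruning rules used
to assemble the final map (small-cluster and mirror-only-group removal,
near-duplicate individual merging, high-missingness / double-crossover
individual removal).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import chi2 as chi2_dist

from .matrix import MarkerGenotypeMatrix

# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def kosambi_cm(r):
    """Kosambi map distance (cM) for recombination fraction ``r``.

    d = 25·ln((1+2r)/(1−2r)); accounts for positive crossover
    interference, so distances are shorter than Haldane's for the same r.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    return 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))


def kosambi_r(d):
    """Inverse Kosambi: r = 0.5·tanh(d/50)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    return 0.5 * np.tanh(d / 50.0)


def haldane_cm(r):
    """Haldane map distance (cM), no interference: d = −50·ln(1−2r)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    return -50.0 * np.log(1 - 2 * r)


def haldane_r(d):
    """Inverse Haldane: r = 0.5·(1−e^(−d/50))."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    return 0.5 * (1 - np.exp(-d / 50.0))


_MAP_FUNCTIONS = {
    ("kosambi", "r_to_cM"): kosambi_cm,
    ("kosambi", "cM_to_r"): kosambi_r,
    ("haldane", "r_to_cM"): haldane_cm,
    ("haldane", "cM_to_r"): haldane_r,
}


def map_function(value, direction: str, kind: str = "kosambi"):
    """Convert between recombination fraction and cM (``r_to_cM`` /
    ``cM_to_r``) under the named map function."""
    try:
        fn = _MAP_FUNCTIONS[(kind, direction)]
    except KeyError:
        raise ValueError(f"unknown map function/direction: {kind!r}, {direction!r}")
    return fn(value)


# ---------------------------------------------------------------------------
# RIL correction
# ---------------------------------------------------------------------------

def ril_correct(R_obs, scheme: str = "selfing_F_inf"):
    """Meiotic recombination fraction r from the observed fraction R of
    recombinant RIL genotypes.

    For fully inbred selfing RILs R = 2r/(1+2r) (recombinants accumulate
    over successive selfing meioses), hence r = R/(2(1−R)).
    """
    if scheme != "selfing_F_inf":
        raise ValueError(f"unknown RIL correction scheme {scheme!r}")
    R = np.asarray(R_obs, dtype=float)
    if np.any((R < 0) | (R > 0.5)):
        raise ValueError("observed RIL recombination fraction must lie in [0, 0.5]")
    return R / (2.0 * (1.0 - R))


def ril_expand(r):
    """Observed RIL recombination fraction R = 2r/(1+2r) from meiotic r."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


# ---------------------------------------------------------------------------
# pairwise recombination estimation
# ---------------------------------------------------------------------------

@dataclass
class RecombEstimate:
    r_hat: float
    R_obs: float
    n_informative: int
    independence_P: float


def _chi2_2x2(n11, n12, n21, n22):
    """Pearson chi-square (no continuity correction) for a 2×2 table;
    degenerate margins give chi2=0, P=1. Vectorised over arrays."""
    n11 = np.asarray(n11, dtype=float)
    n12 = np.asarray(n12, dtype=float)
    n21 = np.asarray(n21, dtype=float)
    n22 = np.asarray(n22, dtype=float)
    n = n11 + n12 + n21 + n22
    r1 = n11 + n12
    r2 = n21 + n22
    c1 = n11 + n21
    c2 = n12 + n22
    denom = r1 * r2 * c1 * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, n * (n11 * n22 - n12 * n21) ** 2 / denom, 0.0)
    p = chi2_dist.sf(stat, 1)
    return stat, np.where(denom > 0, p, 1.0)


def estimate_rf(col1: np.ndarray, col2: np.ndarray) -> RecombEstimate:
    """Recombination estimate between two phased marker columns.

    R_obs is the discordant fraction among pairs where both calls are
    homozygous (A/B); the independence P value comes from the 2×2
    chi-square over joint A/B classes; r_hat applies the selfing-RIL
    correction to R_obs (capped at 0.5).
    """
    a1 = np.asarray(col1)
    a2 = np.asarray(col2)
    m1 = np.isin(a1, ("A", "B"))
    m2 = np.isin(a2, ("A", "B"))
    both = m1 & m2
    n_inf = int(both.sum())
    if n_inf == 0:
        raise ValueError("no informative pairs between the two markers")
    x = a1[both] == "A"
    y = a2[both] == "A"
    n11 = int(np.sum(x & y))
    n12 = int(np.sum(x & ~y))
    n21 = int(np.sum(~x & y))
    n22 = int(np.sum(~x & ~y))
    R = (n12 + n21) / n_inf
    _, p = _chi2_2x2(n11, n12, n21, n22)
    r_hat = float(ril_correct(min(R, 0.5)))
    return RecombEstimate(r_hat=r_hat, R_obs=R, n_informative=n_inf,
                          independence_P=float(p))


def pairwise_rf(matrix: MarkerGenotypeMatrix):
    """All-pairs recombination estimates as dense matrices.

    Returns dict of (n_markers × n_markers) arrays: ``R_obs``, ``r_hat``,
    ``P`` (independence), ``n_informative`` and ``disc`` (absolute
    discordant-pair counts, used by the ordering objective).
    """
    X = matrix.encoded().astype(np.float64)
    P = (X > 0).astype(np.float64)   # A indicator
    Q = (X < 0).astype(np.float64)   # B indicator
    n11 = P.T @ P
    n12 = P.T @ Q
    n21 = Q.T @ P
    n22 = Q.T @ Q
    inf = n11 + n12 + n21 + n22
    disc = n12 + n21
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(inf > 0, disc / inf, 0.5)
    chi2, pval = _chi2_2x2(n11, n12, n21, n22)
    r_hat = ril_correct(np.minimum(R, 0.5))
    return {"R_obs": R, "r_hat": r_hat, "P": pval, "chi2": chi2,
            "n_informative": inf, "disc": disc}


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_markers(matrix: MarkerGenotypeMatrix, p_threshold: float = 1e-18,
                    max_cm: float = 15.0, pw: dict | None = None) -> list[list[str]]:
    """Single-linkage linkage-group clustering.

    Two markers are joined when their independence P value is ≤
    ``p_threshold`` AND the Kosambi distance of their corrected
    recombination fraction is ≤ ``max_cm``. Returns connected components
    (largest first); singletons are allowed. Mirror partners of one
    ambiguous marker are perfectly anti-correlated (R_obs = 1 → r_hat
    capped at 0.5, distance unbounded) so they never share an edge.
    """
    if pw is None:
        pw = pairwise_rf(matrix)
    r = np.minimum(pw["r_hat"], 0.49999999)
    dist = kosambi_cm(r)
    adj = (pw["P"] <= p_threshold) & (dist <= max_cm)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(sparse.csr_matrix(adj), directed=False)
    ids = np.asarray(matrix.marker_ids)
    clusters = [list(ids[labels == k]) for k in range(n_comp)]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------

def _order_cost(order: list[int], D: np.ndarray) -> float:
    return float(sum(D[order[i], order[i + 1]] for i in range(len(order) - 1)))


def _spectral_start(D: np.ndarray) -> list[int]:
    """Seriation start: order markers along the first classical-MDS
    coordinate of their pairwise map distances."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    _, vecs = np.linalg.eigh(B)
    return list(np.argsort(vecs[:, -1], kind="stable"))


def _greedy_start(D: np.ndarray) -> list[int]:
    n = D.shape[0]
    # start at the marker whose farthest neighbour is farthest (a chain end)
    start = int(np.argmax(D.sum(axis=1)))
    order = [start]
    left = set(range(n)) - {start}
    while left:
        last = order[-1]
        nxt = min(left, key=lambda j: (D[last, j], j))
        order.append(nxt)
        left.remove(nxt)
    return order


def _improve(order: list[int], D: np.ndarray) -> list[int]:
    """2-opt segment reversals plus window-ripple reinsertions until no
    move lowers the adjacent recombination-count objective. Move deltas
    are evaluated in O(1) from the (symmetric) pairwise count matrix."""
    n = len(order)
    o = list(order)
    eps = 1e-12

    def two_opt_pass() -> bool:
        applied = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                if i == 0 and j == n - 1:
                    continue  # full reversal: no cost change
                delta = 0.0
                if i > 0:
                    delta += D[o[i - 1], o[j]] - D[o[i - 1], o[i]]
                if j < n - 1:
                    delta += D[o[i], o[j + 1]] - D[o[j], o[j + 1]]
                if delta < -eps:
                    o[i:j + 1] = o[i:j + 1][::-1]
                    applied = True
        return applied

    def ripple_once() -> bool:
        for w in (1, 2, 3):
            if w >= n:
                break
            for i in range(n - w + 1):
                seg = o[i:i + w]
                rest = o[:i] + o[i + w:]
                gain = 0.0
                if i > 0:
                    gain -= D[o[i - 1], seg[0]]
                if i + w < n:
                    gain -= D[seg[-1], o[i + w]]
                if 0 < i and i + w < n:
                    gain += D[o[i - 1], o[i + w]]
                m = len(rest)
                for j in range(m + 1):
                    bridge = D[rest[j - 1], rest[j]] if 0 < j < m else 0.0
                    for s in (seg, seg[::-1]):
                        delta = gain - bridge
                        if j > 0:
                            delta += D[rest[j - 1], s[0]]
                        if j < m:
                            delta += D[s[-1], rest[j]]
                        if delta < -eps:
                            o[:] = rest[:j] + s + rest[j:]
                            return True
        return False

    improved = True
    while improved:
        improved = False
        while two_opt_pass():
            improved = True
        while ripple_once():
            improved = True
    return o


def order_markers(cluster: list[str], matrix: MarkerGenotypeMatrix,
                  disc: np.ndarray | None = None,
                  exact_max: int = 9) -> list[str]:
    """Order markers in a cluster by minimising total observed
    recombination events between adjacent markers.

    Clusters of ``exact_max`` or fewer markers are solved by brute-force
    enumeration; larger clusters refine two starts — greedy
    nearest-neighbour and a spectral seriation of the pairwise map
    distances — by 2-opt and window-ripple moves, keeping the
    lower-cost result. The returned orientation
    places the lowest marker id in the first half (maps are only defined
    up to reversal). Ties between equal-cost orders break by marker id.
    """
    if len(cluster) <= 1:
        return list(cluster)
    sub = matrix.subset_markers(cluster)
    pw = pairwise_rf(sub) if disc is None else None
    if disc is None:
        disc = pw["disc"]
    n = len(cluster)
    if n <= exact_max:
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(n)):
            if perm[0] > perm[-1]:
                continue  # skip reversals
            c = _order_cost(list(perm), disc)
            key = tuple(cluster[i] for i in perm)
            if c < best_cost - 1e-12 or (abs(c - best_cost) <= 1e-12 and
                                         best is not None and key < best):
                best, best_cost = key, c
        order_ids = list(best)
    else:
        if pw is None:
            pw = pairwise_rf(sub)
        dist_cm = kosambi_cm(np.minimum(pw["r_hat"], 0.49))
        starts = [_greedy_start(disc), _spectral_start(dist_cm)]
        cands = []
        for s in starts:
            o = _improve(s, disc)
            cands.append((_order_cost(o, disc), tuple(cluster[i] for i in o)))
        cands.sort()
        order_ids = list(cands[0][1])
    i_min = order_ids.index(min(order_ids))
    if i_min > (len(order_ids) - 1) / 2:
        order_ids.reverse()
    return order_ids


def ordering_cost(order: list[str], matrix: MarkerGenotypeMatrix) -> float:
    """Total adjacent discordant-pair (recombination event) count of an
    order; the objective minimised by :func:`order_markers`."""
    sub = matrix.subset_markers(order)
    disc = pairwise_rf(sub)["disc"]
    return _order_cost(list(range(len(order))), disc)


# ---------------------------------------------------------------------------
# crossover counting
# ---------------------------------------------------------------------------

def count_crossovers(calls: np.ndarray, k: int = 1) -> tuple[int, int]:
    """(total crossovers, double crossovers) for one individual's calls
    along an ordered linkage group.

    A crossover is a phase change between adjacent informative (A/B)
    calls, skipping missing. A double crossover is a run of at most ``k``
    informative calls flanked on both sides by the opposite phase.
    """
    arr = np.asarray(calls)
    inf = arr[np.isin(arr, ("A", "B"))]
    if inf.size < 2:
        return 0, 0
    x = (inf == "A").astype(np.int8)
    changes = np.nonzero(np.diff(x) != 0)[0]
    total = int(changes.size)
    # run lengths
    doubles = 0
    run_starts = np.concatenate(([0], changes + 1))
    run_ends = np.concatenate((changes, [inf.size - 1]))
    for s, e in zip(run_starts[1:-1], run_ends[1:-1]):  # interior runs only
        if e - s + 1 <= k:
            doubles += 1
    return total, doubles


# ---------------------------------------------------------------------------
# map assembly
# ---------------------------------------------------------------------------

@dataclass
class LinkageGroup:
    group_id: str
    markers: list[str]
    positions_cm: np.ndarray

    @property
    def length_cm(self) -> float:
        return float(self.positions_cm[-1]) if len(self.positions_cm) else 0.0


@dataclass
class GeneticMap:
    groups: list[LinkageGroup]
    provenance: list[dict] = field(default_factory=list)

    @property
    def total_cm(self) -> float:
        return float(sum(g.length_cm for g in self.groups))

    @property
    def n_markers(self) -> int:
        return sum(len(g.markers) for g in self.groups)

    def group(self, group_id: str) -> LinkageGroup:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(group_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group_id": g.group_id, "marker_id": m, "position_cM": p}
            for g in self.groups
            for m, p in zip(g.markers, g.positions_cm)
        ]
        return pd.DataFrame(rows, columns=["group_id", "marker_id", "position_cM"])


def _identity_matrix(X: np.ndarray):
    """Pairwise individual identity over cells where both calls are
    informative. X is the signed encoding."""
    inf = (X != 0).astype(np.float64)
    Xf = X.astype(np.float64)
    agree_minus_disagree = Xf @ Xf.T
    both = inf @ inf.T
    with np.errstate(divide="ignore", invalid="ignore"):
        ident = np.where(both > 0, (both + agree_minus_disagree) / (2 * both), 0.0)
    return ident, both


def _consensus(rows: np.ndarray) -> np.ndarray:
    """Cell-wise consensus of near-duplicate individuals: unanimous
    informative call kept, disagreement or all-missing → U."""
    out = np.full(rows.shape[1], "U", dtype="<U1")
    for code in ("A", "B", "H"):
        is_code = rows == code
        other = ~is_code & (rows != "U")
        out[np.where(is_code.any(axis=0) & ~other.any(axis=0))] = code
    return out


def adjacent_distances(order: list[str], matrix: MarkerGenotypeMatrix,
                       kind: str = "kosambi") -> np.ndarray:
    """cM distances between adjacent markers, from pairwise corrected
    recombination fractions."""
    d = np.zeros(len(order) - 1)
    for i in range(len(order) - 1):
        est = estimate_rf(matrix.column(order[i]), matrix.column(order[i + 1]))
        d[i] = map_function(min(est.r_hat, 0.49999999), "r_to_cM", kind)
    return d


def assemble_map(clusters: list[list[str]], matrix: MarkerGenotypeMatrix,
                 min_cluster_size: int = 5, similarity_merge: float = 0.98,
                 max_missing_per_individual: int | None = 650,
                 max_doubles_per_individual: int | None = 28,
                 kind: str = "kosambi",
                 exact_max: int = 9) -> tuple[GeneticMap, MarkerGenotypeMatrix]:
    """Assemble a genetic map from marker clusters, applying the pruning
    rules: order each cluster; discard clusters with ≤ ``min_cluster_size``
    markers; discard groups made exclusively of mirror markers whose
    partners placed in larger groups; merge individuals with ≥
    ``similarity_merge`` genotype identity into a consensus; remove
    individuals exceeding the missing-call or double-crossover
    thresholds; then assign cumulative cM positions from adjacent-pair
    corrected recombination fractions. Every pruning action is logged in
    the map's provenance. Returns the map and the (possibly pruned)
    matrix used for distances.

    Raises ``ValueError`` if every cluster is pruned away.
    """
    log: list[dict] = []
    ordered = [order_markers(c, matrix, exact_max=exact_max) for c in clusters]

    kept = []
    for c in ordered:
        if len(c) <= min_cluster_size:
            log.append({"action": "drop_small_cluster", "markers": list(c)})
        else:
            kept.append(c)

    # mirror-only groups whose partners all mapped in larger groups
    placement = {m: gi for gi, c in enumerate(kept) for m in c}
    kept2 = []
    for gi, c in enumerate(kept):
        partners = [matrix.marker_info.loc[m, "mirror_partner"] for m in c]
        if all(p is not None and not (isinstance(p, float) and np.isnan(p)) for p in partners):
            homes = [placement.get(p) for p in partners]
            if all(h is not None and h != gi and len(kept[h]) > len(c) for h in homes):
                log.append({"action": "drop_mirror_only_group", "markers": list(c)})
                continue
        kept2.append(c)
    if not kept2:
        raise ValueError("all clusters pruned; no linkage groups remain")

    # --- individual-level QC on the matrix restricted to mapped markers
    mapped = [m for c in kept2 for m in c]
    work = matrix.subset_markers(mapped)

    ident, both = _identity_matrix(work.encoded())
    n = work.n_individuals
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if both[i, j] > 0 and ident[i, j] >= similarity_merge:
                parent[find(j)] = find(i)
    groups_of: dict[int, list[int]] = {}
    for i in range(n):
        groups_of.setdefault(find(i), []).append(i)

    new_ids, new_rows = [], []
    for root, members in sorted(groups_of.items()):
        if len(members) == 1:
            new_ids.append(work.individuals[members[0]])
            new_rows.append(work.calls[members[0]])
        else:
            names = [work.individuals[i] for i in members]
            cid = "+".join(names)
            log.append({"action": "merge_individuals", "members": names,
                        "consensus": cid})
            new_ids.append(cid)
            new_rows.append(_consensus(work.calls[members]))
    work = MarkerGenotypeMatrix(new_ids, work.marker_info.copy(), np.array(new_rows))

    # missingness / double-crossover removal
    drop = set()
    miss = (work.calls == "U").sum(axis=1)
    if max_missing_per_individual is not None:
        for i in np.nonzero(miss > max_missing_per_individual)[0]:
            drop.add(work.individuals[i])
            log.append({"action": "drop_individual_missing",
                        "individual": work.individuals[i], "n_missing": int(miss[i])})
    if max_doubles_per_individual is not None:
        col_of = {m: k for k, m in enumerate(work.marker_ids)}
        for i, ind in enumerate(work.individuals):
            doubles = 0
            for c in kept2:
                _, d = count_crossovers(work.calls[i, [col_of[m] for m in c]])
                doubles += d
            if doubles > max_doubles_per_individual and ind not in drop:
                drop.add(ind)
                log.append({"action": "drop_individual_doubles",
                            "individual": ind, "n_doubles": doubles})
    if drop:
        work = work.subset_individuals([i for i in work.individuals if i not in drop])
    if work.n_individuals < 2:
        raise ValueError("fewer than two individuals remain after pruning")

    groups = []
    for gi, c in enumerate(kept2):
        d = adjacent_distances(c, work, kind=kind)
        pos = np.concatenate(([0.0], np.cumsum(d)))
        groups.append(LinkageGroup(group_id=f"LG{gi + 1:02d}", markers=list(c),
                                   positions_cm=pos))
    return GeneticMap(groups=groups, provenance=log), work


def build_map(matrix: MarkerGenotypeMatrix, p_threshold: float = 1e-18,
              max_cm: float = 15.0, **assemble_kwargs):
    """Cluster then assemble in one call."""
    clusters = cluster_markers(matrix, p_threshold=p_threshold, max_cm=max_cm)
    return assemble_map(clusters, matrix, **assemble_kwargs)
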