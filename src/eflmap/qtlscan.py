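"""Single-QTL interval mapping by EM for two-genotype RIL populations.

At each scan position the phenotype is modelled as a two-component
normal mixture with component means mu_A, mu_B, a common residual sigma,
and per-individual mixing weights fixed to the probability of carrying
the homozygous maternal genotype given the flanking informative markers
(classic interval mapping). LOD = log10(L1/L0) against a single-normal
null; the proportion of phenotypic variance explained is
R2 = 1 − sigma2_full/sigma2_null. At a fully informative marker the EM
degenerates to a two-group comparison and the closed-form identity
LOD = (n/2)·log10(1/(1−R2)) holds.

Genome-wide significance thresholds come from permutation testing: the
phenotype is permuted against the genotypes, the genome-wide maximum LOD
recorded per permutation, and the empirical (1−alpha) quantile returned.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkmap import map_function, ril_expand
from .matrix import MarkerGenotypeMatrix

_LN10 = np.log(10.0)
_MIN_VAR = 1e-12


# ---------------------------------------------------------------------------
# genotype probabilities
# ---------------------------------------------------------------------------

@dataclass
class GenoProbGrid:
    """P(homozygous maternal) on a cM grid, per linkage group.

    ``positions`` maps group_id → cM grid; ``prob_A`` maps group_id →
    (n_individuals × n_positions) array.
    """
    individuals: list[str]
    positions: dict[str, np.ndarray]
    prob_A: dict[str, np.ndarray]

    @property
    def group_ids(self) -> list[str]:
        return list(self.positions)

    def stacked(self) -> tuple[pd.DataFrame, np.ndarray]:
        """(frame of group/position rows, n_ind × n_total prob matrix)."""
        rows = []
        mats = []
        for g in self.positions:
            for p in self.positions[g]:
                rows.append({"group_id": g, "position_cM": float(p)})
            mats.append(self.prob_A[g])
        return pd.DataFrame(rows), np.concatenate(mats, axis=1)


def genotype_probabilities(gmap, matrix: MarkerGenotypeMatrix,
                           step_cm: float = 1.0, kind: str = "kosambi",
                           ril_expand_r: bool = True) -> GenoProbGrid:
    """Conditional P(A) along each linkage group.

    The genotype process along a RIL chromosome is a two-state Markov
    chain; the switch probability across an interval of d cM is the
    map-function inverse r(d), expanded to the RIL-observed fraction
    R = 2r/(1+2r) when ``ril_expand_r`` (map distances are meiotic while
    the data are inbred-line genotypes). Positions beyond the terminal
    informative markers condition on the single nearest marker;
    individuals with no informative marker on a group get 0.5
    everywhere. At a typed informative marker the probability is exactly
    0 or 1.
    """
    def switch(d):
        r = map_function(np.minimum(np.asarray(d, float), 1e6), "cM_to_r", kind)
        return ril_expand(r) if ril_expand_r else r

    positions: dict[str, np.ndarray] = {}
    probs: dict[str, np.ndarray] = {}
    n_ind = matrix.n_individuals
    col_of = {m: j for j, m in enumerate(matrix.marker_ids)}
    enc = matrix.encoded()

    for g in gmap.groups:
        L = g.length_cm
        grid = np.arange(0.0, L + step_cm * 0.5, step_cm)
        if grid[-1] < L - 1e-9:
            grid = np.append(grid, L)
        mpos = np.asarray(g.positions_cm, dtype=float)
        cols = np.array([col_of[m] for m in g.markers])
        P = np.full((n_ind, grid.size), 0.5)
        for i in range(n_ind):
            calls = enc[i, cols]
            inf = calls != 0
            if not inf.any():
                continue
            ipos = mpos[inf]
            istate = calls[inf] > 0  # True = A
            # nearest informative markers left/right of each grid point
            ri = np.searchsorted(ipos, grid, side="left")
            li = np.searchsorted(ipos, grid, side="right") - 1
            has_l = li >= 0
            has_r = ri < ipos.size
            pA = np.full(grid.size, 0.5)
            # left contribution
            wl = np.ones(grid.size)
            wr = np.ones(grid.size)
            vl = np.ones(grid.size)
            vr = np.ones(grid.size)
            if has_l.any():
                tl = switch(grid[has_l] - ipos[li[has_l]])
                sl = istate[li[has_l]]
                wl[has_l] = np.where(sl, 1 - tl, tl)       # P(pos=A | left)
                vl[has_l] = np.where(sl, tl, 1 - tl)       # P(pos=B | left)
            if has_r.any():
                tr = switch(ipos[ri[has_r]] - grid[has_r])
                sr = istate[ri[has_r]]
                wr[has_r] = np.where(sr, 1 - tr, tr)       # P(right | pos=A)
                vr[has_r] = np.where(sr, tr, 1 - tr)       # P(right | pos=B)
            num = wl * wr
            den = num + vl * vr
            ok = has_l | has_r
            pA[ok] = num[ok] / den[ok]
            P[i] = pA
        positions[g.group_id] = grid
        probs[g.group_id] = P
    return GenoProbGrid(list(matrix.individuals), positions, probs)


# ---------------------------------------------------------------------------
# EM mixture fit
# ---------------------------------------------------------------------------

def _null_loglik(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-normal MLE log-likelihood per row of Y (P × n)."""
    n = Y.shape[1]
    var0 = Y.var(axis=1)
    var0 = np.maximum(var0, _MIN_VAR)
    ll0 = -0.5 * n * (np.log(2 * np.pi * var0) + 1.0)
    return ll0, var0


def _em_mixture(w: np.ndarray, Y: np.ndarray, tol: float = 1e-6,
                max_iter: int = 200):
    """EM fit of the fixed-weight two-normal mixture, vectorised over the
    rows of Y (each row an independent phenotype vector, e.g. one
    permutation).

    Returns (loglik (P,), mu_A (P,), mu_B (P,), sigma2 (P,), converged (P,)).
    The log-likelihood is non-decreasing across iterations.
    """
    w = np.asarray(w, dtype=float)[None, :]         # (1, n)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))   # (P, n)
    P, n = Y.shape
    sw = w.sum()
    swc = n - sw
    # init: weight-stratified means; fall back to overall mean for empty class
    ybar = Y.mean(axis=1, keepdims=True)
    muA = (Y * w).sum(axis=1, keepdims=True) / sw if sw > 1e-9 else ybar.copy()
    muB = (Y * (1 - w)).sum(axis=1, keepdims=True) / swc if swc > 1e-9 else ybar.copy()
    var = np.maximum(Y.var(axis=1, keepdims=True), _MIN_VAR)
    ll = np.full(P, -np.inf)
    done = np.zeros(P, dtype=bool)
    for _ in range(max_iter):
        dA = Y - muA
        dB = Y - muB
        # responsibilities (common sigma cancels in the ratio)
        logA = -0.5 * dA ** 2 / var
        logB = -0.5 * dB ** 2 / var
        m = np.maximum(logA, logB)
        fA = w * np.exp(logA - m)
        fB = (1 - w) * np.exp(logB - m)
        tot = fA + fB
        new_ll = (np.log(tot) + m).sum(axis=1) \
            - 0.5 * n * np.log(2 * np.pi * var[:, 0])
        gamma = fA / tot
        gA = gamma.sum(axis=1, keepdims=True)
        gB = n - gA
        muA = np.where(gA > 1e-9, (gamma * Y).sum(axis=1, keepdims=True) /
                       np.maximum(gA, 1e-9), muA)
        muB = np.where(gB > 1e-9, ((1 - gamma) * Y).sum(axis=1, keepdims=True) /
                       np.maximum(gB, 1e-9), muB)
        var = (gamma * (Y - muA) ** 2 + (1 - gamma) * (Y - muB) ** 2).sum(
            axis=1, keepdims=True) / n
        var = np.maximum(var, _MIN_VAR)
        delta = new_ll - ll
        done |= np.abs(delta) < tol
        ll = new_ll
        if done.all():
            break
    return ll, muA[:, 0], muB[:, 0], var[:, 0], done


@dataclass
class LODScan:
    frame: pd.DataFrame               # group_id, position_cM, lod
    peak: dict                        # position, LOD_max, R2, class means, sd
    individuals: list[str]
    n_phenotyped: int
    threshold: float | None = None
    n_permutations: int | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def lod_max(self) -> float:
        return float(self.peak["lod"])


def _align_phenotype(individuals: list[str], phenotype) -> np.ndarray:
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(individuals).to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
        if y.shape[0] != len(individuals):
            raise ValueError("phenotype length does not match individuals")
    return y


def em_scan(grid: GenoProbGrid, phenotype, tol: float = 1e-6,
            max_iter: int = 200) -> LODScan:
    """Interval-mapping LOD scan over every grid position.

    ``phenotype`` is a per-individual mean (Series indexed by individual
    id, or array aligned to the grid's individuals). Individuals with
    missing phenotype are dropped. Non-finite infinite values raise.
    """
    y = _align_phenotype(grid.individuals, phenotype)
    keep = ~np.isnan(y)
    if np.isinf(y[keep]).any():
        raise ValueError("non-finite phenotype values")
    y = y[keep]
    n = y.size
    if n < 4:
        raise ValueError("fewer than four phenotyped individuals")
    ll0, var0 = _null_loglik(y[None, :])
    rows = []
    warnings: list[str] = []
    best = None
    for g, gridpos in grid.positions.items():
        W = grid.prob_A[g][keep]
        for k, pos in enumerate(gridpos):
            ll1, muA, muB, var, conv = _em_mixture(W[:, k], y[None, :],
                                                   tol=tol, max_iter=max_iter)
            if not conv[0]:
                warnings.append(f"EM not converged at {g}:{pos:g} cM")
            lod = max(0.0, float((ll1[0] - ll0[0]) / _LN10))
            rows.append({"group_id": g, "position_cM": float(pos), "lod": lod})
            if best is None or lod > best["lod"]:
                r2 = max(0.0, 1.0 - float(var[0]) / float(var0[0]))
                best = {"group_id": g, "position_cM": float(pos), "lod": lod,
                        "mu_A": float(muA[0]), "mu_B": float(muB[0]),
                        "sigma": float(np.sqrt(var[0])), "r2": r2}
    return LODScan(frame=pd.DataFrame(rows), peak=best,
                   individuals=[i for i, k in zip(grid.individuals, keep) if k],
                   n_phenotyped=n, warnings=warnings)


# ---------------------------------------------------------------------------
# closed-form oracle at a typed marker
# ---------------------------------------------------------------------------

def marker_lod_oracle(genotype_column, phenotype) -> float:
    """Closed-form two-group LOD from analysis-of-variance residual sums
    of squares at a fully typed marker: LOD = (n/2)·log10(RSS0/RSS1).

    Used as the independent check of the EM scan (the EM degenerates to
    group means when every weight is 0/1). Returns 0 when either
    genotype class is empty.
    """
    calls = np.asarray(genotype_column)
    y = np.asarray(phenotype, dtype=float)
    ok = np.isin(calls, ("A", "B")) & ~np.isnan(y)
    calls, y = calls[ok], y[ok]
    n = y.size
    if n == 0:
        return 0.0
    a = calls == "A"
    if a.all() or (~a).all():
        return 0.0
    rss0 = float(((y - y.mean()) ** 2).sum())
    rss1 = float(((y[a] - y[a].mean()) ** 2).sum() +
                 ((y[~a] - y[~a].mean()) ** 2).sum())
    if rss0 <= _MIN_VAR * n:
        return 0.0
    rss1 = max(rss1, _MIN_VAR * n)
    return (n / 2.0) * np.log10(rss0 / rss1)


def lod_from_r2(n: int, r2: float) -> float:
    """Gaussian single-QTL identity LOD = (n/2)·log10(1/(1−R2)) at a
    fully informative marker."""
    if not 0 <= r2 < 1:
        raise ValueError("R2 must lie in [0, 1)")
    return (n / 2.0) * np.log10(1.0 / (1.0 - r2))


# ---------------------------------------------------------------------------
# permutation threshold
# ---------------------------------------------------------------------------

def permutation_threshold(grid: GenoProbGrid, phenotype, n_perm: int = 1000,
                          alpha: float = 0.05, seed: int | None = None,
                          tol: float = 1e-4, max_iter: int = 200):
    """Genome-wide empirical LOD threshold at level ``alpha``.

    Permutes the phenotype against the genotype grid ``n_perm`` times,
    scans every position, and returns the (1−alpha) type-7 quantile of
    the per-permutation genome-wide maximum LOD, plus the max-LOD
    sample. The EM at each position is vectorised across permutations.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    y = _align_phenotype(grid.individuals, phenotype)
    keep = ~np.isnan(y)
    y = y[keep]
    rng = np.random.default_rng(seed)
    Y = np.stack([rng.permutation(y) for _ in range(n_perm)])
    ll0, _ = _null_loglik(Y)
    maxlod = np.zeros(n_perm)
    for g in grid.positions:
        W = grid.prob_A[g][keep]
        for k in range(grid.positions[g].size):
            ll1, *_ = _em_mixture(W[:, k], Y, tol=tol, max_iter=max_iter)
            np.maximum(maxlod, (ll1 - ll0) / _LN10, out=maxlod)
    maxlod = np.maximum(maxlod, 0.0)
    threshold = float(np.quantile(maxlod, 1.0 - alpha, method="linear"))
    return threshold, maxlod


# ---------------------------------------------------------------------------
# QTL summary
# ---------------------------------------------------------------------------

def summarize_qtl(scan: LODScan, threshold: float, gmap,
                  matrix: MarkerGenotypeMatrix | None = None,
                  phenotype=None) -> dict:
    """Report the scan peak against the permutation threshold.

    When the genotype matrix and phenotype are supplied, the two typed
    markers flanking (or at) the peak are located on the map, their
    marker LODs computed, and the cM interval between them reported.
    Returns a dict with an empty ``qtl`` list when nothing exceeds the
    threshold.
    """
    report: dict = {"threshold": float(threshold), "qtl": []}
    peak = scan.peak
    if peak is None or peak["lod"] < threshold:
        return report
    entry = dict(peak)
    entry["significant"] = True
    if matrix is not None and phenotype is not None:
        y = _align_phenotype(list(matrix.individuals), phenotype)
        g = gmap.group(peak["group_id"])
        pos = np.asarray(g.positions_cm)
        x = peak["position_cM"]
        left = np.nonzero(pos <= x + 1e-9)[0]
        right = np.nonzero(pos >= x - 1e-9)[0]
        li = int(left[-1]) if left.size else 0
        ri = int(right[0]) if right.size else len(pos) - 1
        if li == ri:  # peak at a typed marker: interval spans its neighbours
            li = max(0, li - 1)
            ri = min(len(pos) - 1, ri + 1)
        flanks = []
        for idx in (li, ri):
            m = g.markers[idx]
            flanks.append({
                "marker": m,
                "position_cM": float(pos[idx]),
                "lod": float(marker_lod_oracle(matrix.column(m), y)),
            })
        entry["flanking_markers"] = flanks
        entry["flank_interval_cM"] = float(pos[ri] - pos[li])
    report["qtl"].append(entry)
    return report
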