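"""Phenotype categorisation, Mendelian tests, bulk-segregant logic,
genotype–phenotype concordance and relative-expression analysis.

Flowering-time categories come from closed day ranges on per-line
replicate means (defaults 71–78 days early / 84–95 days late, values in
the gap treated as missing). Goodness-of-fit chi-square tests check
Mendelian ratios (1:3 in an F2, 1:1 among RILs). qPCR expression is
summarised on the log2-scale quantity 40−ΔCT (ΔCT = mean target CT −
reference-gene CT), so a group difference of Δ corresponds to a
2^Δ-fold expression difference; factor effects are tested by
fixed-effects ANOVA with Tukey HSD post hoc comparisons.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd


# ---------------------------------------------------------------------------
# phenotype categories
# ---------------------------------------------------------------------------

def categorize(phenotypes, early_range=(71.0, 78.0), late_range=(84.0, 95.0),
               ) -> pd.DataFrame:
    """Assign each individual an early/late flowering category from its
    replicate-mean days to flowering.

    ``phenotypes`` is either a long table (individual, replicate,
    days_to_flowering) or a Series of per-individual means. Ranges are
    closed intervals and must be disjoint with early < late; means
    falling outside both (including the documented gap between them)
    are ``missing``. Raises if an individual has no non-missing
    replicate.
    """
    lo_e, hi_e = early_range
    lo_l, hi_l = late_range
    if hi_e >= lo_l:
        raise ValueError("early range must end before the late range starts")
    if isinstance(phenotypes, pd.DataFrame):
        if phenotypes.groupby("individual")["days_to_flowering"].count().eq(0).any() \
                or phenotypes["days_to_flowering"].isna().groupby(
                    phenotypes["individual"]).all().any():
            raise ValueError("individual with no phenotype replicates")
        means = phenotypes.groupby("individual")["days_to_flowering"].mean()
    else:
        means = pd.Series(phenotypes, dtype=float)
        if means.isna().any():
            raise ValueError("individual with no phenotype replicates")
    cat = np.where((means >= lo_e) & (means <= hi_e), "efl_like",
                   np.where((means >= lo_l) & (means <= hi_l), "Efl_like",
                            "missing"))
    return pd.DataFrame({"individual": means.index, "mean_days": means.to_numpy(),
                         "category": cat}).reset_index(drop=True)


def phenotype_marker(categories: pd.DataFrame) -> pd.Series:
    """Qualitative locus marker derived from the phenotype categories:
    A for homozygous-mutant-like (early), B for wild-type-like (late),
    U for intermediate/missing — codable alongside molecular markers."""
    code = {"efl_like": "A", "Efl_like": "B", "missing": "U"}
    return pd.Series([code[c] for c in categories["category"]],
                     index=categories["individual"], name="phenotype_marker")


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

@dataclass
class SegregationTest:
    observed: list[int]
    expected: list[float]
    ratio: list[float]
    chi2: float
    df: int
    P: float
    correction: str


def gof_test(observed, ratio, correction: str = "none") -> SegregationTest:
    """Chi-square goodness of fit of observed class counts against an
    expected ratio (e.g. (1, 3) for a recessive gene in an F2).

    ``correction='yates'`` subtracts 0.5 from each |O−E| (two classes
    only). The P value is the upper chi-square tail on #classes − 1 df.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(ratio, dtype=float)
    props = props / props.sum()
    total = obs.sum()
    if total <= 0:
        raise ValueError("observed counts sum to zero")
    exp = total * props
    if np.any(exp == 0):
        raise ValueError("zero expected count")
    dev = np.abs(obs - exp)
    if correction == "yates":
        if obs.size != 2:
            raise ValueError("Yates correction applies to two classes (df=1)")
        dev = np.maximum(dev - 0.5, 0.0)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    chi2 = float((dev ** 2 / exp).sum())
    df = obs.size - 1
    return SegregationTest(observed=[int(o) for o in obs],
                           expected=list(exp), ratio=list(props),
                           chi2=chi2, df=df, P=float(chi2_dist.sf(chi2, df)),
                           correction=correction)


# ---------------------------------------------------------------------------
# bulked segregants
# ---------------------------------------------------------------------------

def bulk_expectation(member_genotypes) -> str:
    """Expected pooled-DNA call for a bulk of individuals genotyped at
    one SNP: ``A`` / ``B`` when only one allele is present across the
    members, ``both`` when the bulk collectively carries both."""
    members = list(member_genotypes)
    if not members:
        raise ValueError("empty bulk")
    has_a = any(g in ("AA", "AB") for g in members)
    has_b = any(g in ("BB", "AB") for g in members)
    if has_a and has_b:
        return "both"
    return "A" if has_a else "B"


# ---------------------------------------------------------------------------
# co-segregation
# ---------------------------------------------------------------------------

def concordance(genotypes: pd.Series, categories: pd.DataFrame,
                model: str = "recessive") -> dict:
    """Cross-tabulate candidate-SNP genotypes against phenotype
    categories and test perfect co-segregation under a recessive model
    (homozygous mutant ⇔ early; heterozygous or homozygous wild type ⇔
    late), over individuals non-missing in both.

    Returns the crosstab, the perfect-concordance flag (vacuously true,
    with a warning, when nothing overlaps informatively) and every
    discordant individual.
    """
    if model != "recessive":
        raise ValueError(f"unknown inheritance model {model!r}")
    cats = categories.set_index("individual")["category"]
    common = [i for i in genotypes.index if i in cats.index]
    if not common:
        raise ValueError("no overlapping individuals")
    g = genotypes.loc[common]
    c = cats.loc[common]
    informative = (g != "missing") & (c != "missing")
    expected = pd.Series(np.where(g == "AA", "efl_like", "Efl_like"),
                         index=g.index)
    discordant = [i for i in g.index[informative] if expected[i] != c[i]]
    tab = pd.crosstab(g, c, rownames=["genotype"], colnames=["category"])
    return {
        "crosstab": tab,
        "n_informative": int(informative.sum()),
        "perfect": len(discordant) == 0,
        "discordant": discordant,
        "warning": None if informative.any() else "no informative overlap",
    }


# ---------------------------------------------------------------------------
# relative expression
# ---------------------------------------------------------------------------

def relative_expression(records: pd.DataFrame,
                        factors=("genotype", "treatment", "stage")) -> dict:
    """qPCR analysis on the 40−ΔCT scale.

    Per sample (unique genotype/treatment/stage/replicate combination):
    rel_expr = 40 − (mean target CT over primer pairs − reference CT).
    Reports group means per factor, fold differences 2^Δ between
    genotype group means, a fixed-effects ANOVA over the supplied
    factors (those with ≥ 2 levels) and Tukey HSD comparisons per
    factor. Raises if a sample lacks a reference CT.
    """
    needed = {"ct_target", "ct_reference"}
    if not needed <= set(records.columns):
        raise ValueError("records need ct_target and ct_reference columns")
    if records["ct_reference"].isna().any():
        raise ValueError("sample missing reference CT")
    keys = [f for f in ("genotype", "treatment", "stage", "replicate")
            if f in records.columns]
    per_sample = records.groupby(keys, as_index=False).agg(
        ct_target=("ct_target", "mean"), ct_reference=("ct_reference", "mean"))
    per_sample["rel_expr"] = 40.0 - (per_sample["ct_target"]
                                     - per_sample["ct_reference"])

    used = [f for f in factors
            if f in per_sample.columns and per_sample[f].nunique() > 1]
    group_means = {f: per_sample.groupby(f)["rel_expr"].mean() for f in used}

    fold = {}
    if "genotype" in group_means:
        gm = group_means["genotype"]
        levels = list(gm.index)
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                delta = gm[levels[j]] - gm[levels[i]]
                fold[f"{levels[j]}/{levels[i]}"] = float(2.0 ** delta)

    anova = None
    pvalues = {}
    if used:
        formula = "rel_expr ~ " + " + ".join(f"C({f})" for f in used)
        fit = ols(formula, data=per_sample).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
        for f in used:
            pvalues[f] = float(anova.loc[f"C({f})", "PR(>F)"])
    tukey = {
        f: pairwise_tukeyhsd(per_sample["rel_expr"], per_sample[f].astype(str))
        for f in used
    }
    return {"per_sample": per_sample, "group_means": group_means,
            "fold_differences": fold, "anova": anova, "p_values": pvalues,
            "tukey": tukey}
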