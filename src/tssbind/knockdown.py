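"""Knockdown response classification and bound-gene enrichment.

Two independent shRNA constructs, each assayed in replicate (triplicates in
the motivating design), are compared against control arms gene by gene:
log2 fold change = mean(kd) - mean(ctrl) and a two-sample equal-variance
t-test. The constructs are combined by averaging fold changes and by
Fisher's method (Stouffer optional) on the p-values, and genes are
classified into the thousand most up- and downregulated — by average fold
change, or by combined p among genes whose fold changes agree in sign.
Bound-gene enrichment across the up / down / unaffected split is tested by
a chi-square contingency test plus pairwise two-proportion z-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "per_construct_stats",
    "combine_constructs",
    "classify_top_k",
    "bound_enrichment_by_category",
    "fold_change_cdf",
]


def per_construct_stats(
    expr_kd: pd.DataFrame, expr_ctrl: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene log2 fold change and t-test p for one construct.

    Both matrices are genes x replicates on log2 scale, indexed by gene id.
    Genes with zero variance in both arms and equal means get p = 1 by
    convention (no evidence of change).
    """
    if expr_kd.shape[1] < 2 or expr_ctrl.shape[1] < 2:
        raise ValueError("need at least two replicates per arm")
    common = expr_kd.index.intersection(expr_ctrl.index)
    kd = expr_kd.loc[common].to_numpy(dtype=float)
    ctrl = expr_ctrl.loc[common].to_numpy(dtype=float)
    fold = kd.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = stats.ttest_ind(kd, ctrl, axis=1, equal_var=True)
        p = np.asarray(t.pvalue, dtype=float)
    degenerate = np.isnan(p)
    p[degenerate & (np.abs(fold) < 1e-300)] = 1.0
    p[degenerate & (np.abs(fold) >= 1e-300)] = 0.0
    return pd.DataFrame({"fold_change": fold, "p": p}, index=common)


def combine_constructs(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    method: str = "fisher",
) -> pd.DataFrame:
    """Combine two constructs' per-gene statistics.

    avg_fold_change is the arithmetic mean of the two log2 fold changes;
    combined_p uses Fisher's method by default (Stouffer optional). The
    ``concordant`` flag records whether the two fold changes agree in sign
    (zero fold changes count as discordant); directional top-k calls by
    p-value are restricted to concordant genes. Genes present in only one
    construct are excluded (a warning reports how many).
    """
    if method not in ("fisher", "stouffer"):
        raise ValueError(f"unknown combination method {method!r}")
    common = stats1.index.intersection(stats2.index)
    dropped = len(stats1.index.union(stats2.index)) - len(common)
    if dropped:
        warnings.warn(f"{dropped} genes present in only one construct; excluded")
    f1 = stats1.loc[common, "fold_change"].to_numpy()
    f2 = stats2.loc[common, "fold_change"].to_numpy()
    p1 = stats1.loc[common, "p"].to_numpy()
    p2 = stats2.loc[common, "p"].to_numpy()
    if method == "fisher":
        chi2 = -2 * (np.log(np.clip(p1, 1e-300, 1)) + np.log(np.clip(p2, 1e-300, 1)))
        combined = stats.chi2.sf(chi2, df=4)
    else:
        z = (stats.norm.isf(np.clip(p1, 1e-300, 1 - 1e-16))
             + stats.norm.isf(np.clip(p2, 1e-300, 1 - 1e-16))) / np.sqrt(2)
        combined = stats.norm.sf(z)
    return pd.DataFrame(
        {
            "fold_change_1": f1,
            "fold_change_2": f2,
            "p_1": p1,
            "p_2": p2,
            "avg_fold_change": (f1 + f2) / 2,
            "combined_p": combined,
            "concordant": np.sign(f1) * np.sign(f2) > 0,
        },
        index=common,
    )


def classify_top_k(
    table: pd.DataFrame, k: int = 1000, by: str = "fold"
) -> pd.Series:
    """Three-way split: the k most up- and downregulated genes vs the rest.

    ``by="fold"``: up = the k largest average fold changes, down = the k
    smallest. ``by="p"``: up = the k smallest combined p among genes with
    concordant positive fold change (down symmetric); if fewer than k genes
    of a sign exist the category is smaller and a warning is issued. Ties
    break by gene_id; the result is invariant to input row order.
    """
    if by not in ("fold", "p"):
        raise ValueError(f"unknown classification criterion {by!r}")
    if len(table) < 2 * k + 1:
        raise ValueError(f"need at least {2 * k + 1} genes for k={k}")
    cats = pd.Series("unaffected", index=table.index, name="category")
    df = table.copy()
    df["_gene"] = df.index.astype(str)
    if by == "fold":
        up = df.sort_values(["avg_fold_change", "_gene"], ascending=[False, True]).index[:k]
        down = df.sort_values(["avg_fold_change", "_gene"], ascending=[True, True]).index[:k]
    else:
        pos = df[(df["concordant"]) & (df["avg_fold_change"] > 0)]
        neg = df[(df["concordant"]) & (df["avg_fold_change"] < 0)]
        for name, sub in (("up", pos), ("down", neg)):
            if len(sub) < k:
                warnings.warn(
                    f"only {len(sub)} concordant genes available for {name!r} (k={k})"
                )
        up = pos.sort_values(["combined_p", "_gene"]).index[:k]
        down = neg.sort_values(["combined_p", "_gene"]).index[:k]
    cats.loc[up] = "up"
    cats.loc[down] = "down"
    return cats


def bound_enrichment_by_category(
    categories: pd.Series, bound: set[str], universe: set[str] | None = None
) -> dict:
    """Proportion of bound genes per category plus enrichment tests.

    Chi-square test of the bound x {up, down, unaffected} contingency table,
    and pairwise two-proportion z-tests of up-vs-unaffected and
    down-vs-unaffected. Degenerate tables (a zero margin) are reported as
    non-applicable rather than raising.
    """
    if universe is not None:
        missing = set(categories.index) - universe
        if missing:
            raise ValueError("categories extend beyond the declared universe")
    cat_names = ["up", "down", "unaffected"]
    counts, totals = {}, {}
    for c in cat_names:
        ids = categories.index[categories == c]
        totals[c] = len(ids)
        counts[c] = sum(1 for g in ids if g in bound)
    used = [c for c in cat_names if totals[c] > 0]
    table = np.array(
        [[counts[c] for c in used], [totals[c] - counts[c] for c in used]]
    )
    result = {
        "proportions": {
            c: counts[c] / totals[c] if totals[c] else np.nan for c in cat_names
        },
        "counts": counts,
        "totals": totals,
    }
    if len(used) >= 2 and table.sum(axis=1).min() > 0:
        chi2, p, _, _ = stats.chi2_contingency(table)
        result["chi2"] = float(chi2)
        result["chi2_p"] = float(p)
    else:
        result["chi2"] = None
        result["chi2_p"] = None
    for c in ("up", "down"):
        key = f"z_p_{c}_vs_unaffected"
        if totals[c] > 0 and totals["unaffected"] > 0:
            result[key] = _two_proportion_z(
                counts[c], totals[c], counts["unaffected"], totals["unaffected"]
            )
        else:
            result[key] = None
    return result


def _two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> float | None:
    """One-sided pooled two-proportion z-test p (proportion 1 > proportion 2)."""
    p_pool = (x1 + x2) / (n1 + n2)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return None
    z = (x1 / n1 - x2 / n2) / se
    return float(stats.norm.sf(z))


def fold_change_cdf(
    table: pd.DataFrame, bound: set[str], n_grid: int = 512
) -> pd.DataFrame:
    """Empirical CDFs of average fold change for bound vs non-bound genes.

    Both curves are evaluated on one common grid spanning the observed fold
    changes, so tail crossings are directly comparable.
    """
    if table.empty:
        raise ValueError("empty regulation table")
    fc = table["avg_fold_change"]
    is_bound = fc.index.astype(str).isin(bound)
    grid = np.linspace(float(fc.min()), float(fc.max()), n_grid)
    out = {"fold_change": grid}
    for name, values in (
        ("cdf_bound", np.sort(fc[is_bound].to_numpy())),
        ("cdf_not_bound", np.sort(fc[~is_bound].to_numpy())),
        ("cdf_all", np.sort(fc.to_numpy())),
    ):
        if len(values):
            out[name] = np.searchsorted(values, grid, side="right") / len(values)
        else:
            out[name] = np.full(n_grid, np.nan)
    return pd.DataFrame(out)
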