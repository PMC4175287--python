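"""Permutation-calibrated LASSO co-expression network and hub analysis.

Each non-TF target gene's standardized expression is regressed on the
standardized expression of every transcription factor with an L1 penalty;
a nonzero coefficient defines a directed TF -> gene edge. The penalty is
set by permutation: every gene's sample labels are shuffled independently
(destroying inter-gene correlation while preserving marginals) and lambda*
is the smallest value on a 50-point logarithmic grid at which *every*
permuted dataset yields an empty network. A TF's connection count is its
out-degree; hubs are TFs with the largest counts.

Fits use scikit-learn's coordinate-descent Lasso with the objective
(1/2n)||y - Xb||^2 + lambda*||b||_1, so the all-zero solution is optimal
exactly when lambda >= max_j |x_j'y| / n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso

__all__ = [
    "ExpressionMatrix",
    "NetworkModel",
    "standardize",
    "fit_lasso_network",
    "calibrate_lambda_by_permutation",
    "hub_ranking",
    "cross_dataset_rank",
]


@dataclass
class ExpressionMatrix:
    """Samples x genes expression with a declared TF subset.

    ``data`` rows are samples, columns genes. Genes are standardized to
    mean 0, variance 1 (population variance) on construction so the lasso
    penalty is comparable across genes and no intercept is needed.
    """

    data: pd.DataFrame
    tf_list: list[str]

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        unknown = [t for t in self.tf_list if t not in self.data.columns]
        if unknown:
            raise ValueError(f"TFs absent from matrix: {unknown[:5]}")
        self.data = standardize(self.data)

    @property
    def targets(self) -> list[str]:
        tfs = set(self.tf_list)
        return [g for g in self.data.columns if g not in tfs]

    def tf_array(self) -> np.ndarray:
        return self.data[self.tf_list].to_numpy(dtype=float)

    def target_array(self) -> np.ndarray:
        return self.data[self.targets].to_numpy(dtype=float)


def standardize(df: pd.DataFrame) -> pd.DataFrame:
    """Mean 0, variance 1 per gene (constant genes are left at zero)."""
    arr = df.to_numpy(dtype=float)
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0)
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - mu) / sd, index=df.index, columns=df.columns)


@dataclass
class NetworkModel:
    """Sparse TF -> target edge set at one regularization level."""

    edges: pd.DataFrame  # columns: tf, target, coefficient
    lam: float
    tf_list: list[str] = field(default_factory=list)

    def connection_counts(self) -> pd.Series:
        counts = pd.Series(0, index=pd.Index(self.tf_list, name="tf"), dtype=int)
        if len(self.edges):
            observed = self.edges.groupby("tf").size()
            counts.loc[observed.index] = observed
        return counts

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def lambda_max(X: np.ndarray, Y: np.ndarray) -> float:
    """Smallest penalty at which every target's lasso solution is all-zero."""
    n = X.shape[0]
    return float(np.abs(X.T @ Y).max() / n)


def fit_lasso_network(
    xmat: ExpressionMatrix,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> NetworkModel:
    """L1-penalized regression of every target gene on all TFs.

    Deterministic given the data and lambda. Non-convergence of the
    coordinate descent raises rather than returning a partial model.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if xmat.data.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    X = xmat.tf_array()
    model = Lasso(alpha=lam, fit_intercept=False, tol=tol, max_iter=max_iter)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        for target in xmat.targets:
            y = xmat.data[target].to_numpy(dtype=float)
            try:
                model.fit(X, y)
            except UserWarning as exc:  # ConvergenceWarning subclasses UserWarning
                raise RuntimeError(
                    f"lasso did not converge for target {target!r}: {exc}"
                ) from exc
            nz = np.nonzero(model.coef_)[0]
            for j in nz:
                rows.append((xmat.tf_list[j], target, float(model.coef_[j])))
    edges = pd.DataFrame(rows, columns=["tf", "target", "coefficient"])
    return NetworkModel(edges=edges, lam=lam, tf_list=list(xmat.tf_list))


def _permute_genes(data: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Shuffle each gene's sample labels independently."""
    arr = data.to_numpy(dtype=float).copy()
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        arr[:, j] = arr[rng.permutation(n), j]
    return pd.DataFrame(arr, index=data.index, columns=data.columns)


def calibrate_lambda_by_permutation(
    xmat: ExpressionMatrix,
    n_perm: int = 10,
    seed: int | np.random.Generator = 0,
    n_grid: int = 50,
    keep_permutations: bool = False,
) -> dict:
    """Pick lambda* = smallest grid value giving zero edges on every permutation.

    The grid is logarithmic over [0.01 * lambda_max, lambda_max] with
    ``n_grid`` points, where lambda_max is computed on the unpermuted data.
    A permuted dataset has zero edges at lambda iff lambda >= its own
    lambda_max, which is evaluated in closed form; the returned record keeps
    each permutation's threshold so the zero-edge guarantee can be re-checked
    by refitting. If no grid point silences every permutation, lambda_max is
    returned with a warning.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = xmat.tf_array()
    Y = xmat.target_array()
    lmax = lambda_max(X, Y)
    grid = np.geomspace(0.01 * lmax, lmax, n_grid)
    perm_thresholds = []
    permutations = []
    for _ in range(n_perm):
        pdata = _permute_genes(xmat.data, rng)
        pstd = standardize(pdata)
        Xp = pstd[xmat.tf_list].to_numpy(dtype=float)
        Yp = pstd[xmat.targets].to_numpy(dtype=float)
        perm_thresholds.append(lambda_max(Xp, Yp))
        if keep_permutations:
            permutations.append(pstd)
    need = max(perm_thresholds)
    ok = grid[grid >= need - 1e-15]
    if len(ok):
        lam_star = float(ok[0])
        warn = None
    else:
        lam_star = float(grid[-1])
        warn = "zero edges unreachable on grid; returning lambda_max"
        warnings.warn(warn)
    return {
        "lambda_star": lam_star,
        "lambda_max": lmax,
        "grid": grid,
        "permutation_thresholds": perm_thresholds,
        "permutations": permutations if keep_permutations else None,
        "warning": warn,
    }


def hub_ranking(model: NetworkModel) -> pd.DataFrame:
    """TFs ordered by descending connection count (ties by tf id)."""
    counts = model.connection_counts().reset_index(name="connections")
    counts = counts.sort_values(
        ["connections", "tf"], ascending=[False, True]
    ).reset_index(drop=True)
    counts.insert(0, "rank", np.arange(1, len(counts) + 1))
    return counts


def cross_dataset_rank(
    model_a: NetworkModel, model_b: NetworkModel, tf: str, top: int = 30
) -> dict:
    """Compare one TF's hub rank across two independently fitted networks.

    Reports the TF's rank in each model, its percentile (rank / #TFs) in the
    second, and — among the ``top`` best-connected TFs of model A — the TF
    with the most connections in model B.
    """
    ranks = {}
    for name, model in (("a", model_a), ("b", model_b)):
        table = hub_ranking(model)
        row = table[table["tf"] == tf]
        if row.empty:
            raise ValueError(f"TF {tf!r} absent from model {name}")
        ranks[name] = int(row["rank"].iloc[0])
    n_b = len(model_b.tf_list)
    top_a = hub_ranking(model_a).head(top)["tf"].tolist()
    counts_b = model_b.connection_counts()
    shared = [t for t in top_a if t in counts_b.index]
    best_in_b = (
        min(shared, key=lambda t: (-counts_b[t], t)) if shared else None
    )
    return {
        "rank_a": ranks["a"],
        "rank_b": ranks["b"],
        "percentile_b": ranks["b"] / n_b,
        "top_a_best_in_b": best_in_b,
    }
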