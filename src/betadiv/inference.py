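"""Permutation and rank-based statistics for distance matrices and tables.

* :func:`mantel_test` — permutation Mantel test between two labeled distance
  matrices.  The statistic is the correlation (Pearson, or Spearman on
  midranks) of the vectorized upper triangles; the null is built by
  simultaneously permuting the rows and columns of the second matrix, and
  the p-value uses the add-one rule p = (#{r_perm >= r_obs} + 1)/(n_perm + 1)
  for the one-tailed "greater" alternative (|r| for two-sided).  Explicit
  seeding makes results bit-reproducible.
* :func:`spearman_rho`, :func:`kruskal_wallis` — thin, validated fronts over
  scipy's rank statistics (mid-rank ties; Kruskal-Wallis H is tie-corrected
  with a chi-square reference; Spearman p uses the t approximation).
* :func:`pca_correlation` — PCA as an eigendecomposition of the correlation
  matrix with a deterministic loading-sign convention.
* :func:`collinearity_screen` — all variable pairs whose |Spearman rho|
  exceeds a threshold, for user-driven exclusion before ordination or
  regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MantelResult",
    "PCAResult",
    "mantel_test",
    "spearman_rho",
    "kruskal_wallis",
    "kruskal_pairwise",
    "pca_correlation",
    "collinearity_screen",
    "holm_adjust",
]


@dataclass(frozen=True)
class MantelResult:
    r: float
    r2: float
    p: float
    n: int
    n_perm: int
    method: str
    tail: str
    seed: int | None

    def __repr__(self) -> str:  # compact, Table-4 style
        return (
            f"MantelResult(r={self.r:.3f}, r2={self.r2:.3f}, p={self.p:.4g}, "
            f"n={self.n}, n_perm={self.n_perm}, {self.method}/{self.tail})"
        )


def _rank_matrix(square: np.ndarray) -> np.ndarray:
    """Replace off-diagonal entries by the midranks of the condensed vector."""
    n = square.shape[0]
    iu = np.triu_indices(n, 1)
    ranks = stats.rankdata(square[iu])
    out = np.zeros_like(square, dtype=float)
    out[iu] = ranks
    out = out + out.T
    return out


def mantel_test(
    x: DistanceMatrix,
    y: DistanceMatrix,
    n_perm: int = 9999,
    method: str = "pearson",
    tail: str = "greater",
    seed: int | None = None,
) -> MantelResult:
    """Permutation Mantel test between two distance matrices.

    Matrices are aligned on their shared ids (which must be identical as
    sets, n >= 4).  ``method`` is "pearson" or "spearman"; ``tail`` is
    "greater" (default, positive association) or "two-sided".
    """
    if set(x.ids) != set(y.ids):
        raise ValueError("distance matrices have mismatched unit ids")
    n = len(x.ids)
    if n < 4:
        raise ValueError("Mantel test needs >= 4 units")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if tail not in ("greater", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if math.factorial(n) < n_perm:
        warnings.warn(
            f"n_perm={n_perm} exceeds the {math.factorial(n)} distinct "
            f"permutations of {n} units; p-values are granular",
            stacklevel=2,
        )

    X = x.data.astype(float)
    Y = y.filter(x.ids).data.astype(float)
    if method == "spearman":
        X, Y = _rank_matrix(X), _rank_matrix(Y)

    iu = np.triu_indices(n, 1)
    vx, vy = X[iu], Y[iu]
    if np.std(vx) == 0 or np.std(vy) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    xc = vx - vx.mean()
    xnorm = np.linalg.norm(xc)
    yc = vy - vy.mean()
    r_obs = float(xc @ yc / (xnorm * np.linalg.norm(yc)))

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=np.intp)
    for i in range(n_perm):
        perms[i] = rng.permutation(n)
    yp = Y[perms[:, iu[0]], perms[:, iu[1]]]
    ypc = yp - yp.mean(axis=1, keepdims=True)
    r_perm = (ypc @ xc) / (np.linalg.norm(ypc, axis=1) * xnorm)

    # ties at r_obs count toward the tail (small tolerance guards float noise)
    tol = 1e-12
    if tail == "greater":
        p = (np.sum(r_perm >= r_obs - tol) + 1) / (n_perm + 1)
    else:
        p = (np.sum(np.abs(r_perm) >= abs(r_obs) - tol) + 1) / (n_perm + 1)
    return MantelResult(
        r=r_obs,
        r2=r_obs**2,
        p=float(p),
        n=n,
        n_perm=n_perm,
        method=method,
        tail=tail,
        seed=seed,
    )


def spearman_rho(u, v) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties; p via the t approximation."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("u and v must be 1-D of equal length")
    if u.size < 3:
        raise ValueError("need >= 3 pairs")
    if np.std(u) == 0 or np.std(v) == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    res = stats.spearmanr(u, v)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square(k-1) p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("each group must be non-empty")
    if sum(g.size for g in groups) < 5:
        raise ValueError("need >= 5 observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise ValueError("all observations identical: H undefined (tie correction)")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def kruskal_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Mann-Whitney follow-up with Holm correction.

    An extension beyond a bare Kruskal-Wallis: identifies which group pairs
    differ.  Returns a tidy frame (group1, group2, u, p, p_holm).
    """
    labels = list(groups)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            u, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            rows.append({"group1": a, "group2": b, "u": float(u), "p": float(p)})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_holm"] = holm_adjust(df["p"].to_numpy())
    return df


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="holm")[1]


@dataclass(frozen=True)
class PCAResult:
    """Correlation-matrix PCA output.

    ``eigenvalues`` descend; ``variance_fractions`` sum to 1 over all axes;
    ``loadings`` (variables x axes) carry the deterministic sign convention
    that each axis's largest-magnitude loading is positive; ``scores`` are
    the z-scored units projected on the axes.
    """

    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame

    @property
    def n_axes(self) -> int:
        return self.eigenvalues.size

    def cumulative_fraction(self, k: int) -> float:
        return float(self.variance_fractions[:k].sum())


def pca_correlation(table: pd.DataFrame) -> PCAResult:
    """PCA by eigendecomposition of the variables' correlation matrix.

    Requires >= 2 units, >= 2 numeric variables, no missing values and no
    zero-variance variable (the offending column is named in the error).
    """
    X = table.select_dtypes("number").astype(float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs >= 2 units and >= 2 variables")
    if X.isna().any().any():
        bad = [c for c in X.columns if X[c].isna().any()]
        raise ValueError(f"missing values in columns {bad}")
    sds = X.std(ddof=1)
    zero = list(sds.index[sds == 0])
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    Z = (X - X.mean()) / sds
    corr = np.corrcoef(X.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):  # sign convention
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    axes = [f"PC{i + 1}" for i in range(evals.size)]
    loadings = pd.DataFrame(evecs, index=X.columns, columns=axes)
    scores = pd.DataFrame(Z.to_numpy() @ evecs, index=X.index, columns=axes)
    return PCAResult(
        eigenvalues=evals,
        variance_fractions=evals / evals.sum(),
        loadings=loadings,
        scores=scores,
    )


def collinearity_screen(
    table: pd.DataFrame, rho_threshold: float = 0.8
) -> pd.DataFrame:
    """Variable pairs with |Spearman rho| above a threshold (pairwise-complete).

    Returns a frame (var1, var2, rho, n) sorted by |rho| descending, for
    user-driven exclusion of redundant variables.
    """
    X = table.select_dtypes("number").astype(float)
    cols = list(X.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            pair = X[[a, b]].dropna()
            if pair.shape[0] < 3:
                continue
            if pair[a].std() == 0 or pair[b].std() == 0:
                continue
            rho = stats.spearmanr(pair[a], pair[b]).statistic
            if abs(rho) > rho_threshold:
                rows.append(
                    {"var1": a, "var2": b, "rho": float(rho), "n": pair.shape[0]}
                )
    df = pd.DataFrame(rows, columns=["var1", "var2", "rho", "n"])
    if len(df):
        df = df.reindex(df["rho"].abs().sort_values(ascending=False).index)
        df = df.reset_index(drop=True)
    return df
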