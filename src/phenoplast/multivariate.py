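"""Clustering, ordination and correlation stages over family-level profiles.

* :func:`cluster_families` — hierarchical clustering of families on their
  (already [0, 1]-scaled, hence unstandardized) index profiles, with plain
  bootstrap support per internal node from column resampling.
* :func:`pca_families` — PCA on the correlation matrix of a complete
  family-feature matrix, retaining components with eigenvalue > 1.
* :func:`correlation_matrix` — all pairwise Pearson correlations with
  Benjamini-Hochberg adjusted significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .rdpi import IndexMatrix
from .stomatal import LogLinearFit
from .traits import TraitTable


@dataclass
class ClusterTree:
    """Dendrogram over families with per-internal-node bootstrap support."""

    families: list[str]
    linkage: np.ndarray
    nodes: pd.DataFrame  # node, height, n_leaves, members, support
    B: int

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.families[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


@dataclass
class MultivariateResult:
    eigenvalues: np.ndarray | None = None
    variance_fractions: np.ndarray | None = None
    n_retained: int | None = None
    loadings: pd.DataFrame | None = None
    scores: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None
    p_values: pd.DataFrame | None = None
    q_values: pd.DataFrame | None = None
    significant: pd.DataFrame | None = None


def _cluster_leafsets(Z: np.ndarray, n: int) -> list[frozenset[int]]:
    """Leaf-index set of every internal node, in merge order."""
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (a, b, _h, _c) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        out.append(merged)
    return out


def cluster_families(
    index_matrix: pd.DataFrame | IndexMatrix,
    B: int = 1000,
    seed: int | None = None,
    method: str = "average",
    metric: str = "euclidean",
) -> ClusterTree:
    """Hierarchical clustering of families with bootstrap node support.

    Rows are clustered as-is (no standardization: the indices share a common
    [0, 1] scale).  Support of an internal node is the fraction of ``B``
    column-resampled dendrograms containing the identical leaf set.
    """
    if isinstance(index_matrix, IndexMatrix):
        index_matrix = index_matrix.matrix
    if B < 1:
        raise ValueError("B must be >= 1")
    if index_matrix.isna().any().any():
        raise ValueError("index matrix has missing cells; clustering undefined")
    X = index_matrix.to_numpy(float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 families and 2 index columns")

    Z = hierarchy.linkage(X, method=method, metric=metric)
    leafsets = _cluster_leafsets(Z, n)
    counts = np.zeros(len(leafsets))
    rng = np.random.default_rng(seed)
    targets = {ls: i for i, ls in enumerate(leafsets)}
    for _ in range(B):
        cols = rng.integers(0, p, size=p)
        Zb = hierarchy.linkage(X[:, cols], method=method, metric=metric)
        for ls in _cluster_leafsets(Zb, n):
            hit = targets.get(ls)
            if hit is not None:
                counts[hit] += 1

    families = [str(f) for f in index_matrix.index]
    nodes = pd.DataFrame(
        {
            "node": np.arange(n, n + len(leafsets)),
            "height": Z[:, 2],
            "n_leaves": [len(ls) for ls in leafsets],
            "members": [";".join(sorted((families[i] for i in ls))) for ls in leafsets],
            "support": counts / B,
        }
    )
    return ClusterTree(families=families, linkage=Z, nodes=nodes, B=B)


def build_family_features(
    table: TraitTable,
    index_matrix: pd.DataFrame | IndexMatrix,
    fit: LogLinearFit | None = None,
    drop_incomplete: bool = True,
) -> pd.DataFrame:
    """Family-level feature matrix for ordination and correlation.

    Columns: the PP-/RE- index columns, per-family means of every stress-phase
    trait split by treatment (``<trait>-ww`` / ``<trait>-ws``), per-family
    means of the recovery-phase gas-exchange traits (``<trait>-recov-ww`` /
    ``-ws``) and, when a dose-response fit is supplied, the family slope
    ``beta``.
    """
    if isinstance(index_matrix, IndexMatrix):
        index_matrix = index_matrix.matrix
    parts = [index_matrix]
    for phase, suffix in (("stress", ""), ("recovery", "-recov")):
        df = table.subset(phase=phase)
        if df.empty:
            continue
        means = (
            df.groupby(["family", "trait", "treatment"], observed=True)["value"]
            .mean()
            .unstack(["trait", "treatment"])
        )
        means.columns = [f"{t}{suffix}-{trt.lower()}" for t, trt in means.columns]
        parts.append(means)
    if fit is not None:
        beta = fit.coef_table.set_index("family")["beta"].rename("beta")
        parts.append(beta.to_frame())
    features = pd.concat(parts, axis=1)
    features.index.name = "family"
    if drop_incomplete:
        features = features.dropna(axis=1)
    return features


def pca_families(features: pd.DataFrame) -> MultivariateResult:
    """Correlation-matrix PCA with the eigenvalue > 1 retention rule.

    Columns are standardized to zero mean and unit variance; loadings carry a
    deterministic sign (the largest-magnitude loading of each component is
    positive).
    """
    if features.isna().any().any():
        raise ValueError("feature matrix has missing cells")
    X = features.to_numpy(float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 columns")
    sd = X.std(axis=0, ddof=1)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        names = [features.columns[i] for i in zero_var]
        raise ValueError(f"zero-variance column(s): {names}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    for j in range(p):
        i_max = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i_max, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    fractions = eigval / eigval.sum()
    comp_names = [f"PC{i + 1}" for i in range(p)]
    loadings = pd.DataFrame(eigvec, index=features.columns, columns=comp_names)
    scores = pd.DataFrame(Z @ eigvec, index=features.index, columns=comp_names)
    return MultivariateResult(
        eigenvalues=eigval,
        variance_fractions=fractions,
        n_retained=int((eigval > 1.0).sum()),
        loadings=loadings,
        scores=scores,
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def correlation_matrix(features: pd.DataFrame, alpha: float = 0.05) -> MultivariateResult:
    """Pearson correlations for every column pair with BH-adjusted two-sided
    significance.

    Constant columns yield undefined correlations; their pairs are left NaN
    and never flagged significant.  Requires at least 4 rows.
    """
    n = len(features)
    if n < 4:
        raise ValueError("need at least 4 rows for correlation inference")
    cols = list(features.columns)
    X = features.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    p_count = len(cols)
    r = np.full((p_count, p_count), np.nan)
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(X[:, ok], rowvar=False)
        idx = np.flatnonzero(ok)
        r[np.ix_(idx, idx)] = np.atleast_2d(sub)
    np.fill_diagonal(r, np.where(ok, 1.0, np.nan))

    dfree = n - 2
    iu = np.triu_indices(p_count, k=1)
    r_pairs = r[iu]
    p_pairs = np.full(r_pairs.size, np.nan)
    finite = np.isfinite(r_pairs)
    rr = np.clip(r_pairs[finite], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        tstat = rr * np.sqrt(dfree / np.maximum(1.0 - rr**2, np.finfo(float).tiny))
    p_pairs[finite] = np.where(np.abs(rr) >= 1.0, 0.0, 2 * stats.t.sf(np.abs(tstat), dfree))

    q_pairs = np.full_like(p_pairs, np.nan)
    if finite.any():
        q_pairs[finite] = bh_adjust(p_pairs[finite])

    def square(pairs: np.ndarray, diag: float) -> np.ndarray:
        M = np.full((p_count, p_count), np.nan)
        M[iu] = pairs
        M[(iu[1], iu[0])] = pairs
        np.fill_diagonal(M, diag)
        return M

    p_mat = square(p_pairs, np.nan)
    q_mat = square(q_pairs, np.nan)
    sig = np.zeros((p_count, p_count), dtype=bool)
    with np.errstate(invalid="ignore"):
        sig[q_mat <= alpha] = True
    np.fill_diagonal(sig, False)  # diagonal flags suppressed
    wrap = lambda M: pd.DataFrame(M, index=cols, columns=cols)
    return MultivariateResult(
        correlations=wrap(r),
        p_values=wrap(p_mat),
        q_values=wrap(q_mat),
        significant=wrap(sig),
    )
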