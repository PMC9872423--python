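"""Normalization, aggregation, clustering and embedding of radiomic features.

Quantile normalization forces every sample's (row's) feature distribution
onto a common reference built from mean order statistics, so feature values
are comparable across images/patients.  Patient-level features are the
arithmetic mean of the patient's image-level rows.  Unsupervised structure
is explored with complete-linkage hierarchical clustering and t-SNE, and
cluster/clinical contingency is assessed with Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import lgamma
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.manifold import TSNE

__all__ = [
    "QuantileNormalizer",
    "quantile_normalize",
    "aggregate_patient",
    "ClusterResult",
    "hcluster",
    "tsne_embed",
    "cluster_enrichment",
    "fisher_exact_2xk",
]


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Map each row's empirical distribution onto a mean-order-statistic reference.

    ``fit`` computes the reference (the mean across rows of each sorted
    position); ``transform`` replaces every row's values by the reference
    values at the row's ranks, ties receiving the mean of their tied
    reference values.  After ``fit_transform`` all rows share identical
    sorted values and each row's rank order is preserved.
    """

    def fit(self, X: np.ndarray, y=None) -> "QuantileNormalizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D units x features matrix")
        if np.isnan(X).any():
            raise ValueError("matrix has missing values")
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        ref = self.reference_
        out = np.empty_like(X, dtype=float)
        for i, row in enumerate(X):
            order = np.argsort(row, kind="stable")
            vals = ref.copy()
            # average reference values over tie groups of the row
            uniq, inv = np.unique(row, return_inverse=True)
            if uniq.size < row.size:
                assigned = np.empty_like(row)
                assigned[order] = vals
                sums = np.bincount(inv, weights=assigned)
                counts = np.bincount(inv)
                out[i] = (sums / counts)[inv]
            else:
                out[i, order] = vals
        return out


def quantile_normalize(matrix: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Quantile-normalize a units x features matrix across rows (samples)."""
    is_df = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    if X.shape[0] == 1:
        warnings.warn("quantile normalization of a single unit is an identity",
                      stacklevel=2)
        return matrix.copy() if is_df else X.copy()
    res = QuantileNormalizer().fit_transform(X)
    if is_df:
        return pd.DataFrame(res, index=matrix.index, columns=matrix.columns)
    return res


def aggregate_patient(drf_frame: pd.DataFrame) -> pd.DataFrame:
    """Patient-level features: feature-wise mean of each patient's image rows.

    Accepts the image-level frame produced by ``DRFMatrix.to_frame()`` (or
    any frame with a ``patient_id`` column and numeric feature columns).
    """
    if "patient_id" not in drf_frame.columns:
        raise ValueError("frame must carry a patient_id column")
    feats = [c for c in drf_frame.columns
             if c not in ("patient_id", "image_id")]
    return drf_frame.groupby("patient_id", sort=True)[feats].mean()


@dataclass
class ClusterResult:
    labels: np.ndarray
    method: str
    k: int
    enrichment: dict[str, float]


def hcluster(matrix: np.ndarray | pd.DataFrame, k: int) -> ClusterResult:
    """Agglomerative clustering (Euclidean, complete linkage) cut at k clusters."""
    X = np.asarray(matrix, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} available units")
    if k == 1:
        labels = np.ones(X.shape[0], dtype=int)
    else:
        Z = linkage(X, method="complete", metric="euclidean")
        labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(labels=np.asarray(labels), method="hierarchical",
                         k=k, enrichment={})


def tsne_embed(matrix: np.ndarray | pd.DataFrame, perplexity: float = 30.0,
               seed: int = 0) -> np.ndarray:
    """2-D t-SNE embedding; deterministic given the seed."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] <= 3 * perplexity:
        raise ValueError(f"perplexity {perplexity} too large for "
                         f"{X.shape[0]} units (need units > 3*perplexity)")
    emb = TSNE(n_components=2, perplexity=perplexity, init="pca",
               random_state=seed).fit_transform(X)
    return np.asarray(emb)


def _log_binom(n: float, k: float) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def _table_logprob(table: np.ndarray) -> float:
    # Fisher's conditional probability of a 2xk table given all margins
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    lp = sum(_log_binom(c, x) for c, x in zip(col, table[0]))
    return lp - _log_binom(n, row[0])


def fisher_exact_2xk(table: np.ndarray, seed: int = 0,
                     max_tables: int = 2_000_000,
                     n_mc: int = 200_000) -> float:
    """Two-sided Fisher exact test for a 2 x k contingency table.

    k = 2 uses the classical hypergeometric test; k > 2 uses Freeman–Halton
    enumeration over all tables with the observed margins, falling back to a
    seeded Patefield Monte Carlo estimate when the table space is too large.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("expected a 2 x k table with k >= 2")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
            return 1.0
    if table.shape[1] == 2:
        return float(stats.fisher_exact(table, alternative="two-sided")[1])

    col = table.sum(axis=0)
    a = int(table.sum(axis=1)[0])
    space = np.prod([min(c, a) + 1.0 for c in col])
    obs_lp = _table_logprob(table)
    tol = 1e-9
    if space <= max_tables:
        k = table.shape[1]
        log_denom = _log_binom(table.sum(), a)

        # enumerate first-row compositions x_1..x_k with sum a, x_j <= col_j,
        # accumulating the probability of tables no more probable than observed

        def recurse_p(j: int, remaining: int, lp: float) -> float:
            if j == k - 1:
                if remaining > col[j]:
                    return 0.0
                full = lp + _log_binom(col[j], remaining) - log_denom
                return float(np.exp(full)) if full <= obs_lp + tol else 0.0
            acc = 0.0
            hi = min(col[j], remaining)
            lo = max(0, remaining - int(col[j + 1:].sum()))
            for x in range(lo, hi + 1):
                acc += recurse_p(j + 1, remaining - x,
                                 lp + _log_binom(col[j], x))
            return acc

        return float(min(1.0, recurse_p(0, a, 0.0)))

    # Monte Carlo fallback with fixed margins
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(table.sum(axis=1), col)
    samples = sampler.rvs(n_mc, random_state=rng)
    lps = np.array([_table_logprob(t) for t in samples])
    return float((np.sum(lps <= obs_lp + tol) + 1) / (n_mc + 1))


def cluster_enrichment(labels: Sequence[int], clinical_column: pd.Series,
                       seed: int = 0) -> float:
    """Fisher exact p-value for cluster membership vs a binary clinical label.

    Units with missing clinical values are excluded before tabulation.
    """
    labels = np.asarray(labels)
    y = pd.Series(clinical_column).reset_index(drop=True)
    keep = y.notna().to_numpy()
    if not keep.any():
        raise ValueError("clinical column has no observed values")
    labels, y = labels[keep], y[keep].to_numpy(dtype=float)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters for an enrichment test")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("clinical column must be binary (0/1)")
    table = np.array([[np.sum((y == v) & (labels == c)) for c in uniq]
                      for v in (1.0, 0.0)], dtype=int)
    return fisher_exact_2xk(table, seed=seed)
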