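"""Genomic feature derivation: risk-gene expression, signature scores,
single-sample pathway activity, and first-quartile binarization.

Three categories of patient-level genomic features (GFs) are assembled from
one expression matrix:

* ``risk_gene`` — raw expression of a curated gene list;
* ``signature`` — weighted sums of gene expression (the generic contract
  behind commercial prognostic panels; weights are user-supplied);
* ``pathway`` — single-sample gene-set enrichment (ssGSEA) activity scores.

The ssGSEA statistic follows the rank-weighted running-sum definition: with
genes sorted by descending expression, the score is the sum over ranked
positions of the difference between the in-set cumulative fraction weighted
by rank^alpha and the unweighted out-of-set cumulative fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "GenomicFeatureTable",
    "read_gmt",
    "write_gmt",
    "ssgsea_score",
    "ssgsea_matrix",
    "signature_score",
    "binarize_top_quartile",
    "assemble_gf_table",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("risk_gene", "signature", "pathway")


@dataclass
class GeneSet:
    set_id: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.set_id!r} is empty")


@dataclass
class GenomicFeatureTable:
    """Patients x GFs table with a per-column category annotation."""

    values: pd.DataFrame            # patients x GFs
    categories: pd.Series           # per-column category label

    def __post_init__(self) -> None:
        if list(self.categories.index) != list(self.values.columns):
            raise ValueError("categories must be indexed by the GF columns")
        bad = set(self.categories) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown GF categories: {sorted(bad)}")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.index)

    def columns_of(self, category: str) -> list[str]:
        return list(self.categories.index[self.categories == category])

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.columns = pd.MultiIndex.from_arrays(
            [self.categories.values, out.columns], names=["category", "gf_id"])
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomicFeatureTable":
        df = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
        cats = pd.Series([c[0] for c in df.columns],
                         index=[c[1] for c in df.columns])
        df.columns = [c[1] for c in df.columns]
        return cls(values=df, categories=cats)


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets.append(GeneSet(parts[0], [g for g in parts[2:] if g]))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.set_id, "na"] + list(gs.genes)) + "\n")


def ssgsea_score(expr_sample: pd.Series, gene_set: GeneSet | Sequence[str],
                 alpha: float = 0.25) -> float:
    """Single-sample gene-set enrichment score for one patient.

    Genes are ranked by descending expression (ties broken by gene id); the
    score sums, over the ranked list, the difference between the
    rank^alpha-weighted in-set cumulative fraction and the unweighted
    out-of-set cumulative fraction.  Rank-based, hence invariant to any
    strictly increasing transform of the sample.
    """
    genes = list(gene_set.genes) if isinstance(gene_set, GeneSet) else list(gene_set)
    sample = pd.Series(expr_sample)
    in_set = sample.index.isin(set(genes))
    n = sample.size
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set has no overlap with the expressed genes")
    if n_in == n:
        raise ValueError("gene set covers every expressed gene (empty complement)")

    # descending expression, gene id as tie-break
    order = np.lexsort((np.asarray(sample.index), -sample.to_numpy(dtype=float)))
    member = in_set[order]
    ranks = np.arange(n, 0, -1, dtype=float)  # top position gets rank n
    w = ranks ** alpha
    w_in = np.where(member, w, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    out = (~member).astype(float)
    p_out = np.cumsum(out) / (n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(expr: pd.DataFrame, gene_sets: Sequence[GeneSet],
                  alpha: float = 0.25) -> pd.DataFrame:
    """Patients x gene-sets matrix of ssGSEA scores (expr is genes x patients)."""
    scores = {
        gs.set_id: [ssgsea_score(expr[p], gs, alpha=alpha) for p in expr.columns]
        for gs in gene_sets
    }
    return pd.DataFrame(scores, index=expr.columns)


def signature_score(expr: pd.DataFrame, weights: Mapping[str, float],
                    ) -> pd.Series:
    """Per-patient weighted-sum signature score (expr is genes x patients).

    Weighted genes absent from the expression matrix are logged and skipped.
    """
    present = [g for g in weights if g in expr.index]
    missing = [g for g in weights if g not in expr.index]
    if not present:
        raise ValueError("no weighted gene is present in the expression matrix")
    if missing:
        logger.warning("signature: %d weighted genes absent, skipped: %s",
                       len(missing), missing[:10])
    w = pd.Series({g: weights[g] for g in present})
    return expr.loc[present].mul(w, axis=0).sum(axis=0)


def binarize_top_quartile(scores: pd.Series) -> pd.Series:
    """Binary status with the top quarter of patients positive.

    The cut-off is the k-th largest score with k = ceil(n/4); ties at the
    cut are all positive, so the positive count is at least ceil(n/4).
    """
    scores = pd.Series(scores).astype(float)
    n = scores.size
    if n < 4:
        raise ValueError("need at least 4 patients to binarize at the quartile")
    if scores.nunique() == 1:
        raise ValueError("constant scores admit no quartile split")
    k = int(np.ceil(n / 4))
    threshold = np.sort(scores.to_numpy())[n - k]
    return (scores >= threshold).astype(int)


def assemble_gf_table(expr: pd.DataFrame,
                      risk_gene_ids: Sequence[str],
                      signature_weight_sets: Mapping[str, Mapping[str, float]]
                      | None = None,
                      pathway_sets: Sequence[GeneSet] | None = None,
                      alpha: float = 0.25) -> GenomicFeatureTable:
    """Assemble the three-category genomic feature table from expression.

    One column per risk gene (raw expression), per signature (weighted sum)
    and per pathway (ssGSEA score); patient order follows the expression
    matrix.
    """
    signature_weight_sets = signature_weight_sets or {}
    pathway_sets = pathway_sets or []

    ids = (list(risk_gene_ids) + list(signature_weight_sets)
           + [gs.set_id for gs in pathway_sets])
    dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate GF ids: {sorted(set(dupes))}")

    blocks, cats = [], []
    missing = [g for g in risk_gene_ids if g not in expr.index]
    if missing:
        raise ValueError(f"risk genes absent from expression: {missing[:10]}")
    if len(risk_gene_ids):
        blocks.append(expr.loc[list(risk_gene_ids)].T)
        cats += ["risk_gene"] * len(risk_gene_ids)
    if signature_weight_sets:
        sig = pd.DataFrame({name: signature_score(expr, w)
                            for name, w in signature_weight_sets.items()})
        blocks.append(sig)
        cats += ["signature"] * len(signature_weight_sets)
    if pathway_sets:
        blocks.append(ssgsea_matrix(expr, pathway_sets, alpha=alpha))
        cats += ["pathway"] * len(pathway_sets)

    values = pd.concat(blocks, axis=1).loc[list(expr.columns)]
    categories = pd.Series(cats, index=values.columns)
    return GenomicFeatureTable(values=values, categories=categories)
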