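"""Single-sample signature scores.

Implements the Barbie-style single-sample GSEA statistic (rank-weighted
running-sum integral, exponent ``alpha``), simple marker-mean scores (the
MCPcounter-style abundance summary), ESTIMATE-like immune/stromal scores, and
the neuroendocrine (NE) score — a correlation contrast that places a sample
on the NE → non-NE axis.

ssGSEA is computed from expression ranks only, so any strictly increasing
transform of a sample's profile leaves its scores unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix, GeneSetCollection, ValidationError


def ssgsea_score(expr_column: pd.Series, gene_set, alpha: float = 0.25) -> float:
    """Single-sample enrichment of ``gene_set`` in one expression profile.

    Genes are ranked by expression (descending; average ranks on ties). The
    score integrates, down the ranked list, the difference between the
    rank^alpha-weighted ECDF of in-set genes and the unweighted ECDF of
    out-set genes. Positive scores mean the set concentrates at the top.
    """
    expr_column = pd.Series(expr_column)
    gene_set = set(gene_set)
    if not gene_set:
        raise ValidationError("empty gene set")
    in_set = expr_column.index.isin(gene_set)
    n = len(expr_column)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValidationError("gene set has no members in the expression profile")
    if n_in == n:
        raise ValidationError("gene set covers the whole profile; no out-set genes")
    # rank value: largest expression → rank n (average ranks for ties)
    ranks = rankdata(expr_column.to_numpy(), method="average")
    order = np.argsort(-ranks, kind="stable")
    in_ord = in_set[order]
    w = ranks[order] ** alpha
    w_in = np.where(in_ord, w, 0.0)
    cdf_in = np.cumsum(w_in) / w_in.sum()
    cdf_out = np.cumsum(~in_ord) / (n - n_in)
    return float(np.sum(cdf_in - cdf_out))


def marker_mean_score(expr_column: pd.Series, marker_set) -> float:
    """Arithmetic mean expression over the markers present in the profile."""
    expr_column = pd.Series(expr_column)
    present = [g for g in marker_set if g in expr_column.index]
    if not present:
        raise ValidationError("no marker genes present in the expression profile")
    return float(expr_column.loc[present].mean())


def estimate_like_scores(expr: ExpressionMatrix, immune_set, stromal_set, alpha: float = 0.25):
    """Per-sample (immune, stromal) ssGSEA scores, ESTIMATE-style."""
    rows = []
    for s in expr.sample_ids:
        col = expr.sample_vector(s)
        rows.append(
            (ssgsea_score(col, immune_set, alpha), ssgsea_score(col, stromal_set, alpha))
        )
    return pd.DataFrame(rows, index=expr.sample_ids, columns=["immune", "stromal"])


def ne_prototypes(expr: ExpressionMatrix, ne_samples, nonne_samples, signature_genes):
    """Mean expression prototypes over signature genes from labelled samples."""
    sub = expr.subset_genes(list(signature_genes))
    ne = sub.subset_samples(list(ne_samples)).values.mean(axis=1)
    nonne = sub.subset_samples(list(nonne_samples)).values.mean(axis=1)
    return (
        pd.Series(ne, index=sub.gene_ids),
        pd.Series(nonne, index=sub.gene_ids),
    )


def ne_score(expr_column: pd.Series, ne_prototype: pd.Series, nonne_prototype: pd.Series,
             signature_genes=None) -> float:
    """NE score = (corr with NE prototype − corr with non-NE prototype) / 2.

    Bounded in [−1, 1]; +1 at the NE pole, −1 at the non-NE pole.
    """
    expr_column = pd.Series(expr_column)
    genes = list(signature_genes) if signature_genes is not None else list(ne_prototype.index)
    x = expr_column.reindex(genes).to_numpy(dtype=float)
    a = pd.Series(ne_prototype).reindex(genes).to_numpy(dtype=float)
    b = pd.Series(nonne_prototype).reindex(genes).to_numpy(dtype=float)
    if np.isnan(x).any() or np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("signature genes missing from sample or prototypes")
    if np.std(x) == 0:
        raise ValidationError("zero-variance sample vector over signature genes")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("zero-variance prototype vector")
    r_ne = float(np.corrcoef(x, a)[0, 1])
    r_nonne = float(np.corrcoef(x, b)[0, 1])
    return (r_ne - r_nonne) / 2.0


def score_table(expr: ExpressionMatrix, collection: GeneSetCollection,
                method: str = "ssgsea", alpha: float = 0.25) -> pd.DataFrame:
    """Samples × signatures score matrix using one scoring method."""
    if method not in ("ssgsea", "marker_mean"):
        raise ValidationError(f"unknown scoring method {method!r}")
    out = {}
    for name in collection.names():
        gene_set = collection[name]
        vals = []
        for s in expr.sample_ids:
            col = expr.sample_vector(s)
            if method == "ssgsea":
                vals.append(ssgsea_score(col, gene_set, alpha))
            else:
                vals.append(marker_mean_score(col, gene_set))
        out[name] = vals
    return pd.DataFrame(out, index=expr.sample_ids)
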