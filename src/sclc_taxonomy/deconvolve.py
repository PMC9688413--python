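"""Four-cell-type deconvolution and tumor-intrinsic M/I scores.

Bulk expression is modelled, on the linear TPM scale where mixing is
additive, as a non-negative combination of epithelial, fibroblast,
endothelial and immune reference profiles. Per-sample fractions come from
non-negative least squares (NNLS) on the signature genes; per-group
cell-type profiles from gene-wise NNLS on the fraction design; a per-sample
epithelial profile from residual attribution around the group profile. The
tumor-intrinsic mesenchymal (M) and inflamed (I) scores are mean log2
expression over the top differentially expressed classifier genes between
the two subtypes' epithelial profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, ValidationError

CELL_TYPES = ["epithelial", "fibroblast", "endothelial", "immune"]


def validate_signature(sig: pd.DataFrame) -> pd.DataFrame:
    """Signature matrix: genes × cell types, non-negative, with ≥1 marker
    (row maximal in that column) per cell type."""
    sig = sig.astype(float)
    if (sig < 0).any().any():
        raise ValidationError("signature matrix must be non-negative")
    top = sig.idxmax(axis=1)
    for ct in sig.columns:
        if not (top == ct).any():
            raise ValidationError(f"cell type {ct!r} has no unique positive marker gene")
    return sig


def estimate_fractions(bulk_column: pd.Series, sig: pd.DataFrame) -> pd.Series:
    """NNLS fractions of one bulk profile (linear TPM) on signature columns,
    renormalised to the unit simplex."""
    sig = validate_signature(sig)
    shared = [g for g in sig.index if g in bulk_column.index]
    sub = sig.loc[shared]
    top = sub.idxmax(axis=1)
    for ct in sig.columns:
        if (top == ct).sum() < 4:
            raise ValidationError(f"fewer than 4 signature genes present for {ct!r}")
    b = bulk_column.loc[shared].to_numpy(dtype=float)
    if not np.any(b > 0):
        raise ValidationError("bulk profile is all-zero over signature genes")
    coef, _ = nnls(sub.to_numpy(), b)
    total = coef.sum()
    if total == 0:
        raise ValidationError("NNLS returned all-zero coefficients")
    return pd.Series(coef / total, index=sig.columns, name=bulk_column.name)


def fractions_table(expr_tpm: ExpressionMatrix, sig: pd.DataFrame) -> pd.DataFrame:
    rows = [estimate_fractions(expr_tpm.sample_vector(s), sig) for s in expr_tpm.sample_ids]
    return pd.DataFrame(rows, index=expr_tpm.sample_ids)


def groupwise_expression(bulk_group: ExpressionMatrix, fractions_group: pd.DataFrame) -> pd.DataFrame:
    """Per-cell-type expression profiles of one sample group.

    For each gene, NNLS of its across-sample bulk values (linear TPM) on the
    samples × cell-types fraction matrix. A cell type whose fraction is
    constant across the group makes the design rank-deficient; it is dropped
    from the fit (profile set to 0) with a warning.
    """
    if bulk_group.n_samples < 8:
        raise ValidationError("groupwise deconvolution needs at least 8 samples")
    F = fractions_group.loc[bulk_group.sample_ids].to_numpy(dtype=float)
    cols = list(fractions_group.columns)
    keep = [j for j in range(F.shape[1]) if np.ptp(F[:, j]) > 1e-12]
    if len(keep) < F.shape[1]:
        dropped = [cols[j] for j in range(F.shape[1]) if j not in keep]
        warnings.warn(f"constant fraction column(s) dropped from group fit: {dropped}")
    if not keep:
        # every fraction constant: keep the dominant type; the per-gene fit
        # degenerates to mean(bulk)/fraction for that type
        keep = [int(np.argmax(F.mean(axis=0)))]
    Fk = F[:, keep]
    out = np.zeros((bulk_group.n_genes, F.shape[1]))
    for i in range(bulk_group.n_genes):
        coef, _ = nnls(Fk, bulk_group.values[i])
        out[i, keep] = coef
    return pd.DataFrame(out, index=bulk_group.gene_ids, columns=cols)


def epithelial_per_sample(
    bulk: ExpressionMatrix,
    fractions: pd.DataFrame,
    group_profiles: dict,
    sample_groups: dict | pd.Series,
    low_fraction: float = 0.05,
):
    """Per-sample epithelial expression by residual attribution.

    ``ê_gs = max(0, P_g,epi + w_s · r_gs)`` where ``P`` is the sample group's
    epithelial profile, ``r_gs`` the bulk residual after subtracting all
    predicted mixture components, and ``w_s = f_s,epi / Σ_c f_s,c²`` the
    epithelial share weight. Samples with epithelial fraction below
    ``low_fraction`` are flagged low-confidence.
    """
    sample_groups = pd.Series(sample_groups)
    est = np.zeros((bulk.n_genes, bulk.n_samples))
    flags = {}
    for j, s in enumerate(bulk.sample_ids):
        grp = sample_groups.loc[s]
        if grp not in group_profiles:
            raise ValidationError(f"no group profile for sample {s!r} (group {grp!r})")
        P = group_profiles[grp].reindex(bulk.gene_ids).to_numpy(dtype=float)
        f = fractions.loc[s].to_numpy(dtype=float)
        predicted = P @ f
        r = bulk.values[:, j] - predicted
        w = f[0] / max(np.sum(f**2), 1e-12)
        est[:, j] = np.maximum(0.0, P[:, 0] + w * r)
        flags[s] = bool(f[0] < low_fraction)
    return (
        pd.DataFrame(est, index=bulk.gene_ids, columns=bulk.sample_ids),
        pd.Series(flags, name="low_confidence"),
    )


@dataclass
class DifferentialExpression:
    table: pd.DataFrame          # gene, t, p, q — ranked by t descending
    up_in_a: list
    up_in_b: list
    skipped: list


def epithelial_de(
    epi_a: pd.DataFrame, epi_b: pd.DataFrame, n_classifier: int = 100
) -> DifferentialExpression:
    """Welch-t differential expression between two epithelial profile groups
    (log2 scale) with BH FDR; classifier lists are the top ``n_classifier/2``
    genes up in each direction."""
    if epi_a.shape[1] < 3 or epi_b.shape[1] < 3:
        raise ValidationError("need at least 3 samples per side")
    genes = [g for g in epi_a.index if g in set(epi_b.index)]
    A = epi_a.loc[genes].to_numpy(dtype=float)
    B = epi_b.loc[genes].to_numpy(dtype=float)
    defined = ~((A.std(axis=1) == 0) & (B.std(axis=1) == 0) & (A.mean(axis=1) == B.mean(axis=1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = ttest_ind(A, B, axis=1, equal_var=False)
    valid = np.isfinite(t) & np.isfinite(p)
    skipped = [g for g, v in zip(genes, valid & defined) if not v]
    genes_v = [g for g, v in zip(genes, valid) if v]
    t_v, p_v = t[valid], p[valid]
    q_v = multipletests(p_v, method="fdr_bh")[1]
    table = (
        pd.DataFrame({"gene": genes_v, "t": t_v, "p": p_v, "q": q_v})
        .sort_values("t", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    half = n_classifier // 2
    up_a = table.head(half)["gene"].tolist()
    up_b = table.tail(half).sort_values("t")["gene"].tolist() if len(table) else []
    up_b = [g for g in up_b if g not in set(up_a)]
    return DifferentialExpression(table=table, up_in_a=up_a, up_in_b=up_b, skipped=skipped)


def mi_intrinsic_scores(expr: ExpressionMatrix, m_up, i_up) -> pd.DataFrame:
    """M/I scores: mean log2 expression over each classifier list; the
    differential score is exactly M − I."""
    m_present = [g for g in m_up if g in expr.gene_ids]
    i_present = [g for g in i_up if g in expr.gene_ids]
    if not m_present and not i_present:
        raise ValidationError("neither classifier list is represented in the matrix")
    if not m_present or not i_present:
        raise ValidationError("one classifier list has no genes in the matrix")
    M = expr.subset_genes(m_present).values.mean(axis=0)
    I = expr.subset_genes(i_present).values.mean(axis=0)
    return pd.DataFrame(
        {"M_score": M, "I_score": I, "diff": M - I}, index=expr.sample_ids
    )


def gene_diff_correlation(expr: ExpressionMatrix, diff_scores: pd.Series) -> pd.DataFrame:
    """Per-gene Pearson correlation with the M−I differential score, with a
    two-sided t-based p-value; zero-variance genes are skipped."""
    d = pd.Series(diff_scores).reindex(expr.sample_ids).to_numpy(dtype=float)
    n = len(d)
    if n < 4:
        raise ValidationError("need at least 4 samples")
    V = expr.values
    sd_g = V.std(axis=1)
    keep = sd_g > 0
    Vc = V[keep] - V[keep].mean(axis=1, keepdims=True)
    dc = d - d.mean()
    r = (Vc @ dc) / (np.sqrt((Vc**2).sum(axis=1)) * np.sqrt((dc**2).sum()))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    from scipy.stats import t as t_dist

    p = 2 * t_dist.sf(np.abs(tstat), df=n - 2)
    return pd.DataFrame(
        {"r": r, "p": p}, index=[g for g, k in zip(expr.gene_ids, keep) if k]
    )


def _running_sum_es(order_in_set: np.ndarray, weights: np.ndarray) -> float:
    """Signed maximum deviation of the GSEA running sum."""
    w_in = np.where(order_in_set, weights, 0.0)
    tot_in = w_in.sum()
    n_out = (~order_in_set).sum()
    if tot_in == 0 or n_out == 0:
        raise ValidationError("gene set empty or covering the whole ranking")
    running = np.cumsum(w_in / tot_in - (~order_in_set) / n_out)
    return float(running[np.argmax(np.abs(running))])


def celltype_gsea(
    ranked_stats: pd.Series,
    gene_set,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
):
    """Classic GSEA enrichment of ``gene_set`` in a ranked statistic vector.

    ES is the Kolmogorov–Smirnov-style signed maximum deviation of the
    weighted running sum; the p-value comes from random gene sets of the same
    size (add-one permutation estimate, two-sided on |ES|).
    """
    stats = pd.Series(ranked_stats).sort_values(ascending=False, kind="stable")
    in_set = stats.index.isin(set(gene_set))
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValidationError("gene set has no members in the ranking")
    weights = np.abs(stats.to_numpy(dtype=float)) ** weight
    es = _running_sum_es(in_set, weights)
    rng = np.random.default_rng(seed)
    n = len(stats)
    exceed = 0
    for _ in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_in, replace=False)] = True
        if abs(_running_sum_es(perm, weights)) >= abs(es):
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return es, float(p)
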