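"""Normalisation and gene filtering.

RNA-seq counts are converted to transcripts per million (TPM) using per-gene
effective lengths, then log2(TPM + 1) transformed; the pseudocount of one
keeps the matrix non-negative, which downstream non-negative factorisation
requires. Feature selection for unsupervised analysis keeps the genes with the
largest median absolute deviation (MAD) across samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ValidationError


def counts_to_tpm(counts: ExpressionMatrix, lengths) -> ExpressionMatrix:
    """Convert raw counts to TPM.

    ``TPM_gs = 1e6 * (count_gs / length_g) / sum_g'(count_g's / length_g')``;
    every column sums to 1e6. ``lengths`` is a mapping or Series of per-gene
    lengths (any constant unit — the formula is scale-invariant).
    """
    if counts.unit != "counts":
        raise ValidationError(f"expected counts, got {counts.unit}")
    lengths = pd.Series(lengths).reindex(counts.gene_ids)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValidationError(f"missing gene lengths for {missing}")
    lv = lengths.to_numpy(dtype=float)
    if np.any(lv <= 0):
        raise ValidationError("gene lengths must be strictly positive")
    rate = counts.values / lv[:, None]
    col_tot = rate.sum(axis=0)
    zero = np.flatnonzero(col_tot == 0)
    if zero.size:
        raise ValidationError(
            f"sample(s) with zero total count: {[counts.sample_ids[j] for j in zero]}"
        )
    tpm = 1e6 * rate / col_tot
    return ExpressionMatrix(tpm, counts.gene_ids, counts.sample_ids, "TPM")


def log_transform(tpm: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    if tpm.unit != "TPM":
        raise ValidationError(f"expected TPM, got {tpm.unit}")
    return ExpressionMatrix(
        np.log2(tpm.values + pseudocount), tpm.gene_ids, tpm.sample_ids, "log2TPM"
    )


def counts_to_log_tpm(counts: ExpressionMatrix, lengths, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Counts → TPM → log2(TPM + pseudocount) in one step."""
    return log_transform(counts_to_tpm(counts, lengths), pseudocount)


def tpm_from_log(log_expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Invert the log transform (needed for linear-scale deconvolution)."""
    if log_expr.unit != "log2TPM":
        raise ValidationError(f"expected log2TPM, got {log_expr.unit}")
    vals = np.maximum(2.0 ** log_expr.values - pseudocount, 0.0)
    return ExpressionMatrix(vals, log_expr.gene_ids, log_expr.sample_ids, "TPM")


def filter_variable_genes(X: ExpressionMatrix, n_top: int) -> ExpressionMatrix:
    """Keep the ``n_top`` genes with largest MAD across samples.

    Ties are broken by gene id lexical order so the selection is deterministic.
    """
    if n_top > X.n_genes:
        raise ValidationError(f"n_top={n_top} exceeds n_genes={X.n_genes}")
    med = np.median(X.values, axis=1, keepdims=True)
    mad = np.median(np.abs(X.values - med), axis=1)
    order = sorted(range(X.n_genes), key=lambda i: (-mad[i], X.gene_ids[i]))
    keep = sorted(order[:n_top])  # preserve original gene order
    return ExpressionMatrix(
        X.values[keep], [X.gene_ids[i] for i in keep], X.sample_ids, X.unit
    )
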