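"""Pseudotime ordering and cross-species NE→non-NE concordance.

Units (deconvoluted human epithelial profiles, or mouse single cells) are
ordered along a one-dimensional principal curve fitted in PCA space by
projection-index iteration; pseudotime is the normalised rank of arc-length
position, oriented so that it anti-correlates with the neuroendocrine score
(the NE→non-NE transition runs forward in pseudotime). Cross-species
concordance is the matrix of Pearson correlations between per-unit
standardised profiles over ortholog-shared genes, with both axes sorted by
pseudotime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.decomposition import PCA

from .matrix import ExpressionMatrix, ValidationError


@dataclass
class TrajectoryResult:
    pseudotime: pd.Series            # unit → rank position in [0, 1]
    ne_scores: pd.Series
    n_iterations: int
    curve: np.ndarray                # smoothed curve nodes in PC space
    embedding: np.ndarray            # units × n_pcs PCA coordinates
    labels: pd.Series | None = None
    diagnostics: dict = field(default_factory=dict)


def _smooth_curve(Y: np.ndarray, order: np.ndarray, window: int) -> np.ndarray:
    """Running-mean smoothing of coordinates along the current ordering."""
    n = len(order)
    sorted_Y = Y[order]
    half = max(1, window // 2)
    cum = np.vstack([np.zeros(Y.shape[1]), np.cumsum(sorted_Y, axis=0)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cum[hi] - cum[lo]) / (hi - lo)[:, None]


def _project_to_curve(Y: np.ndarray, curve: np.ndarray) -> np.ndarray:
    """Arc-length position of each point's projection onto the polyline."""
    seg = np.diff(curve, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    arc0 = np.concatenate([[0.0], np.cumsum(seg_len)])
    pos = np.empty(len(Y))
    for i, y in enumerate(Y):
        d = y[None, :] - curve[:-1]
        denom = np.maximum((seg**2).sum(axis=1), 1e-12)
        t = np.clip((d * seg).sum(axis=1) / denom, 0.0, 1.0)
        proj = curve[:-1] + t[:, None] * seg
        dist2 = ((y[None, :] - proj) ** 2).sum(axis=1)
        j = int(np.argmin(dist2))
        pos[i] = arc0[j] + t[j] * seg_len[j]
    return pos


def infer_pseudotime(
    X,
    ne_scores,
    n_pcs: int = 3,
    window_frac: float = 0.3,
    max_iter: int = 10,
    unit_ids=None,
) -> TrajectoryResult:
    """Principal-curve pseudotime of a genes × units matrix.

    Genes are standardised, units embedded by PCA (``n_pcs`` components), and
    a principal curve fitted by alternating running-mean smoothing along the
    current ordering with re-projection of units onto the smoothed polyline.
    Pseudotime is the normalised rank of arc-length position, flipped when it
    correlates positively with the NE score.
    """
    if isinstance(X, ExpressionMatrix):
        V, units = X.values, X.sample_ids
    elif isinstance(X, pd.DataFrame):
        V, units = X.to_numpy(dtype=float), list(X.columns)
    else:
        V = np.asarray(X, dtype=float)
        units = list(unit_ids) if unit_ids is not None else list(range(V.shape[1]))
    n = V.shape[1]
    if n < 10:
        raise ValidationError("pseudotime inference needs at least 10 units")
    if n < n_pcs + 1:
        raise ValidationError(f"need more than n_pcs+1={n_pcs + 1} units")
    ne = pd.Series(ne_scores)
    ne = ne.reindex(units) if not isinstance(ne.index, pd.RangeIndex) else pd.Series(
        ne.to_numpy(), index=units
    )

    sd = V.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    Z = (V[keep] - V[keep].mean(axis=1, keepdims=True)) / sd[keep]
    n_pcs_eff = min(n_pcs, Z.shape[0], n - 1)
    Y = PCA(n_components=n_pcs_eff, random_state=0).fit_transform(Z.T)

    window = max(3, int(round(window_frac * n)))
    lam = Y[:, 0].copy()           # projection-index init on PC1
    order = np.argsort(lam, kind="stable")
    n_it = 0
    for n_it in range(1, max_iter + 1):
        curve = _smooth_curve(Y, order, window)
        lam = _project_to_curve(Y, curve)
        new_order = np.argsort(lam, kind="stable")
        if np.array_equal(new_order, order):
            break
        order = new_order
    ranks = np.empty(n)
    ranks[order] = np.arange(n)
    pt = ranks / max(n - 1, 1)
    valid_ne = ne.notna().to_numpy()
    if valid_ne.sum() >= 3 and np.std(ne.to_numpy()[valid_ne]) > 0:
        c = np.corrcoef(pt[valid_ne], ne.to_numpy()[valid_ne])[0, 1]
        if c > 0:
            pt = 1.0 - pt
    return TrajectoryResult(
        pseudotime=pd.Series(pt, index=units, name="pseudotime"),
        ne_scores=ne,
        n_iterations=n_it,
        curve=curve,
        embedding=Y,
    )


def crossspecies_concordance(
    human_epi: pd.DataFrame,
    mouse_expr: pd.DataFrame,
    ortholog_map: pd.DataFrame | dict,
    human_pt: pd.Series,
    mouse_pt: pd.Series,
    min_shared: int = 50,
) -> pd.DataFrame:
    """Human-units × mouse-units Pearson correlation matrix over shared genes.

    ``ortholog_map`` maps human gene id → mouse gene id (two-column frame or
    dict). Each unit's shared-gene vector is standardised before correlation;
    rows and columns are sorted by their pseudotime.
    """
    if isinstance(ortholog_map, pd.DataFrame):
        pairs = dict(zip(ortholog_map.iloc[:, 0].astype(str), ortholog_map.iloc[:, 1].astype(str)))
    else:
        pairs = {str(k): str(v) for k, v in ortholog_map.items()}
    shared = [
        (h, m) for h, m in pairs.items() if h in human_epi.index and m in mouse_expr.index
    ]
    if not shared:
        raise ValidationError("empty ortholog intersection")
    if len(shared) < min_shared:
        raise ValidationError(f"only {len(shared)} shared genes after mapping (< {min_shared})")
    hg = [h for h, _ in shared]
    mg = [m for _, m in shared]
    H = human_epi.loc[hg].to_numpy(dtype=float)
    M = mouse_expr.loc[mg].to_numpy(dtype=float)

    def _std_cols(A):
        A = A - A.mean(axis=0, keepdims=True)
        sd = A.std(axis=0, keepdims=True)
        return A / np.where(sd == 0, 1.0, sd)

    corr = _std_cols(H).T @ _std_cols(M) / len(shared)
    corr = np.clip(corr, -1.0, 1.0)
    h_order = pd.Series(human_pt).reindex(human_epi.columns).sort_values(kind="stable").index
    m_order = pd.Series(mouse_pt).reindex(mouse_expr.columns).sort_values(kind="stable").index
    out = pd.DataFrame(corr, index=human_epi.columns, columns=mouse_expr.columns)
    return out.loc[h_order, m_order]


def subtype_occurrence(labels, pseudotime, n_bins: int = 5):
    """Per-pseudotime-bin subtype frequencies and per-subtype median pseudotime."""
    if n_bins < 2:
        raise ValidationError("need at least 2 bins")
    labels = pd.Series(labels)
    pt = pd.Series(pseudotime)
    pt = pt.reindex(labels.index) if labels.index.equals(pt.index) else pd.Series(
        pt.to_numpy(), index=labels.index
    )
    bins = np.clip((pt.to_numpy() * n_bins).astype(int), 0, n_bins - 1)
    freq = pd.crosstab(labels, bins, normalize="columns")
    freq = freq.reindex(columns=range(n_bins), fill_value=0.0)
    medians = pt.groupby(labels).median().sort_values()
    return freq, medians


def marker_trends(
    expr: pd.DataFrame,
    pseudotime: pd.Series,
    marker_sets: dict,
    window_frac: float = 0.2,
) -> dict:
    """Smoothed marker-set mean expression along pseudotime.

    Each set's per-unit mean is ordered by pseudotime and smoothed with a
    centred running average whose window is ``window_frac`` of the range
    (the full-range window returns the global mean everywhere). Monotonicity
    is summarised by the Spearman rho of the unsmoothed means vs pseudotime.
    """
    pt = pd.Series(pseudotime).reindex(expr.columns)
    order = np.argsort(pt.to_numpy(), kind="stable")
    n = len(order)
    out = {}
    for name, markers in marker_sets.items():
        present = [g for g in markers if g in expr.index]
        if not present:
            raise ValidationError(f"no markers of set {name!r} present")
        means = expr.loc[present].mean(axis=0).to_numpy(dtype=float)
        sorted_means = means[order]
        if window_frac >= 1.0:
            trend = np.full(n, sorted_means.mean())
        else:
            half = max(1, int(round(window_frac * n / 2)))
            cum = np.concatenate([[0.0], np.cumsum(sorted_means)])
            lo = np.maximum(np.arange(n) - half, 0)
            hi = np.minimum(np.arange(n) + half + 1, n)
            trend = (cum[hi] - cum[lo]) / (hi - lo)
        if np.std(means) == 0:
            rho = 0.0
        else:
            rho = float(spearmanr(pt.to_numpy()[order], sorted_means).statistic)
        out[name] = {
            "pseudotime": pt.to_numpy()[order],
            "trend": trend,
            "rho": rho,
        }
    return out
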