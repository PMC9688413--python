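"""Co-expression regulon inference and subtype–regulon enrichment.

A simplified, fully documented ARACNe-style procedure: pairwise mutual
information (MI) between each candidate regulator and every gene, estimated
by a plug-in estimator on equal-frequency bins; a permutation null on
shuffled pairs sets the edge-retention threshold; the data-processing
inequality (DPI) removes the weakest edge of each MI triangle as likely
indirect. Subtype specificity of a regulon is then scored by a one-sided
Fisher exact test on the overlap between subtype-specific genes and the
regulon's targets, reported as −log10 p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata

from .matrix import ExpressionMatrix, ValidationError


def _default_bins(n: int) -> int:
    return int(np.clip(int(np.sqrt(n / 5)), 2, 10))


def _equal_freq_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value to one of ``n_bins`` equal-frequency bins.

    Average ranks keep tied values in the same bin.
    """
    n = len(x)
    ranks = rankdata(x, method="average")
    return np.clip(((ranks - 0.5) * n_bins / n).astype(int), 0, n_bins - 1)


def mutual_information(x, y, n_bins: int | None = None) -> float:
    """Plug-in MI (nats) between two samples on equal-frequency bins.

    Default ``n_bins = floor(sqrt(n/5))`` clamped to [2, 10]. A constant
    vector has zero MI by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 8:
        raise ValidationError("need at least 8 observations for MI estimation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    if n_bins is None:
        n_bins = _default_bins(n)
    bx = _equal_freq_bins(x, n_bins)
    by = _equal_freq_bins(y, n_bins)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (bx, by), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mask = joint > 0
    outer = px[:, None] * py[None, :]
    return float(np.sum(joint[mask] * np.log(joint[mask] / outer[mask])))


@dataclass
class Regulon:
    """A regulator with its inferred targets and MI edge weights."""

    regulator: str
    targets: set
    mi_weights: dict

    def __post_init__(self) -> None:
        if self.regulator in self.targets:
            raise ValidationError("regulator cannot be its own target")


def build_network(
    expr: ExpressionMatrix,
    regulator_list,
    n_perm: int = 200,
    seed: int = 0,
    fdr_q: float = 0.05,
    n_bins: int | None = None,
) -> pd.DataFrame:
    """MI edges between regulators and genes, thresholded by a permutation null.

    The null distribution pools MI values of randomly chosen
    (regulator, gene) pairs with one member shuffled across samples; edges
    with MI above the null's (1 − fdr_q) quantile are retained. Returns a
    DataFrame with columns (regulator, target, mi); the threshold is stored
    in ``df.attrs["threshold"]``.
    """
    regulator_list = list(regulator_list)
    if not regulator_list:
        raise ValidationError("empty regulator list")
    missing = [r for r in regulator_list if r not in expr.gene_ids]
    if missing:
        raise ValidationError(f"regulators not present in expression matrix: {missing}")
    rng = np.random.default_rng(seed)
    V = expr.values
    gidx = {g: i for i, g in enumerate(expr.gene_ids)}

    null = np.empty(n_perm)
    for p in range(n_perm):
        r = regulator_list[rng.integers(len(regulator_list))]
        j = rng.integers(expr.n_genes)
        y = V[j, rng.permutation(expr.n_samples)]
        null[p] = mutual_information(V[gidx[r]], y, n_bins)
    threshold = float(np.quantile(null, 1.0 - fdr_q))

    rows = []
    for r in regulator_list:
        xr = V[gidx[r]]
        for g in expr.gene_ids:
            if g == r:
                continue
            mi = mutual_information(xr, V[gidx[g]], n_bins)
            if mi > threshold:
                rows.append((r, g, mi))
    df = pd.DataFrame(rows, columns=["regulator", "target", "mi"])
    df.attrs["threshold"] = threshold
    return df


def dpi_prune(edges: pd.DataFrame, tolerance: float = 0.0) -> pd.DataFrame:
    """Data-processing-inequality pruning of an MI edge list.

    For every triangle of edges, the weakest edge is removed when its MI is
    below ``(1 − tolerance) ×`` the smaller of the other two; ``tolerance=1``
    disables pruning. Removal decisions are evaluated on the input graph, so
    the operation is idempotent at fixed tolerance.
    """
    if edges.empty:
        return edges.copy()
    mi_of: dict = {}
    adj: dict = {}
    for a, b, w in edges[["regulator", "target", "mi"]].itertuples(index=False):
        key = frozenset((a, b))
        mi_of[key] = float(w)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    to_remove: set = set()
    for key in list(mi_of):
        a, b = tuple(key)
        for c in adj[a] & adj[b]:
            trio = [(mi_of[key], key),
                    (mi_of[frozenset((a, c))], frozenset((a, c))),
                    (mi_of[frozenset((b, c))], frozenset((b, c)))]
            trio.sort(key=lambda t: t[0])
            weakest_mi, weakest = trio[0]
            if weakest_mi < (1.0 - tolerance) * trio[1][0]:
                to_remove.add(weakest)
    keep = [
        frozenset((a, b)) not in to_remove
        for a, b in edges[["regulator", "target"]].itertuples(index=False)
    ]
    out = edges.loc[keep].reset_index(drop=True)
    out.attrs = dict(edges.attrs)
    return out


def edges_to_regulons(edges: pd.DataFrame) -> list:
    regs = []
    for r, grp in edges.groupby("regulator", sort=True):
        regs.append(
            Regulon(
                regulator=r,
                targets=set(grp["target"]),
                mi_weights=dict(zip(grp["target"], grp["mi"])),
            )
        )
    return regs


def regulon_enrichment(subtype_genes, regulon: Regulon, universe) -> dict:
    """One-sided Fisher exact test (hypergeometric upper tail) of the overlap
    between subtype-specific genes and regulon targets."""
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    S = set(subtype_genes) & universe
    T = regulon.targets & universe
    k = len(S & T)
    M, n, N = len(universe), len(T), len(S)
    p = float(hypergeom.sf(k - 1, M, n, N))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return {
        "regulator": regulon.regulator,
        "overlap": k,
        "p_value": p,
        "neg_log10_p": float(-np.log10(p)),
    }


def enrichment_table(subtype_gene_sets: dict, regulons, universe) -> pd.DataFrame:
    """All subtype × regulon Fisher enrichments, one row each."""
    rows = []
    for subtype, genes in subtype_gene_sets.items():
        for reg in regulons:
            row = regulon_enrichment(genes, reg, universe)
            row["subtype"] = subtype
            rows.append(row)
    return pd.DataFrame(rows)[
        ["subtype", "regulator", "overlap", "p_value", "neg_log10_p"]
    ]
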