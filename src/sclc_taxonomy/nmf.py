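"""Consensus non-negative matrix factorization with cophenetic rank selection.

The factorization minimises the generalized Kullback–Leibler divergence
``D(V || WH) = Σ v log(v/ŵh) − v + ŵh`` by multiplicative updates (the
Brunet-style NMF used for tumor subtyping). Cluster stability at each rank K
is measured by consensus clustering over random gene subsamples: samples are
co-clustered when the same metagene dominates their H column, the consensus
matrix averages co-clustering over subsamples, and its cophenetic correlation
coefficient quantifies how tree-like (stable) the consensus is. A permutation
null — every gene's values shuffled independently across samples — yields a
5–95% band of cophenetic scores against which the observed curve is compared,
and the rank is selected by the "last supported K before a substantial drop"
rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from .matrix import ExpressionMatrix, ValidationError

_EPS = 1e-10


@dataclass
class NMFFactors:
    """Result of one NMF run: ``V ≈ W @ H`` with non-negative factors."""

    W: np.ndarray                  # genes × K metagenes, columns unit L1
    H: np.ndarray                  # K × samples loadings
    objective: np.ndarray          # KL divergence at each recorded iteration
    n_iter: int
    seed: int
    converged: bool


def _as_array(X) -> np.ndarray:
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    if V.ndim != 2:
        raise ValidationError("expression input must be 2-D")
    if np.any(V < 0):
        raise ValidationError("NMF requires a non-negative matrix")
    return np.asarray(V, dtype=float)


def _kl_divergence(V, WH) -> float:
    mask = V > 0
    div = np.sum(V[mask] * np.log(V[mask] / WH[mask])) - V.sum() + WH.sum()
    return float(div)


def _nndsvda_init(V, K):
    """NNDSVDa initialisation (Boutsidis & Gallopoulos): non-negative parts of
    the leading singular vectors, zeros filled with the matrix mean."""
    U, S, Vt = np.linalg.svd(V, full_matrices=False)
    W = np.zeros((V.shape[0], K))
    H = np.zeros((K, V.shape[1]))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, K):
        u, v = U[:, j], Vt[j, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        pos = np.linalg.norm(up) * np.linalg.norm(vp)
        neg = np.linalg.norm(un) * np.linalg.norm(vn)
        if pos >= neg:
            uu, vv, sig = up, vp, pos
        else:
            uu, vv, sig = un, vn, neg
        if sig > 0:
            W[:, j] = np.sqrt(S[j] * sig) * uu / np.linalg.norm(uu)
            H[j, :] = np.sqrt(S[j] * sig) * vv / np.linalg.norm(vv)
    mean = V.mean()
    W[W <= 0] = mean
    H[H <= 0] = mean
    return W, H


def _kmeans_init(V, K, rng):
    """Cluster samples (k-means on gene-standardised profiles) and seed W with
    cluster means, H with soft memberships."""
    from sklearn.cluster import KMeans

    sd = np.maximum(V.std(axis=1, keepdims=True), 1e-9)
    Z = (V - V.mean(axis=1, keepdims=True)) / sd
    km = KMeans(n_clusters=K, n_init=1, random_state=int(rng.integers(2**31)))
    labels = km.fit_predict(Z.T)
    W = np.column_stack(
        [
            V[:, labels == k].mean(axis=1) if np.any(labels == k) else V.mean(axis=1)
            for k in range(K)
        ]
    )
    H = np.full((K, V.shape[1]), 0.01)
    H[labels, np.arange(V.shape[1])] = 1.0
    return W, H


def _kl_nmf_single(V, K, rng, max_iter, tol, trace_every, init="random"):
    g, n = V.shape
    if init == "nndsvda":
        W, H = _nndsvda_init(V, K)
        W = W + _EPS
        H = H + _EPS
    elif init == "kmeans":
        W, H = _kmeans_init(V, K, rng)
        W = W + _EPS
        H = H + _EPS
    else:
        scale = np.sqrt(V.mean() / K)
        W = rng.random((g, K)) * scale + _EPS
        H = rng.random((K, n)) * scale + _EPS
    trace = []
    prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        WH = W @ H
        np.maximum(WH, _EPS, out=WH)
        # H update
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = W @ H
        np.maximum(WH, _EPS, out=WH)
        # W update
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        if it % trace_every == 0 or it == max_iter:
            WH = W @ H
            np.maximum(WH, _EPS, out=WH)
            obj = _kl_divergence(V, WH)
            trace.append(obj)
            if np.isfinite(prev) and prev > 0 and (prev - obj) / max(prev, _EPS) < tol:
                converged = True
                break
            prev = obj
    return W, H, np.asarray(trace), it, converged


def nmf_factorize(
    X,
    K: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    n_restarts: int = 1,
    trace_every: int = 1,
) -> NMFFactors:
    """KL-divergence NMF by multiplicative updates.

    The first start is k-means-seeded (cluster means of the sample partition
    found on gene-standardised profiles — a standard NMF initialisation that
    lands the updates in a partition-shaped basin); the remaining
    ``n_restarts − 1`` starts are random. The best final objective is kept. ``W`` columns are rescaled to unit L1 with
    the inverse scale absorbed into ``H``, so metagene loadings are
    comparable across runs. The recorded objective trace is non-increasing.
    """
    V = _as_array(X)
    if not (1 <= K <= min(V.shape)):
        raise ValidationError(f"K={K} must lie in [1, min(dims)={min(V.shape)}]")
    ss = np.random.SeedSequence(seed)
    best = None
    inits = ["kmeans"] * max(1, n_restarts)
    for init, child in zip(inits, ss.spawn(len(inits))):
        rng = np.random.default_rng(child)
        W, H, trace, it, conv = _kl_nmf_single(V, K, rng, max_iter, tol, trace_every, init)
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace, it, conv)
    W, H, trace, it, conv = best
    col = W.sum(axis=0)
    col = np.where(col <= 0, 1.0, col)
    W = W / col[None, :]
    H = H * col[:, None]
    return NMFFactors(W=W, H=H, objective=trace, n_iter=it, seed=seed, converged=conv)


def assign_clusters(H: np.ndarray) -> np.ndarray:
    """Hard label per sample = argmax metagene loading (ties → lower index)."""
    return np.argmax(np.asarray(H), axis=0)


def extract_metagene_genes(W: np.ndarray, k: int, n_top: int, gene_ids) -> list:
    """Top ``n_top`` genes most specific to metagene ``k``.

    Each gene's W row is z-scored across the K metagenes and genes are ranked
    by the z of column ``k``, so ubiquitously high-loading genes do not
    dominate; ties break on gene id.
    """
    W = np.asarray(W, dtype=float)
    mu = W.mean(axis=1, keepdims=True)
    sd = W.std(axis=1, keepdims=True)
    z = (W - mu) / np.where(sd == 0, 1.0, sd)
    gene_ids = list(gene_ids)
    order = sorted(range(len(gene_ids)), key=lambda i: (-z[i, k], gene_ids[i]))
    return [gene_ids[i] for i in order[:n_top]]


def connectivity_matrix(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    return (labels[:, None] == labels[None, :]).astype(float)


def consensus_matrix(
    X,
    K: int,
    n_subsamples: int = 50,
    subsample_frac: float = 0.65,
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> np.ndarray:
    """Mean co-clustering over NMF runs on random gene subsamples.

    Each subsample keeps ``subsample_frac`` of the genes and all samples, so
    the consensus is over a fixed sample set; entries lie in [0, 1] with unit
    diagonal and exact symmetry.
    """
    V = _as_array(X)
    if n_subsamples < 2:
        raise ValidationError("n_subsamples must be >= 2")
    if not (0 < subsample_frac <= 1):
        raise ValidationError("subsample_frac must lie in (0, 1]")
    g, n = V.shape
    n_keep = max(K, int(round(subsample_frac * g)))
    ss = np.random.SeedSequence(seed)
    C = np.zeros((n, n))
    for child in ss.spawn(n_subsamples):
        rng = np.random.default_rng(child)
        rows = rng.choice(g, size=n_keep, replace=False)
        sub_seed = int(rng.integers(0, 2**31))
        fac = nmf_factorize(
            V[np.sort(rows)], K, seed=sub_seed, max_iter=max_iter, tol=tol,
            n_restarts=n_restarts, trace_every=10,
        )
        C += connectivity_matrix(assign_clusters(fac.H))
    C /= n_subsamples
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return C


def cophenetic_coefficient(C: np.ndarray) -> float:
    """Cophenetic correlation of the consensus dissimilarity ``D = 1 − C``.

    Average-linkage hierarchical clustering of D; returns the Pearson
    correlation between the dendrogram's cophenetic distances and D over all
    sample pairs. Undefined (error) when D is constant.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValidationError("consensus matrix must be square")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    d = squareform(np.maximum(D, 0.0), checks=False)
    if np.ptp(d) == 0:
        raise ValidationError("cophenetic coefficient undefined: constant dissimilarities")
    Z = average(d)
    coph = cophenet(Z)
    if np.ptp(coph) == 0:
        raise ValidationError("cophenetic coefficient undefined: constant cophenetic distances")
    return float(np.corrcoef(d, coph)[0, 1])


def permutation_band(
    X,
    K_range,
    n_perm: int = 20,
    n_subsamples: int = 10,
    seed: int = 0,
    subsample_frac: float = 0.65,
    n_restarts: int = 1,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> dict:
    """Null 5th/95th percentile band of cophenetic scores per K.

    Each permutation shuffles every gene's values independently across
    samples (gene marginals preserved, sample structure destroyed), then the
    consensus → cophenetic pipeline is re-run. Returns ``{K: (p5, p95)}``.
    """
    V = _as_array(X)
    K_range = list(K_range)
    ss = np.random.SeedSequence(seed)
    null = {K: [] for K in K_range}
    for child in ss.spawn(n_perm):
        rng = np.random.default_rng(child)
        perm = np.empty_like(V)
        for i in range(V.shape[0]):
            perm[i] = V[i, rng.permutation(V.shape[1])]
        for K in K_range:
            C = consensus_matrix(
                perm, K, n_subsamples=n_subsamples, subsample_frac=subsample_frac,
                seed=int(rng.integers(0, 2**31)), n_restarts=n_restarts,
                max_iter=max_iter, tol=tol,
            )
            null[K].append(cophenetic_coefficient(C))
    return {
        K: (float(np.percentile(v, 5)), float(np.percentile(v, 95)))
        for K, v in null.items()
    }


def select_rank(rho: dict, band: dict | None = None, drop_threshold: float = 0.02) -> dict:
    """Pick K* from the per-K cophenetic curve.

    K* is the largest K (with a successor in the scanned range) whose score
    clears the null 95th percentile and is followed by a drop of at least
    ``drop_threshold``; if no K qualifies, K* falls back to argmax ρ (smallest
    K on ties). Returns the selected rank plus the decision trail.
    """
    Ks = sorted(rho)
    if len(Ks) < 3:
        raise ValidationError("need at least 3 K values to select a rank")
    if any(b - a != 1 for a, b in zip(Ks, Ks[1:])):
        raise ValidationError("K range must be contiguous")
    qualifying = []
    for K in Ks[:-1]:
        above = True if band is None else rho[K] >= band[K][1]
        drop = rho[K] - rho[K + 1]
        if above and drop >= drop_threshold:
            qualifying.append(K)
    if qualifying:
        selected = max(qualifying)
        rule = "largest K with rho >= null p95 and drop >= threshold"
    else:
        best = max(rho.values())
        selected = min(K for K in Ks if rho[K] == best)
        rule = "fallback: argmax rho (no K qualified)"
    return {
        "selected_rank": int(selected),
        "rule": rule,
        "drop_threshold": drop_threshold,
        "qualifying": qualifying,
    }


@dataclass
class ConsensusResult:
    """Full rank-scan output: per-K consensus, stability curve, chosen K."""

    consensus: dict                       # K → samples × samples matrix
    cophenetic: dict                      # K → rho
    band: dict                            # K → (p5, p95) null percentiles
    selected_rank: int
    selection: dict                       # decision trail from select_rank
    labels: np.ndarray                    # final labels at K*
    factors: NMFFactors                   # full-data factorization at K*
    sample_ids: list = field(default_factory=list)


def run_rank_scan(
    X,
    k_min: int = 2,
    k_max: int = 10,
    n_subsamples: int = 50,
    n_perm: int = 20,
    seed: int = 0,
    subsample_frac: float = 0.65,
    drop_threshold: float = 0.02,
    n_restarts: int = 3,
    null_subsamples: int = 10,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> ConsensusResult:
    """Consensus NMF over K = k_min..k_max, permutation band, rank selection,
    and a final full-data factorization at the selected rank."""
    V = _as_array(X)
    sample_ids = X.sample_ids if isinstance(X, ExpressionMatrix) else []
    ss = np.random.SeedSequence(seed)
    s_cons, s_perm, s_final = ss.spawn(3)
    K_range = list(range(k_min, k_max + 1))
    consensus = {}
    rho = {}
    for K, child in zip(K_range, s_cons.spawn(len(K_range))):
        C = consensus_matrix(
            V, K, n_subsamples=n_subsamples, subsample_frac=subsample_frac,
            seed=int(np.random.default_rng(child).integers(0, 2**31)),
            n_restarts=n_restarts, max_iter=max_iter, tol=tol,
        )
        consensus[K] = C
        rho[K] = cophenetic_coefficient(C)
    band = permutation_band(
        V, K_range, n_perm=n_perm, n_subsamples=null_subsamples,
        seed=int(np.random.default_rng(s_perm).integers(0, 2**31)),
        subsample_frac=subsample_frac, max_iter=max_iter, tol=tol,
    )
    selection = select_rank(rho, band, drop_threshold=drop_threshold)
    K_star = selection["selected_rank"]
    factors = nmf_factorize(
        V, K_star, seed=int(np.random.default_rng(s_final).integers(0, 2**31)),
        max_iter=max(max_iter, 500), tol=tol / 10, n_restarts=max(n_restarts, 3),
        trace_every=10,
    )
    return ConsensusResult(
        consensus=consensus,
        cophenetic=rho,
        band=band,
        selected_rank=K_star,
        selection=selection,
        labels=assign_clusters(factors.H),
        factors=factors,
        sample_ids=sample_ids,
    )
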