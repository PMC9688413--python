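"""Nearest-shrunken-centroid (PAM-style) subtype classifier.

Standardised class-centroid deviations are soft-thresholded by a shrinkage
amount Δ (Tibshirani's prediction analysis of microarrays); Δ is chosen by
stratified cross-validation, preferring the largest Δ (fewest genes) among
ties. Prediction uses the shrunken-centroid discriminant

    δ_k(x) = Σ_i (x_i − c̄'_ik)² / (s_i + s0)² − 2 log π_k

with soft class probabilities via softmax(−δ/2). For cross-cohort
application, new-cohort genes are median-shifted onto the training scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .matrix import ExpressionMatrix, ValidationError


@dataclass
class NSCModel:
    genes: list
    classes: list
    overall_centroid: np.ndarray          # per gene
    shrunken_centroids: np.ndarray        # genes × classes
    s: np.ndarray                         # pooled within-class sd per gene
    s0: float
    delta: float
    priors: np.ndarray
    train_medians: np.ndarray             # per gene, for cross-cohort median shift
    cv_errors: dict = field(default_factory=dict)

    def n_active_genes(self) -> int:
        dev = self.shrunken_centroids - self.overall_centroid[:, None]
        return int(np.sum(np.any(np.abs(dev) > 1e-12, axis=1)))

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes,
            "classes": self.classes,
            "overall_centroid": self.overall_centroid.tolist(),
            "shrunken_centroids": self.shrunken_centroids.tolist(),
            "s": self.s.tolist(),
            "s0": self.s0,
            "delta": self.delta,
            "priors": self.priors.tolist(),
            "train_medians": self.train_medians.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "NSCModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            genes=d["genes"],
            classes=d["classes"],
            overall_centroid=np.asarray(d["overall_centroid"]),
            shrunken_centroids=np.asarray(d["shrunken_centroids"]),
            s=np.asarray(d["s"]),
            s0=float(d["s0"]),
            delta=float(d["delta"]),
            priors=np.asarray(d["priors"]),
            train_medians=np.asarray(d["train_medians"]),
        )


def _centroid_stats(V: np.ndarray, y: np.ndarray, classes: list):
    n = V.shape[1]
    K = len(classes)
    overall = V.mean(axis=1)
    centroids = np.column_stack([V[:, y == c].mean(axis=1) for c in classes])
    nk = np.array([(y == c).sum() for c in classes])
    ss = np.zeros(V.shape[0])
    for j, c in enumerate(classes):
        ss += ((V[:, y == c] - centroids[:, [j]]) ** 2).sum(axis=1)
    s = np.sqrt(ss / max(n - K, 1))
    s0 = float(np.median(s))
    mk = np.sqrt(np.maximum(1.0 / nk - 1.0 / n, 1e-12))
    d = (centroids - overall[:, None]) / (mk[None, :] * (s + s0)[:, None])
    return overall, centroids, s, s0, mk, d


def _shrink(overall, s, s0, mk, d, delta):
    d_shr = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    return overall[:, None] + mk[None, :] * (s + s0)[:, None] * d_shr


def _discriminant(V, centroids, s, s0, priors):
    # V: genes × samples; centroids: genes × classes
    denom = (s + s0) ** 2
    delta_scores = np.empty((V.shape[1], centroids.shape[1]))
    for k in range(centroids.shape[1]):
        delta_scores[:, k] = (
            ((V - centroids[:, [k]]) ** 2 / denom[:, None]).sum(axis=0)
            - 2.0 * np.log(priors[k])
        )
    return delta_scores


def train(
    X: ExpressionMatrix,
    labels,
    delta_grid=None,
    cv_folds: int = 10,
    seed: int = 0,
    priors: str = "uniform",
) -> NSCModel:
    """Fit the classifier and pick Δ by stratified cross-validation."""
    y = np.asarray(list(labels))
    if len(y) != X.n_samples:
        raise ValidationError("labels length must match sample count")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    tiny = [c for c, k in counts.items() if k < 2]
    if tiny:
        raise ValidationError(f"class(es) with fewer than 2 samples: {tiny}")

    V = X.values
    overall, centroids, s, s0, mk, d = _centroid_stats(V, y, classes)
    if delta_grid is None:
        delta_grid = np.linspace(0.0, float(np.abs(d).max()), 30)
    pri = (
        np.full(len(classes), 1.0 / len(classes))
        if priors == "uniform"
        else np.array([counts[c] / len(y) for c in classes])
    )

    n_folds = min(cv_folds, min(counts.values()))
    cv_err = {float(dl): 0 for dl in delta_grid}
    if n_folds >= 2:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for tr_idx, te_idx in skf.split(V.T, y):
            ov, _, s_f, s0_f, mk_f, d_f = _centroid_stats(V[:, tr_idx], y[tr_idx], classes)
            for dl in delta_grid:
                shr = _shrink(ov, s_f, s0_f, mk_f, d_f, dl)
                scores = _discriminant(V[:, te_idx], shr, s_f, s0_f, pri)
                pred = np.asarray(classes)[np.argmin(scores, axis=1)]
                cv_err[float(dl)] += int((pred != y[te_idx]).sum())
    best_err = min(cv_err.values())
    best_delta = max(dl for dl, e in cv_err.items() if e == best_err)  # ties → fewest genes

    shrunken = _shrink(overall, s, s0, mk, d, best_delta)
    return NSCModel(
        genes=list(X.gene_ids),
        classes=classes,
        overall_centroid=overall,
        shrunken_centroids=shrunken,
        s=s,
        s0=s0,
        delta=float(best_delta),
        priors=pri,
        train_medians=np.median(V, axis=1),
        cv_errors=cv_err,
    )


def predict(model: NSCModel, X_new: ExpressionMatrix, harmonize: bool = True):
    """Classify new samples; returns (labels, probabilities DataFrame).

    Model genes absent from the new cohort are imputed at the overall
    centroid (an error when more than half are missing). With
    ``harmonize=True`` each gene is median-shifted onto the training scale.
    """
    idx = {g: i for i, g in enumerate(X_new.gene_ids)}
    present = [g for g in model.genes if g in idx]
    if len(present) < 0.5 * len(model.genes):
        raise ValidationError(
            f"only {len(present)}/{len(model.genes)} model genes present in new cohort"
        )
    V = np.tile(model.overall_centroid[:, None], (1, X_new.n_samples))
    rows_model = [i for i, g in enumerate(model.genes) if g in idx]
    rows_new = [idx[model.genes[i]] for i in rows_model]
    V[rows_model] = X_new.values[rows_new]
    if harmonize and X_new.n_samples > 1:
        new_med = np.median(V[rows_model], axis=1)
        V[rows_model] += (model.train_medians[rows_model] - new_med)[:, None]

    scores = _discriminant(V, model.shrunken_centroids, model.s, model.s0, model.priors)
    labels = [model.classes[k] for k in np.argmin(scores, axis=1)]
    logits = -scores / 2.0
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    prob_df = pd.DataFrame(probs, index=X_new.sample_ids, columns=model.classes)
    return labels, prob_df
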