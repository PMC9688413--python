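"""Survival comparison and the IHC arm.

Kaplan–Meier curves and the k-group log-rank test compare overall survival
across molecular subtypes. The immunohistochemistry (IHC) arm reduces each
tumor to an H-score (percent vimentin-positive cells × staining intensity,
0–300) and a CD8+ TIL score (mean of five high-power-field counts); any
vimentin positivity combined with a low CD8 score calls the tumor SCLC-M,
vimentin-positive/CD8-high calls SCLC-I, and vimentin-negative tumors are
left as "other". Group comparisons of CD8 scores use the Mann–Whitney U
test, exact by enumeration for small tie-free samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import mannwhitneyu

from .matrix import ValidationError


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event/censoring time with the survival
    probability and the number at risk just before that time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("need at least one record")
    if np.any(times <= 0):
        raise ValidationError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"]
    out = pd.DataFrame(
        {"time": sf.index.to_numpy(), "survival": sf.to_numpy()}
    )
    out["at_risk"] = at_risk.reindex(sf.index).to_numpy()
    return out[out["time"] > 0].reset_index(drop=True)


def logrank_test(times, events, groups):
    """k-group log-rank test; returns (chi2, df, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(list(groups))
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValidationError("log-rank test needs at least 2 non-empty groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), int(len(uniq) - 1), float(res.p_value)


def h_score(proportion: float, intensity: int) -> float:
    """IHC H-score = percent positive cells (0–100) × intensity (0–3)."""
    if not (0 <= proportion <= 100):
        raise ValidationError(f"proportion {proportion} outside [0, 100]")
    if intensity not in (0, 1, 2, 3):
        raise ValidationError(f"intensity {intensity} not in {{0,1,2,3}}")
    return float(proportion * intensity)


def cd8_score(counts) -> float:
    """Mean CD8+ TIL count over exactly five high-power fields."""
    counts = list(counts)
    if len(counts) != 5:
        raise ValidationError(f"expected 5 field counts, got {len(counts)}")
    arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("field counts must be non-negative")
    return float(arr.mean())


def mannwhitney_u(a, b, mode: str = "auto"):
    """Mann–Whitney U with midrank ties; returns (U, two-sided p).

    ``mode="auto"`` uses exact enumeration when the combined sample size is
    at most 12 and there are no ties, and otherwise the normal approximation
    with tie correction; ``"exact"``/``"asymptotic"`` force a method.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def ihc_scores(records: pd.DataFrame) -> pd.DataFrame:
    """Per-record H-score and CD8 score from the clinical-table columns."""
    out = records.copy()
    out["h_score"] = [
        h_score(p, int(i))
        for p, i in zip(records["vimentin_proportion"], records["vimentin_intensity"])
    ]
    cd8_cols = [f"cd8_f{i}" for i in range(1, 6)]
    out["cd8_score"] = [cd8_score(row) for row in records[cd8_cols].to_numpy()]
    return out


def ihc_classify(records: pd.DataFrame, cd8_cutoff="median") -> pd.DataFrame:
    """IHC-based subtype call per record.

    Any vimentin positivity (H-score > 0) marks the tumor vimentin-positive.
    Among vimentin-positive tumors, a CD8 score below the cutoff (default:
    the median CD8 score of vimentin-positive tumors) calls SCLC-M, at or
    above calls SCLC-I; vimentin-negative tumors are "other". Every record
    receives exactly one call.
    """
    scored = ihc_scores(records)
    vim_pos = scored["h_score"] > 0
    if isinstance(cd8_cutoff, str):
        if cd8_cutoff != "median":
            raise ValidationError(f"unknown cutoff rule {cd8_cutoff!r}")
        pos_scores = scored.loc[vim_pos, "cd8_score"]
        if len(pos_scores) == 0:
            cutoff = np.nan
        elif pos_scores.nunique() == 1:
            raise ValidationError(
                "median cutoff undefined: all vimentin-positive CD8 scores identical"
            )
        else:
            cutoff = float(pos_scores.median())
    else:
        cutoff = float(cd8_cutoff)
    calls = np.where(
        ~vim_pos, "other", np.where(scored["cd8_score"] < cutoff, "SCLC-M", "SCLC-I")
    )
    scored["call"] = calls
    scored.attrs["cd8_cutoff"] = cutoff
    return scored
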