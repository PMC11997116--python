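"""Evaluation metrics and statistics.

ROC/PR areas (mid-rank tie handling; PR area by the average-precision step
convention), confusion-matrix operating points, DeLong's test for paired ROC
curves, Mann-Whitney U (exact for small samples), Pearson correlation, and
depth-stratified AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass(frozen=True)
class ScoredSet:
    """Scores in [0, 1] with binary labels and optional per-example depth."""

    scores: np.ndarray
    labels: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        l = np.asarray(self.labels, dtype=np.int64)
        if s.shape != l.shape or s.ndim != 1:
            raise ValueError("scores and labels must be equal-length 1-D arrays")
        if set(np.unique(l)) - {0, 1}:
            raise ValueError("labels must be binary (0/1)")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "labels", l)
        if self.depth is not None:
            d = np.asarray(self.depth, dtype=np.int64)
            if d.shape != s.shape:
                raise ValueError("depth must match scores in length")
            object.__setattr__(self, "depth", d)


def _coerce(s, labels=None) -> ScoredSet:
    if isinstance(s, ScoredSet):
        return s
    return ScoredSet(np.asarray(s, dtype=float), np.asarray(labels))


def roc_auc(scores, labels=None) -> float:
    """Area under the ROC curve (equals the scaled Mann-Whitney U statistic;
    ties counted half)."""
    ss = _coerce(scores, labels)
    if np.unique(ss.labels).size < 2:
        raise ValueError("roc_auc requires both classes")
    return float(roc_auc_score(ss.labels, ss.scores))


def pr_auc(scores, labels=None) -> float:
    """Area under the precision-recall curve, average-precision convention."""
    ss = _coerce(scores, labels)
    if ss.labels.sum() == 0:
        raise ValueError("pr_auc requires at least one positive")
    return float(average_precision_score(ss.labels, ss.scores))


def operating_point(scores, labels=None, cutoff: float = 0.5) -> dict:
    """Sensitivity/specificity/precision/FPR at ``score > cutoff``.

    Ratios with an empty denominator are reported as ``None``.
    """
    ss = _coerce(scores, labels)
    pred = ss.scores > cutoff
    tp = int(np.sum(pred & (ss.labels == 1)))
    fn = int(np.sum(~pred & (ss.labels == 1)))
    tn = int(np.sum(~pred & (ss.labels == 0)))
    fp = int(np.sum(pred & (ss.labels == 0)))
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    prec = tp / (tp + fp) if tp + fp else None
    return {"sensitivity": sens, "specificity": spec, "precision": prec,
            "fpr": None if spec is None else 1.0 - spec}


# ---------------------------------------------------------------------------
# DeLong's test
# ---------------------------------------------------------------------------

def _placements(pos: np.ndarray, neg: np.ndarray):
    """Mid-rank structural components V10 (per positive) and V01 (per
    negative) of the AUC."""
    m, n = pos.size, neg.size
    all_scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_scores)  # mid-ranks
    rpos, rneg = ranks[:m], ranks[m:]
    rpos_within = stats.rankdata(pos)
    rneg_within = stats.rankdata(neg)
    v10 = (rpos - rpos_within) / n
    v01 = 1.0 - (rneg - rneg_within) / m
    return v10, v01


def delong_test(s1: ScoredSet, s2: ScoredSet) -> dict:
    """DeLong's paired test comparing two ROC curves on identical labels.

    Returns ``{"auc1", "auc2", "z", "p"}`` with a two-sided normal p-value.
    """
    if not np.array_equal(s1.labels, s2.labels):
        raise ValueError("DeLong's test requires identical labels")
    labels = s1.labels
    if np.unique(labels).size < 2:
        raise ValueError("DeLong's test requires both classes")
    pos_idx = labels == 1
    v10 = np.empty((2, int(pos_idx.sum())))
    v01 = np.empty((2, int((~pos_idx).sum())))
    aucs = np.empty(2)
    for i, ss in enumerate((s1, s2)):
        p10, p01 = _placements(ss.scores[pos_idx], ss.scores[~pos_idx])
        v10[i], v01[i] = p10, p01
        aucs[i] = p10.mean()
    m, n = v10.shape[1], v01.shape[1]
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = aucs[0] - aucs[1]
    if var <= 0:
        z = 0.0
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return {"auc1": float(aucs[0]), "auc2": float(aucs[1]),
            "z": float(z), "p": float(min(p, 1.0))}


# ---------------------------------------------------------------------------
# Depth stratification
# ---------------------------------------------------------------------------

def depth_stratified_auc(s: ScoredSet,
                         bins: Sequence[tuple[int, int]]) -> dict:
    """ROC AUC within closed depth intervals; one-class or empty bins are
    reported as ``None`` (missing), not 0."""
    if s.depth is None:
        raise ValueError("ScoredSet has no depth information")
    for i, (lo1, hi1) in enumerate(bins):
        if lo1 > hi1:
            raise ValueError(f"invalid bin ({lo1}, {hi1})")
        for lo2, hi2 in bins[i + 1:]:
            if lo1 <= hi2 and lo2 <= hi1:
                raise ValueError("depth bins must not overlap")
    out = {}
    for lo, hi in bins:
        mask = (s.depth >= lo) & (s.depth <= hi)
        labels = s.labels[mask]
        if mask.sum() == 0 or np.unique(labels).size < 2:
            out[(lo, hi)] = None
        else:
            out[(lo, hi)] = roc_auc(s.scores[mask], labels)
    return out


# ---------------------------------------------------------------------------
# Rank and correlation utilities
# ---------------------------------------------------------------------------

def mann_whitney(a, b) -> float:
    """Two-sided Mann-Whitney U p-value: exact for n <= 8 per group (no
    ties), normal approximation with tie correction otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return 1.0  # all observations tied: no evidence of a shift
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= 8 and b.size <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def pearson(x, y) -> dict:
    """Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson requires equal-length inputs of size >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("pearson requires variance > 0 in both inputs")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p)}
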