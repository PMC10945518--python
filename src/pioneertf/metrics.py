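"""Classifier evaluation: ROC AUC, PR AUC, maximal MCC, Mann-Whitney U.

Known pioneer TFs are the positive class, all other scored TFs negatives.
ROC AUC is the probability that a random positive outranks a random negative
(ties count 1/2, the Mann-Whitney identity); PR AUC is the step-function
area under the precision-recall curve; MCC is maximized over all distinct
score thresholds with zero-denominator MCC defined as 0.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    if y.all() or not y.any():
        raise ValueError("need at least one positive and one negative")
    return s, y


def roc_auc(scores, labels) -> float:
    """P(score+ > score-) + P(score+ == score-)/2 via midranks."""
    s, y = _validate(scores, labels)
    ranks = stats.rankdata(s)  # midranks handle ties
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def pr_auc(scores, labels) -> float:
    """Step-wise area under the precision-recall curve.

    Equals sum over descending thresholds of (R_i - R_{i-1}) * P_i (no linear
    interpolation between operating points).
    """
    s, y = _validate(scores, labels)
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    n_pos = int(y.sum())
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    # operating points: last index of each distinct score
    last = np.nonzero(np.append(s[1:] != s[:-1], True))[0]
    precision = tp[last] / (tp[last] + fp[last])
    recall = tp[last] / n_pos
    prev_r = 0.0
    area = 0.0
    for p, r in zip(precision, recall):
        area += (r - prev_r) * p
        prev_r = r
    return float(area)


def max_mcc(scores, labels) -> tuple[float, float]:
    """Matthews correlation coefficient maximized over thresholds.

    A threshold t classifies score >= t as positive; candidate thresholds are
    the distinct scores.  Returns (best MCC, threshold achieving it).
    """
    s, y = _validate(scores, labels)
    best = (-np.inf, float("nan"))
    # descending thresholds: ties resolve to the most stringent classifier
    for t in np.unique(s)[::-1]:
        pred = s >= t
        tp = int(np.sum(pred & y))
        fp = int(np.sum(pred & ~y))
        fn = int(np.sum(~pred & y))
        tn = int(np.sum(~pred & ~y))
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
        if mcc > best[0]:
            best = (float(mcc), float(t))
    return best


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test; exact p by enumeration when n_x*n_y <= 400 and
    there are no ties, otherwise the tie-corrected normal approximation with
    continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty input")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) * len(y) <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def evaluate_scores(scores, labels) -> dict:
    """All Fig.-2-style metrics for one labeled score set."""
    auc = roc_auc(scores, labels)
    pr = pr_auc(scores, labels)
    mcc, thr = max_mcc(scores, labels)
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    u, p = mann_whitney(s[y], s[~y], alternative="greater")
    return dict(
        roc_auc=auc, pr_auc=pr, max_mcc=mcc, mcc_threshold=thr, mw_u=u, mw_p=p
    )
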