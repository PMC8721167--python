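"""Independent brute-force reference computations used to cross-check the
vectorized implementations. These deliberately share no code with the
package's own metric/diffusion paths."""

from __future__ import annotations

import math

import numpy as np


def jaccard_oracle(features: np.ndarray) -> np.ndarray:
    """Set-based Jaccard per pair; 0/0 -> 0 off-diagonal, diagonal 1."""
    m = features.shape[0]
    sets = [set(np.flatnonzero(row)) for row in features]
    s = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            if i == j:
                s[i, j] = 1.0
                continue
            union = sets[i] | sets[j]
            s[i, j] = len(sets[i] & sets[j]) / len(union) if union else 0.0
    return s


def rwr_closed_form(w: np.ndarray, alpha: float) -> np.ndarray:
    """Stationary diffusion states row-by-row from the linear system
    p = (1 - alpha) * e_i * (I - alpha W)^{-1}."""
    m = w.shape[0]
    inv = np.linalg.inv(np.eye(m) - alpha * w)
    return (1.0 - alpha) * inv  # row i of inv scaled = e_i (I - aW)^{-1}


def ppmi_oracle(p: np.ndarray) -> np.ndarray:
    """Scalar entrywise evaluation of positive PMI."""
    m, n = p.shape
    total = 0.0
    for i in range(m):
        for j in range(n):
            total += p[i, j]
    x = np.zeros_like(p, dtype=float)
    for i in range(m):
        r = sum(p[i, k] for k in range(n))
        for j in range(n):
            c = sum(p[k, j] for k in range(m))
            if p[i, j] > 0 and r > 0 and c > 0:
                x[i, j] = max(0.0, math.log2(p[i, j] * total / (r * c)))
    return x


def confusion_oracle(y_true, y_pred, l):
    """Per-class one-vs-rest confusion counts by explicit counting."""
    counts = {}
    n = len(y_true)
    for c in range(l):
        tp = sum(1 for t, p in zip(y_true, y_pred) if p == c and t == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if p == c and t != c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if p != c and t == c)
        counts[c] = (tp, fp, fn, n - tp - fp - fn)
    return counts


def macro_metrics_oracle(y_true, y_pred, l):
    """acc / macro precision / macro recall / F1 from the confusion counts."""
    counts = confusion_oracle(y_true, y_pred, l)
    n = len(y_true)
    accs, precs, recs = [], [], []
    for c in range(l):
        tp, fp, fn, tn = counts[c]
        accs.append((tp + tn) / n)
        precs.append(tp / (tp + fp) if tp + fp else 0.0)
        recs.append(tp / (tp + fn) if tp + fn else 0.0)
    mp, mr = sum(precs) / l, sum(recs) / l
    f1 = 2 * mp * mr / (mp + mr) if mp + mr else 0.0
    return sum(accs) / l, mp, mr, f1


def _pr_points(y: np.ndarray, scores: np.ndarray):
    """Precision/recall at every unique-score threshold, descending."""
    order = np.argsort(-scores, kind="stable")
    y = y[order]
    scores = scores[order]
    distinct = np.flatnonzero(np.diff(scores)) if len(scores) > 1 else np.array([], int)
    cuts = np.r_[distinct, len(y) - 1]
    tps = np.cumsum(y)[cuts]
    fps = (cuts + 1) - tps
    return tps, fps, y.sum()


def average_precision_oracle(y: np.ndarray, scores: np.ndarray) -> float:
    """Step-wise AP = sum (R_k - R_{k-1}) P_k over the threshold sweep."""
    tps, fps, pos = _pr_points(np.asarray(y, float), np.asarray(scores, float))
    precision = tps / (tps + fps)
    recall = tps / pos
    prev_r, ap = 0.0, 0.0
    for p, r in zip(precision, recall):
        ap += (r - prev_r) * p
        prev_r = r
    return ap


def roc_auc_oracle(y: np.ndarray, scores: np.ndarray) -> float:
    """Trapezoidal area under the (FPR, TPR) threshold sweep."""
    tps, fps, pos = _pr_points(np.asarray(y, float), np.asarray(scores, float))
    neg = len(y) - pos
    tpr = np.r_[0.0, tps / pos]
    fpr = np.r_[0.0, fps / neg]
    return float(np.trapezoid(tpr, fpr))
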