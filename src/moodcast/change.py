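"""Day-level emotional-state-change scoring from valence distributions.

Two windowed scores over a daily series of predicted valence probability
3-vectors:

* entropy: Shannon entropy (bits) of the mean distribution over the w days
  preceding each day — overall disorder in the recent window;
* divergence: distance between the present day's distribution P and the mean
  Q of the w preceding days. The default variant is the standard
  Jensen-Shannon divergence, 1/2 KL(P||M) + 1/2 KL(Q||M) with M = (P+Q)/2,
  which is symmetric and bounded in [0, 1] bits. The "jeffreys" variant is
  the symmetrized KL, 1/2 [KL(P||Q) + KL(Q||P)], with epsilon smoothing.

Days without w prior distributions get no score (NaN) rather than a
shrunken window, keeping scores comparable across days.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve, roc_auc_score

_EPS = 1e-10


def _entropy_bits(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def entropy_window(distributions: np.ndarray, window: int = 3) -> np.ndarray:
    """Per-day entropy (bits) of the mean distribution over the ``window``
    days strictly before each day; NaN where fewer than ``window`` prior days
    exist (or any of them is undefined)."""
    dists = np.asarray(distributions, dtype=float)
    T = len(dists)
    out = np.full(T, np.nan)
    for t in range(window, T):
        win = dists[t - window : t]
        if np.isnan(win).any():
            continue
        out[t] = _entropy_bits(win.mean(axis=0))
    return out


def _js_bits(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)

    def kl(a, b):
        nz = a > 0
        return float((a[nz] * np.log2(a[nz] / b[nz])).sum())

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def _jeffreys_bits(p: np.ndarray, q: np.ndarray) -> float:
    p = (p + _EPS) / (p + _EPS).sum()
    q = (q + _EPS) / (q + _EPS).sum()
    return float(0.5 * ((p * np.log2(p / q)).sum() + (q * np.log2(q / p)).sum()))


def divergence_window(distributions: np.ndarray, window: int = 3, variant: str = "js") -> np.ndarray:
    """Per-day divergence (bits) between the present-day distribution and the
    mean distribution of the ``window`` preceding days."""
    if variant not in ("js", "jeffreys"):
        raise ValueError("variant must be 'js' or 'jeffreys'")
    dists = np.asarray(distributions, dtype=float)
    T = len(dists)
    out = np.full(T, np.nan)
    fn = _js_bits if variant == "js" else _jeffreys_bits
    for t in range(window, T):
        win = dists[t - window : t]
        if np.isnan(win).any() or np.isnan(dists[t]).any():
            continue
        out[t] = fn(dists[t], win.mean(axis=0))
    return out


def score_series(
    distributions: np.ndarray,
    labels: np.ndarray,
    window: int = 3,
) -> pd.DataFrame:
    """Bundle entropy and both divergence variants with change labels.

    Rows where scores are undefined keep NaN scores; downstream ROC uses
    scored days only.
    """
    return pd.DataFrame(
        {
            "entropy": entropy_window(distributions, window),
            "js": divergence_window(distributions, window, "js"),
            "jeffreys": divergence_window(distributions, window, "jeffreys"),
            "label": np.asarray(labels, dtype=float),
        }
    )


def detection_roc(
    scores: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray | None = None,
) -> dict[str, dict]:
    """Threshold-sweep ROC per group over days with defined scores.

    Returns {group: {"fpr", "tpr", "thresholds", "auc", "n"}}; the single
    group is named "all" when ``groups`` is None. A group whose scored days
    lack both label classes raises a ValueError naming the group.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if groups is None:
        groups = np.full(len(scores), "all", dtype=object)
    groups = np.asarray(groups, dtype=object)
    result: dict[str, dict] = {}
    for g in pd.unique(groups):
        sel = (groups == g) & ~np.isnan(scores) & ~np.isnan(labels)
        y = labels[sel].astype(int)
        s = scores[sel]
        if len(np.unique(y)) < 2:
            raise ValueError(f"degenerate change labels in group {g!r}: need both classes")
        fpr, tpr, thr = roc_curve(y, s)
        result[str(g)] = {
            "fpr": fpr,
            "tpr": tpr,
            "thresholds": thr,
            "auc": float(roc_auc_score(y, s)),
            "n": int(sel.sum()),
        }
    return result
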