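"""Shared metric suite: confusion-based classification metrics, one-vs-rest
AUCs, and forecaster comparison curves."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)


@dataclass
class MetricsReport:
    """Per-class and macro-averaged classification metrics.

    AUCs are one-vs-rest from the predicted probability columns; a class
    absent from the truth gets NaN and is excluded from the macro average.
    """

    classes: list[int]
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    roc_auc: dict[int, float]
    pr_auc: dict[int, float]
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_roc_auc: float
    macro_pr_auc: float
    confusion: np.ndarray = field(repr=False, default=None)
    n: int = 0
    group: str = "all"

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n": self.n,
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "macro_roc_auc": self.macro_roc_auc,
            "macro_pr_auc": self.macro_pr_auc,
            "per_class": {
                int(c): {
                    "precision": self.precision[c],
                    "recall": self.recall[c],
                    "f1": self.f1[c],
                    "roc_auc": self.roc_auc[c],
                    "pr_auc": self.pr_auc[c],
                }
                for c in self.classes
            },
            "confusion": self.confusion.tolist(),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": c,
                "precision": self.precision[c],
                "recall": self.recall[c],
                "f1": self.f1[c],
                "roc_auc": self.roc_auc[c],
                "pr_auc": self.pr_auc[c],
            }
            for c in self.classes
        ]
        rows.append(
            {
                "class": "macro",
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
                "roc_auc": self.macro_roc_auc,
                "pr_auc": self.macro_pr_auc,
            }
        )
        return pd.DataFrame(rows)


def classification_metrics(
    y_true: np.ndarray,
    proba: np.ndarray,
    classes: list[int] | None = None,
    group: str = "all",
) -> MetricsReport:
    """Argmax-based confusion metrics plus probability-based AUCs.

    ``proba`` has one column per class in ``classes`` (defaults to
    0..C-1 from the column count).
    """
    y_true = np.asarray(y_true, dtype=int)
    proba = np.atleast_2d(np.asarray(proba, dtype=float))
    if len(y_true) != len(proba):
        raise ValueError("labels and probabilities misaligned")
    if classes is None:
        classes = list(range(proba.shape[1]))
    if len(np.unique(y_true)) < 2:
        raise ValueError("need at least two classes in the truth")
    y_pred = np.asarray(classes)[proba.argmax(axis=1)]
    prec, rec, f1, _ = precision_recall_fscore_support(y_true, y_pred, labels=classes, zero_division=0)
    cm = confusion_matrix(y_true, y_pred, labels=classes)

    roc, pr = {}, {}
    for j, c in enumerate(classes):
        mask = y_true == c
        if mask.any() and not mask.all():
            roc[c] = float(roc_auc_score(mask.astype(int), proba[:, j]))
            pr[c] = float(average_precision_score(mask.astype(int), proba[:, j]))
        else:
            roc[c] = np.nan
            pr[c] = np.nan
    roc_vals = [v for v in roc.values() if not np.isnan(v)]
    pr_vals = [v for v in pr.values() if not np.isnan(v)]

    return MetricsReport(
        classes=list(classes),
        precision={c: float(p) for c, p in zip(classes, prec)},
        recall={c: float(r) for c, r in zip(classes, rec)},
        f1={c: float(v) for c, v in zip(classes, f1)},
        roc_auc=roc,
        pr_auc=pr,
        accuracy=float((y_pred == y_true).mean()),
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        macro_roc_auc=float(np.mean(roc_vals)) if roc_vals else np.nan,
        macro_pr_auc=float(np.mean(pr_vals)) if pr_vals else np.nan,
        confusion=cm,
        n=len(y_true),
        group=group,
    )


def compare_forecasters(
    hmm_curve: pd.DataFrame,
    transformer_curve: pd.DataFrame,
    plot_path=None,
) -> pd.DataFrame:
    """Tabulate per-horizon state-match accuracies and their difference.

    Both inputs are ``state_match_curve`` outputs over identical horizons.
    Optionally writes a comparison plot.
    """
    h1 = hmm_curve["horizon"].to_numpy()
    h2 = transformer_curve["horizon"].to_numpy()
    if len(h1) != len(h2) or np.any(h1 != h2):
        raise ValueError("horizon mismatch between curves")
    df = pd.DataFrame(
        {
            "horizon": h1,
            "hmm": hmm_curve["accuracy"].to_numpy(),
            "transformer": transformer_curve["accuracy"].to_numpy(),
        }
    )
    df["difference"] = df["transformer"] - df["hmm"]
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(df["horizon"], df["hmm"], marker="o", label="HMM (gamma A^h)")
        ax.plot(df["horizon"], df["transformer"], marker="s", label="Transformer")
        ax.set_xlabel("forecast horizon (days)")
        ax.set_ylabel("state-match accuracy")
        ax.set_ylim(0, 1.02)
        ax.legend()
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return df
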