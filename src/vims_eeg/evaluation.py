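"""Evaluation surfaces: confusion matrix, ACC/SPE/SEN, PLCC/SROCC/RMSE.

Sensitivity and specificity depend on which class is declared positive;
reports therefore always carry an explicit positive-class label and
include both conventions side by side rather than silently choosing one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = ["ConfusionMatrix", "confusion_matrix", "classification_metrics",
           "regression_metrics", "EvalReport", "plot_loss_curves"]


@dataclass
class ConfusionMatrix:
    """2x2 counts under a declared positive class."""

    tn: int
    fp: int
    fn: int
    tp: int
    positive: int = 1

    def __post_init__(self):
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def swapped(self) -> "ConfusionMatrix":
        """The same predictions with the other class declared positive."""
        return ConfusionMatrix(tn=self.tp, fp=self.fn, fn=self.fp,
                               tp=self.tn, positive=1 - self.positive)

    def as_array(self) -> np.ndarray:
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


def confusion_matrix(labels, preds, positive: int = 1) -> ConfusionMatrix:
    labels = np.asarray(labels).astype(int)
    preds = np.asarray(preds).astype(int)
    if labels.shape != preds.shape:
        raise ValueError("labels and predictions differ in length")
    values = set(np.unique(labels)) | set(np.unique(preds))
    if not values <= {0, 1}:
        raise ValueError(f"labels/predictions must be binary 0/1, got {values}")
    pos = labels == positive
    ppos = preds == positive
    return ConfusionMatrix(
        tn=int(np.sum(~pos & ~ppos)), fp=int(np.sum(~pos & ppos)),
        fn=int(np.sum(pos & ~ppos)), tp=int(np.sum(pos & ppos)),
        positive=positive)


def classification_metrics(cm: ConfusionMatrix) -> dict:
    """ACC, SEN = TP/(TP+FN), SPE = TN/(TN+FP) under both conventions.

    An empty class yields ``None`` for the undefined rate rather than 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def rates(m: ConfusionMatrix):
        sen = m.tp / (m.tp + m.fn) if (m.tp + m.fn) else None
        spe = m.tn / (m.tn + m.fp) if (m.tn + m.fp) else None
        return sen, spe

    acc = (cm.tp + cm.tn) / cm.total
    sen, spe = rates(cm)
    sen_alt, spe_alt = rates(cm.swapped())
    return {"acc": acc, "sen": sen, "spe": spe, "positive": cm.positive,
            "sen_other_convention": sen_alt, "spe_other_convention": spe_alt}


def regression_metrics(preds, targets) -> dict:
    """PLCC (Pearson), SROCC (Spearman, average ranks on ties), RMSE."""
    preds = np.asarray(preds, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if preds.shape != targets.shape:
        raise ValueError("prediction/target length mismatch")
    if preds.size < 2:
        raise ValueError("need at least two points for correlation")
    if np.std(preds) == 0 or np.std(targets) == 0:
        raise ValueError("constant input: correlation undefined")
    plcc = float(stats.pearsonr(preds, targets).statistic)
    srocc = float(stats.spearmanr(preds, targets).statistic)
    rmse = float(np.sqrt(np.mean((preds - targets) ** 2)))
    return {"plcc": plcc, "srocc": srocc, "rmse": rmse, "n": int(preds.size)}


@dataclass
class EvalReport:
    """Bundle of classification and/or regression results."""

    n: int
    confusion: ConfusionMatrix | None = None
    classification: dict | None = None
    regression: dict | None = None

    def to_json(self) -> str:
        d = {"n": self.n}
        if self.confusion is not None:
            d["confusion"] = asdict(self.confusion)
        if self.classification is not None:
            d["classification"] = self.classification
        if self.regression is not None:
            d["regression"] = self.regression
        return json.dumps(d, indent=2)

    def text(self) -> str:
        lines = [f"n = {self.n}"]
        if self.confusion is not None:
            cm = self.confusion
            lines += [f"confusion (positive={cm.positive}):",
                      f"  TN={cm.tn}  FP={cm.fp}",
                      f"  FN={cm.fn}  TP={cm.tp}"]
        if self.classification is not None:
            c = self.classification
            fmt = lambda v: "undefined" if v is None else f"{v:.4f}"
            lines.append(f"ACC={c['acc']:.4f}  SEN={fmt(c['sen'])}  "
                         f"SPE={fmt(c['spe'])} (positive={c['positive']})")
            lines.append(f"  other convention: SEN={fmt(c['sen_other_convention'])}  "
                         f"SPE={fmt(c['spe_other_convention'])}")
        if self.regression is not None:
            r = self.regression
            lines.append(f"PLCC={r['plcc']:.4f}  SROCC={r['srocc']:.4f}  "
                         f"RMSE={r['rmse']:.4f}")
        return "\n".join(lines)


def plot_loss_curves(history, path) -> None:
    """Write a train/val loss curve figure from a training history frame."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(history["epoch"], history["train_loss"], label="train")
    if "val_loss" in history:
        ax.plot(history["epoch"], history["val_loss"], label="validation")
    ax.set_xlabel("epoch")
    ax.set_ylabel("loss")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
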