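"""Test-set evaluation: accuracy, NLL, the F1-score matrix and the
robustness comparison grid.

The F1-score matrix is the elementwise harmonic mean of the row-normalised
(recall-like) and column-normalised (precision-like) confusion matrix; its
diagonal equals the classical per-class F1 score, while off-diagonal entries
highlight systematic confusions between class pairs.

Metrics are aggregated across the cross-validation models evaluated on
identical test inputs: mean and sample standard deviation of accuracy and
NLL over the model ensemble.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion",
    "f1_score_matrix",
    "evaluate_models",
    "robustness_comparison",
]


@dataclass
class ConfusionMatrix:
    """Counts[t][p]: samples of true class t predicted as p."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(c < 0):
            raise ValueError("confusion counts must be non-negative")
        self.counts = c.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total) if self.total else 0.0


@dataclass
class EvalReport:
    """Ensemble metrics for one input condition.

    ``accuracies``/``nlls`` are per-model; ``acc_mean``/``acc_std`` (and the
    NLL counterparts) aggregate them with the sample (n-1) standard
    deviation.  ``f1_matrices`` holds one F1-score matrix per model.
    """

    accuracies: list[float]
    nlls: list[float]
    f1_matrices: list[np.ndarray]
    confusions: list[np.ndarray]
    input_condition: str  # "in_focus" | "defocused"
    augmented_training: bool
    model_dims: int
    acc_mean: float = 0.0
    acc_std: float = 0.0
    nll_mean: float = 0.0
    nll_std: float = 0.0
    std_convention: str = "sample (n-1) over CV models"

    def __post_init__(self) -> None:
        accs = np.asarray(self.accuracies, dtype=np.float64)
        nlls = np.asarray(self.nlls, dtype=np.float64)
        if np.any(accs < 0) or np.any(accs > 1):
            raise ValueError("accuracies must lie in [0, 1]")
        self.acc_mean = float(accs.mean())
        self.nll_mean = float(nlls.mean())
        if len(accs) > 1:
            self.acc_std = float(accs.std(ddof=1))
            self.nll_std = float(nlls.std(ddof=1))
        else:
            warnings.warn("single-model report: standard deviation reported as 0")
            self.acc_std = 0.0
            self.nll_std = 0.0

    def to_json(self) -> str:
        d = asdict(self)
        d["f1_matrices"] = [m.tolist() for m in self.f1_matrices]
        d["confusions"] = [m.tolist() for m in self.confusions]
        return json.dumps(d, indent=2)


def confusion(predictions, labels, n_classes: int) -> ConfusionMatrix:
    """Count-based confusion matrix (rows true, columns predicted).

    Ties in the upstream argmax are broken toward the lowest class index by
    ``numpy.argmax``; this function takes already-argmaxed predictions.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if len(labels) and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError("label out of range")
    if len(predictions) and (predictions.min() < 0 or predictions.max() >= n_classes):
        raise ValueError("prediction out of range")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (labels, predictions), 1)
    return ConfusionMatrix(counts=counts)


def f1_score_matrix(cm: ConfusionMatrix) -> np.ndarray:
    """Elementwise harmonic mean of row- and column-normalised confusions.

    ``F[i][j] = 2 R_ij P_ij / (R_ij + P_ij)`` with ``R`` the row-normalised
    and ``P`` the column-normalised matrix; zero-sum rows/columns normalise
    to zeros and ``F = 0`` wherever ``R + P = 0``.  The diagonal equals the
    standard per-class F1 score ``2TP / (2TP + FP + FN)``.
    """
    c = cm.counts.astype(np.float64)
    row_sums = c.sum(axis=1, keepdims=True)
    col_sums = c.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(row_sums > 0, c / row_sums, 0.0)
        p = np.where(col_sums > 0, c / col_sums, 0.0)
        f = np.where(r + p > 0, 2.0 * r * p / (r + p), 0.0)
    return f


def evaluate_models(
    models,
    inputs: np.ndarray,
    labels: np.ndarray,
    class_weights,
    input_condition: str = "in_focus",
    augmented_training: bool = False,
    batch_size: int = 8,
) -> EvalReport:
    """Evaluate an ensemble of CV models on identical test inputs.

    ``inputs`` is the stacked network input array (same for every model);
    ``class_weights`` weights the reported NLL the same way training does.
    """
    from .training import weighted_nll_loss

    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("empty test set")
    accs, nlls, f1s, cms = [], [], [], []
    n_classes = models[0].config.n_classes
    for m in models:
        if m.config.n_classes != n_classes:
            raise ValueError("models disagree on n_classes")
        lp = m.predict_log_proba(inputs, batch_size=batch_size)
        preds = lp.argmax(axis=1)
        cm = confusion(preds, labels, n_classes)
        accs.append(cm.accuracy())
        nlls.append(weighted_nll_loss(lp, labels, class_weights))
        f1s.append(f1_score_matrix(cm))
        cms.append(cm.counts)
    return EvalReport(
        accuracies=accs,
        nlls=nlls,
        f1_matrices=f1s,
        confusions=cms,
        input_condition=input_condition,
        augmented_training=augmented_training,
        model_dims=models[0].dims,
    )


#: Row ordering of the robustness grid: (dims, augmented, condition)
GRID_ORDER = [
    (2, False, "in_focus"),
    (3, False, "in_focus"),
    (2, True, "in_focus"),
    (3, True, "in_focus"),
    (2, False, "defocused"),
    (3, False, "defocused"),
    (2, True, "defocused"),
    (3, True, "defocused"),
]


def robustness_comparison(reports: list[EvalReport]):
    """Arrange reports into the 2x2x2 comparison grid with derived deltas.

    Rows follow :data:`GRID_ORDER` — {2D, 3D} x {plain, defocus-augmented}
    x {in-focus, defocused test inputs}.  Missing conditions appear as
    labelled gaps.  Deltas: volumetric minus planar accuracy per
    (augmentation, condition), and augmented minus plain per (dims,
    condition).
    """
    import pandas as pd

    by_key = {(r.model_dims, r.augmented_training, r.input_condition): r for r in reports}
    rows = []
    for dims, augm, cond in GRID_ORDER:
        r = by_key.get((dims, augm, cond))
        name = f"{dims}D-model" + ("-augm" if augm else "")
        if r is None:
            rows.append({"model": name, "input_type": cond.replace("_", " "),
                         "accuracy": np.nan, "acc_std": np.nan,
                         "nll": np.nan, "nll_std": np.nan, "status": "missing"})
        else:
            rows.append({"model": name, "input_type": cond.replace("_", " "),
                         "accuracy": r.acc_mean, "acc_std": r.acc_std,
                         "nll": r.nll_mean, "nll_std": r.nll_std, "status": "ok"})
    table = pd.DataFrame(rows)

    deltas = {}
    for augm in (False, True):
        for cond in ("in_focus", "defocused"):
            a, b = by_key.get((3, augm, cond)), by_key.get((2, augm, cond))
            if a and b:
                key = f"3d_minus_2d{'_augm' if augm else ''}_{cond}"
                deltas[key] = a.acc_mean - b.acc_mean
    for dims in (2, 3):
        for cond in ("in_focus", "defocused"):
            a, b = by_key.get((dims, True, cond)), by_key.get((dims, False, cond))
            if a and b:
                deltas[f"{dims}d_augm_minus_plain_{cond}"] = a.acc_mean - b.acc_mean
    return table, deltas


def save_f1_heatmap(f1: np.ndarray, class_names, path) -> None:
    """Optional PNG heatmap of an F1-score matrix (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(f1, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(class_names)), class_names, rotation=45)
    ax.set_yticks(range(len(class_names)), class_names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(f1.shape[0]):
        for j in range(f1.shape[1]):
            ax.text(j, i, f"{f1[i, j]:.2f}", ha="center", va="center",
                    color="w" if f1[i, j] < 0.5 else "k", fontsize=7)
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
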