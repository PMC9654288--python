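"""Class-weighted NLL training with stratified splits, cross-validation and
early stopping.

The data is split 85:15 into training and test sets, stratified by class; the
training set is further split into stratified folds, and one model is trained
per fold configuration (all folds but one for training, the held-out fold for
validation), giving an ensemble whose spread estimates the training variance.

The loss is the negative log-likelihood of the true class under the model's
log-softmax output, weighted per class to counter the imbalanced class
frequencies: with inverse-frequency weights ``w_c`` (normalised to mean 1),
the batch loss is ``sum_i w_{y_i} (-l_{i,y_i}) / sum_i w_{y_i}``.  Because
the networks end in a log-softmax, this equals weighted cross-entropy on the
pre-normalisation scores.

Optimisation is Adam; early stopping restores the weights of the epoch with
the best validation loss once no improvement is seen for ``patience_epochs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .models import HologramClassifier, ModelConfig, build_classifier
from .synthetic import DatasetManifest, HologramSample
from .volumes import (
    DEFAULT_DEFOCUS_RANGE_UM,
    DEFAULT_DEPTH_STEP_UM,
    VolumeSample,
    build_volume,
    defocus_augment,
    geometric_augment,
    make_defocused_test_set,
)

__all__ = [
    "ClassWeights",
    "TrainConfig",
    "TrainingHistory",
    "FoldPair",
    "compute_class_weights",
    "weighted_nll_loss",
    "make_splits",
    "train_model",
    "run_cv",
]


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights ``w_c`` (positive, mean-normalised)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 1 or np.any(w <= 0):
            raise ValueError("weights must be a 1D array of positive reals")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol settings."""

    lr: float = 2e-4
    weight_decay: float = 0.01
    patience_epochs: int = 10
    max_epochs: int = 200
    split_ratio: float = 0.85
    n_folds: int = 5
    batch_size: int = 32
    seed: int = 0
    use_defocus_augment: bool = False
    use_geometric_augment: bool = True
    defocus_range_um: float = DEFAULT_DEFOCUS_RANGE_UM
    model_dims: int = 3
    n_steps: int = 6
    step_um: float = DEFAULT_DEPTH_STEP_UM

    def __post_init__(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.model_dims not in (2, 3):
            raise ValueError("model_dims must be 2 or 3")


@dataclass
class TrainingHistory:
    """Per-epoch learning curves and stopping bookkeeping."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "train_acc": self.train_acc,
                "val_acc": self.val_acc,
            }
        )


@dataclass(frozen=True)
class FoldPair:
    """Index arrays (into the dataset) for one fold configuration."""

    train_idx: np.ndarray
    val_idx: np.ndarray


def compute_class_weights(labels, n_classes: int) -> ClassWeights:
    """Inverse-frequency class weights, normalised so the mean weight is 1.

    ``labels`` are integer class ids; every class must appear at least once.
    """
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=n_classes)
    missing = np.flatnonzero(counts == 0)
    if missing.size:
        raise ValueError(f"class(es) {missing.tolist()} absent from training labels")
    inv = 1.0 / counts
    return ClassWeights(weights=inv / inv.mean())


def weighted_nll_loss(
    log_probs: np.ndarray,
    labels: np.ndarray,
    weights: ClassWeights,
    reduction: str = "weighted_mean",
) -> float:
    """Class-weighted negative log-likelihood of log-softmax outputs.

    Per sample the loss is ``-w_y * l_y``; the batch reduction divides by the
    summed weights (``weighted_mean``, the convention that keeps a balanced
    batch's loss on the natural ln scale) or by the batch size (``mean``).
    """
    log_probs = np.asarray(log_probs, dtype=np.float64)
    labels = np.asarray(labels)
    n_classes = log_probs.shape[1]
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("label out of range")
    w = weights.weights[labels]
    per_sample = -w * log_probs[np.arange(len(labels)), labels]
    if reduction == "weighted_mean":
        return float(per_sample.sum() / w.sum())
    if reduction == "mean":
        return float(per_sample.mean())
    raise ValueError(f"unknown reduction {reduction!r}")


def _loss_grad(log_probs: np.ndarray, labels: np.ndarray, weights: ClassWeights) -> np.ndarray:
    """Gradient of the weighted-mean NLL w.r.t. the log-probabilities."""
    w = weights.weights[labels]
    g = np.zeros_like(log_probs)
    g[np.arange(len(labels)), labels] = -w / w.sum()
    return g


def make_splits(manifest: DatasetManifest, cfg: TrainConfig) -> tuple[np.ndarray, list[FoldPair]]:
    """Stratified test split plus stratified CV folds of the training set.

    Returns ``(test_idx, fold_pairs)`` where each fold pair trains on all but
    one fold and validates on the held-out fold.  Deterministic given
    ``cfg.seed``.
    """
    labels = manifest.records["label"].to_numpy()
    if len(labels) == 0:
        raise ValueError("empty manifest")
    counts = manifest.records["label"].value_counts()
    if (counts < cfg.n_folds).any():
        bad = counts[counts < cfg.n_folds]
        raise ValueError(f"class(es) with fewer members than n_folds: {bad.to_dict()}")
    idx = np.arange(len(labels))
    # integer test size so a 100-sample set splits exactly 85:15
    n_test = int(round(len(labels) * (1.0 - cfg.split_ratio)))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=n_test,
        stratify=labels,
        random_state=cfg.seed,
    )
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    pairs = []
    for tr, va in skf.split(train_idx, labels[train_idx]):
        pairs.append(FoldPair(train_idx=np.sort(train_idx[tr]), val_idx=np.sort(train_idx[va])))
    return np.sort(test_idx), pairs


def _labels_to_ids(labels, class_names) -> np.ndarray:
    lut = {c: i for i, c in enumerate(class_names)}
    return np.array([lut[l] for l in labels])


class _BatchBuilder:
    """Assemble network inputs from stored samples, applying augmentations.

    For the volumetric branch, defocus augmentation (when enabled) perturbs
    the base hologram before the volume is rebuilt; without it, volumes are
    built once and cached.  Geometric augmentation is applied last.
    """

    def __init__(self, samples: list[HologramSample], cfg: TrainConfig):
        self.samples = samples
        self.cfg = cfg
        self._volume_cache: dict[int, np.ndarray] = {}

    def _base_array(self, i: int, rng: np.random.Generator | None) -> np.ndarray:
        s = self.samples[i]
        cfg = self.cfg
        if cfg.use_defocus_augment and rng is not None:
            s = defocus_augment(s, rng, max_offset_um=cfg.defocus_range_um)
        elif cfg.model_dims == 3:
            cached = self._volume_cache.get(i)
            if cached is not None:
                return cached
        if cfg.model_dims == 3:
            arr = build_volume(s, n_steps=cfg.n_steps, step_um=cfg.step_um).volume
            if not cfg.use_defocus_augment:
                self._volume_cache[i] = arr
        else:
            arr = s.pair.as_array()
        return arr

    def build(self, indices, rng: np.random.Generator | None, augment: bool) -> np.ndarray:
        out = []
        for i in indices:
            arr = self._base_array(int(i), rng if augment else None)
            if augment and self.cfg.use_geometric_augment and rng is not None:
                k = int(rng.integers(0, 4))
                hflip = bool(rng.integers(0, 2))
                vflip = bool(rng.integers(0, 2))
                arr = np.rot90(arr, k, axes=(-2, -1))
                if hflip:
                    arr = arr[..., ::-1]
                if vflip:
                    arr = arr[..., ::-1, :]
            out.append(np.ascontiguousarray(arr, dtype=np.float32))
        return np.stack(out)


def train_model(
    samples: list[HologramSample],
    fold: FoldPair,
    model_config: ModelConfig,
    cfg: TrainConfig,
    class_names,
    model_seed: int | None = None,
    init_model: HologramClassifier | None = None,
) -> tuple[HologramClassifier, TrainingHistory]:
    """Train one classifier on a fold pair with early stopping.

    Class weights are computed from the fold's training labels only.  All
    randomness (init, shuffling, augmentation draws, dropout) derives from
    ``model_seed`` (default ``cfg.seed``).  ``init_model`` warm-starts the
    weights: a model of the same dimensionality is copied, a planar model is
    kernel-inflated into a volumetric one (see
    :func:`holoclass.models.inflate_to_3d`).  Returns the model restored to
    its best-validation-epoch weights together with the learning curves.
    """
    seed = cfg.seed if model_seed is None else model_seed
    rng = np.random.default_rng(seed)
    if init_model is None:
        model = build_classifier(model_config, cfg.model_dims, seed=seed)
    elif init_model.dims == 2 and cfg.model_dims == 3:
        from .models import inflate_to_3d

        model = inflate_to_3d(init_model)
    elif init_model.dims == cfg.model_dims:
        model = build_classifier(model_config, cfg.model_dims, seed=seed)
        model.load_state_dict(init_model.state_dict())
    else:
        raise ValueError("init_model dimensionality incompatible with cfg.model_dims")
    opt = nn.Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)

    all_ids = _labels_to_ids([s.label for s in samples], class_names)
    y_train = all_ids[fold.train_idx]
    y_val = all_ids[fold.val_idx]
    weights = compute_class_weights(y_train, model_config.n_classes)

    builder = _BatchBuilder(samples, cfg)
    # Validation inputs are fixed across epochs.  Under defocus augmentation
    # the validation fold receives one seeded defocus draw so that model
    # selection sees the same input distribution the model trains for.
    val_samples = [samples[i] for i in fold.val_idx]
    if cfg.use_defocus_augment:
        val_samples = make_defocused_test_set(val_samples, seed=seed,
                                              range_um=cfg.defocus_range_um)
    if cfg.model_dims == 3:
        val_x = np.stack(
            [build_volume(s, cfg.n_steps, cfg.step_um).volume for s in val_samples])
    else:
        val_x = np.stack([s.pair.as_array() for s in val_samples])
    history = TrainingHistory()
    best_state, best_val = None, np.inf
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(fold.train_idx))
        ep_losses, ep_hits, ep_n = [], 0, 0
        for start in range(0, len(order), cfg.batch_size):
            sel = fold.train_idx[order[start : start + cfg.batch_size]]
            yb = all_ids[sel]
            xb = builder.build(sel, rng, augment=True)
            opt.zero_grad()
            lp = model.forward(xb, train=True)
            if not np.all(np.isfinite(lp)):
                raise FloatingPointError(
                    f"non-finite network output at epoch {epoch}; training diverged"
                )
            loss = weighted_nll_loss(lp, yb, weights)
            model.backward(_loss_grad(lp, yb, weights).astype(np.float32))
            opt.step()
            ep_losses.append(loss)
            ep_hits += int((lp.argmax(axis=1) == yb).sum())
            ep_n += len(yb)
        val_lp = model.predict_log_proba(val_x, batch_size=cfg.batch_size)
        val_loss = weighted_nll_loss(val_lp, y_val, weights)
        history.train_loss.append(float(np.mean(ep_losses)))
        history.val_loss.append(val_loss)
        history.train_acc.append(ep_hits / ep_n)
        history.val_acc.append(float((val_lp.argmax(axis=1) == y_val).mean()))
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.state_dict()
            history.best_epoch = epoch
        if epoch - history.best_epoch >= cfg.patience_epochs:
            break
    history.stopped_epoch = len(history.train_loss) - 1
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def _predict(model, builder: _BatchBuilder, indices, batch_size: int) -> np.ndarray:
    out = []
    for start in range(0, len(indices), batch_size):
        xb = builder.build(indices[start : start + batch_size], None, augment=False)
        out.append(model.forward(xb, train=False))
    return np.concatenate(out)


def run_cv(
    samples: list[HologramSample],
    manifest: DatasetManifest,
    model_config: ModelConfig,
    cfg: TrainConfig,
    class_names,
    init_models: list[HologramClassifier] | None = None,
) -> tuple[np.ndarray, list[HologramClassifier], list[TrainingHistory]]:
    """Full protocol: split, then train one model per fold configuration.

    Fold ``i`` trains with seed ``cfg.seed + i`` (recorded in checkpoints by
    the command-line layer) and, when ``init_models`` is given, warm-starts
    from ``init_models[i]`` (see :func:`train_model`).  Returns
    ``(test_idx, models, histories)``.
    """
    test_idx, pairs = make_splits(manifest, cfg)
    if init_models is not None and len(init_models) != len(pairs):
        raise ValueError("need one init model per fold")
    models, histories = [], []
    for i, pair in enumerate(pairs):
        m, h = train_model(
            samples, pair, model_config, cfg, class_names, model_seed=cfg.seed + i,
            init_model=None if init_models is None else init_models[i],
        )
        models.append(m)
        histories.append(h)
    return test_idx, models, histories
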