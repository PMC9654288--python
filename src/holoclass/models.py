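"""Hologram classifiers: a 3D residual CNN over refocused volumes and its
matched 2D baseline over a single reconstruction.

Both networks share the same channel plan for a fair comparison.  The body is
four residual convolution blocks; each block runs two Conv-BatchNorm-LeakyReLU
stages, adds a 1x1(x1)-projected skip of its input, and max-pools the spatial
axes by two while leaving the depth axis (when present) untouched.  The head
max-pools the whole depth (3D only), average-pools the spatial extent to 2x2,
flattens, and applies Dropout -> Linear -> LeakyReLU -> Linear -> LogSoftmax,
so the network outputs per-class log-probabilities.

Public tensors are channels-first — ``(B, 2, D, H, W)`` volumes or
``(B, 2, H, W)`` planes — matching how samples are stored; the engine works
channels-last internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn

__all__ = ["ModelConfig", "ResConvBlock", "build_res_conv_block", "build_classifier",
           "HologramClassifier", "inflate_to_3d", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters shared by the 2D and 3D classifiers."""

    in_channels: int = 2
    n_classes: int = 7
    block_channels: tuple[int, int, int, int] = (16, 32, 64, 128)
    leaky_slope: float = 0.01
    dropout_p: float = 0.5
    dense_hidden: int = 128
    conv_kernel: int = 3

    def __post_init__(self) -> None:
        if len(self.block_channels) != 4:
            raise ValueError("block_channels must list exactly 4 entries")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


class ResConvBlock(nn.Layer):
    """Conv-BN-LReLU x2 plus a projected skip, then a spatial 2x2 max pool."""

    def __init__(self, in_ch: int, out_ch: int, dims: int, rng: np.random.Generator,
                 leaky_slope: float = 0.01, kernel: int = 3) -> None:
        if dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if in_ch <= 0 or out_ch <= 0:
            raise ValueError("channel counts must be positive")
        k = (kernel,) * dims
        one = (1,) * dims
        self.dims = dims
        self.main = nn.Sequential(
            nn.Conv(in_ch, out_ch, k, rng, "conv1"),
            nn.BatchNorm(out_ch, name="bn1"),
            nn.LeakyReLU(leaky_slope),
            nn.Conv(out_ch, out_ch, k, rng, "conv2"),
            nn.BatchNorm(out_ch, name="bn2"),
            nn.LeakyReLU(leaky_slope),
        )
        self.proj = nn.Conv(in_ch, out_ch, one, rng, "proj")
        self.pool = nn.SpatialMaxPool()

    def parameters(self):
        return self.main.parameters() + self.proj.parameters()

    def forward(self, x, train=False):
        y = self.main.forward(x, train) + self.proj.forward(x, train)
        return self.pool.forward(y, train)

    def backward(self, grad):
        g = self.pool.backward(grad)
        return self.main.backward(g) + self.proj.backward(g)


def build_res_conv_block(in_ch: int, out_ch: int, dims: int,
                         rng: np.random.Generator | int | None = None,
                         leaky_slope: float = 0.01, kernel: int = 3) -> ResConvBlock:
    """Standalone residual block builder (``dims`` = 2 for planar, 3 for volumetric)."""
    rng = np.random.default_rng(rng)
    return ResConvBlock(in_ch, out_ch, dims, rng, leaky_slope, kernel)


class HologramClassifier(nn.Layer):
    """Full classifier; ``dims`` selects the volumetric or planar variant."""

    def __init__(self, config: ModelConfig, dims: int, seed: int = 0) -> None:
        if dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        self.config = config
        self.dims = dims
        self.seed = seed
        rng = np.random.default_rng(seed)
        blocks = []
        ch = config.in_channels
        for out_ch in config.block_channels:
            blocks.append(ResConvBlock(ch, out_ch, dims, rng, config.leaky_slope, config.conv_kernel))
            ch = out_ch
        self.blocks = blocks
        head = []
        if dims == 3:
            head.append(nn.DepthMaxPool())
        head += [
            nn.SpatialAvgPool(2),
            nn.Flatten(),
            nn.Dropout(config.dropout_p, rng),
            nn.Linear(4 * ch, config.dense_hidden, rng, "fc1"),
            nn.LeakyReLU(config.leaky_slope),
            nn.Linear(config.dense_hidden, config.n_classes, rng, "fc2"),
            nn.LogSoftmax(),
        ]
        # near-uniform initial predictions: start the final layer small so the
        # initial loss sits at ln(n_classes) instead of a large arbitrary value
        head[-2].weight.data *= 0.01
        self.head = nn.Sequential(*head)

    # -- plumbing ----------------------------------------------------------
    def parameters(self):
        return [p for b in self.blocks for p in b.parameters()] + self.head.parameters()

    def _check_input(self, x: np.ndarray) -> None:
        want = self.dims + 2  # batch + channels + spatial(+depth)
        if x.ndim != want:
            raise ValueError(f"{self.dims}D model expects {want}D input (B, C, ..., H, W), got shape {x.shape}")
        h, w = x.shape[-2:]
        if h % 16 or w % 16 or h < 32 or w < 32:
            raise ValueError(
                f"spatial size {h}x{w} must be divisible by 16 and at least 32 "
                "(four 2x2 max pools followed by a 2x2 average pool)")

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=nn._dt())
        self._check_input(x)
        # channels-first -> channels-last
        x = np.moveaxis(x, 1, -1)
        for b in self.blocks:
            x = b.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, grad):
        g = self.head.backward(grad)
        for b in reversed(self.blocks):
            g = b.backward(g)
        return np.moveaxis(g, -1, 1)

    def predict_log_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Evaluation-mode log-probabilities, batched over the first axis."""
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.forward(np.asarray(x[i : i + batch_size]), train=False))
        return np.concatenate(out, axis=0)

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            state[f"p{i:03d}_{p.name}"] = p.data.copy()
        for j, bn in enumerate(self._batchnorms()):
            state[f"bn{j:02d}_running_mean"] = bn.running_mean.copy()
            state[f"bn{j:02d}_running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[f"p{i:03d}_{p.name}"]
        for j, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = state[f"bn{j:02d}_running_mean"]
            bn.running_var[...] = state[f"bn{j:02d}_running_var"]

    def _batchnorms(self) -> list[nn.BatchNorm]:
        bns = []
        for b in self.blocks:
            bns += [l for l in b.main.layers if isinstance(l, nn.BatchNorm)]
        bns += [l for l in self.head.layers if isinstance(l, nn.BatchNorm)]
        return bns


def build_classifier(config: ModelConfig, dims: int, seed: int = 0) -> HologramClassifier:
    """Build the volumetric (``dims=3``) or planar (``dims=2``) classifier."""
    return HologramClassifier(config, dims, seed)


def inflate_to_3d(model2d: HologramClassifier) -> HologramClassifier:
    """Warm-start a volumetric classifier from a trained planar one.

    Kernel inflation: each trained 2D convolution kernel is placed in the
    centre depth slab of the matching 3D kernel (zeros elsewhere), and batch
    norm statistics and the dense head are copied.  At this starting point the
    3D network applies the 2D network to every depth slice and max-pools the
    slice features over depth; fine-tuning on volumes then learns genuine
    depth mixing.  This is the standard way to cut the several-fold training
    cost of volumetric CNNs when a matched planar model is available.
    """
    if model2d.dims != 2:
        raise ValueError("inflate_to_3d expects a 2D model")
    model3d = HologramClassifier(model2d.config, dims=3, seed=model2d.seed)
    k = model2d.config.conv_kernel
    for b2, b3 in zip(model2d.blocks, model3d.blocks):
        for l2, l3 in zip(b2.main.layers + [b2.proj], b3.main.layers + [b3.proj]):
            if isinstance(l2, nn.Conv):
                kd = l3.kernel[0]
                w2 = l2.weight.data.reshape(l2.out_ch, l2.kernel[0] * l2.kernel[1], l2.in_ch)
                w3 = np.zeros((l3.out_ch, kd, l3.kernel[1] * l3.kernel[2], l3.in_ch), dtype=w2.dtype)
                w3[:, kd // 2] = w2
                l3.weight.data[...] = w3.reshape(l3.weight.data.shape)
                l3.bias.data[...] = l2.bias.data
            elif isinstance(l2, nn.BatchNorm):
                l3.gamma.data[...] = l2.gamma.data
                l3.beta.data[...] = l2.beta.data
                l3.running_mean[...] = l2.running_mean
                l3.running_var[...] = l2.running_var
    # dense head: identical shapes, skip the extra DepthMaxPool in the 3D head
    head2 = [l for l in model2d.head.layers if isinstance(l, (nn.Linear, nn.BatchNorm))]
    head3 = [l for l in model3d.head.layers if isinstance(l, (nn.Linear, nn.BatchNorm))]
    for l2, l3 in zip(head2, head3):
        if isinstance(l2, nn.Linear):
            l3.weight.data[...] = l2.weight.data
            l3.bias.data[...] = l2.bias.data
    return model3d


def save_checkpoint(model: HologramClassifier, path: str | Path, extra: dict | None = None) -> None:
    """Save weights as ``.npz`` with a JSON sidecar recording config and seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    meta = {"model_config": asdict(model.config), "dims": model.dims, "seed": model.seed}
    meta.update(extra or {})
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def load_checkpoint(path: str | Path) -> HologramClassifier:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg_d = dict(meta["model_config"])
    cfg_d["block_channels"] = tuple(cfg_d["block_channels"])
    model = HologramClassifier(ModelConfig(**cfg_d), meta["dims"], meta.get("seed", 0))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as state:
        model.load_state_dict(dict(state))
    return model
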