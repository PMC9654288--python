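"""Network-input construction: refocused volumes, defocus and geometric augmentation.

A stored hologram crop is a single reconstruction; the volumetric classifier
instead sees a ladder of reconstructions at equally spaced depths.  The stored
amplitude/phase pair is re-embedded as a complex field and propagated ``k``
steps for ``k = -n_steps .. +n_steps`` (backward and forward of the base
plane), each slice stored again as amplitude and phase — a
``(2, 2*n_steps+1, H, W)`` array whose middle slice is the base reconstruction.

Hologram defocus augmentation propagates the base hologram by a random
distance drawn uniformly from a symmetric range before any volume is built,
so for the 3D branch the in-focus slice shifts away from the middle of the
volume, exactly as a focusing error would do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import HologramSample
from .wave_optics import propagate, to_amplitude_phase

__all__ = [
    "VolumeSample",
    "DEFAULT_DEPTH_STEP_UM",
    "DEFAULT_DEFOCUS_RANGE_UM",
    "build_volume",
    "defocus_augment",
    "geometric_augment",
    "make_defocused_test_set",
    "tamura_sharpness",
]

DEFAULT_DEPTH_STEP_UM = 3.43
#: +-4 depth steps — the continuous range used both for training-time
#: augmentation and for the defocused robustness evaluation.
DEFAULT_DEFOCUS_RANGE_UM = 13.72


@dataclass
class VolumeSample:
    """A (C=2, D, H, W) stack of reconstructions at equally spaced depths."""

    volume: np.ndarray
    depth_step_um: float
    label: str

    def __post_init__(self) -> None:
        if self.volume.ndim != 4 or self.volume.shape[0] != 2:
            raise ValueError(f"volume must be (2, D, H, W), got {self.volume.shape}")
        if self.volume.shape[1] % 2 != 1:
            raise ValueError("depth D must be odd (centre slice = base reconstruction)")
        if self.depth_step_um <= 0:
            raise ValueError("depth_step_um must be positive")

    @property
    def n_steps(self) -> int:
        return self.volume.shape[1] // 2


def build_volume(
    sample: HologramSample, n_steps: int = 6, step_um: float = DEFAULT_DEPTH_STEP_UM
) -> VolumeSample:
    """Propagate a sample ``n_steps`` backward and forward into a depth stack.

    Slice ``n_steps + k`` holds the amplitude/phase of the base field
    propagated by ``k * step_um`` (k < 0 backward, k > 0 forward); slice
    ``n_steps`` is the unpropagated base reconstruction.
    """
    if step_um <= 0:
        raise ValueError(f"step_um must be positive, got {step_um}")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    base = sample.field()
    h, w = base.shape
    depth = 2 * n_steps + 1
    vol = np.empty((2, depth, h, w), dtype=np.float32)
    for k in range(-n_steps, n_steps + 1):
        if k == 0:
            pair = sample.pair
        else:
            pair = to_amplitude_phase(propagate(base, k * step_um))
        vol[:, n_steps + k] = pair.as_array()
    return VolumeSample(volume=vol, depth_step_um=step_um, label=sample.label)


def defocus_augment(
    sample: HologramSample,
    rng: np.random.Generator,
    max_offset_um: float = DEFAULT_DEFOCUS_RANGE_UM,
) -> HologramSample:
    """Propagate the hologram by d ~ Uniform(-max_offset, +max_offset).

    Returns a new sample with ``focus_offset_um`` incremented by the draw; the
    original is untouched.  For the volumetric branch this must be applied to
    the base hologram *before* :func:`build_volume`.
    """
    if max_offset_um < 0:
        raise ValueError("max_offset_um must be >= 0")
    if max_offset_um == 0:
        return sample
    d = float(rng.uniform(-max_offset_um, max_offset_um))
    shifted = propagate(sample.field(), d)
    return HologramSample(
        pair=to_amplitude_phase(shifted),
        label=sample.label,
        focus_offset_um=sample.focus_offset_um + d,
        params=sample.params,
    )


def _apply_dihedral(planes: np.ndarray, quarter_turns: int, hflip: bool, vflip: bool) -> np.ndarray:
    """Apply the same right-angle rotation/flips to the last two axes."""
    out = np.rot90(planes, quarter_turns, axes=(-2, -1))
    if hflip:
        out = out[..., ::-1]
    if vflip:
        out = out[..., ::-1, :]
    return np.ascontiguousarray(out)


def geometric_augment(
    x: HologramSample | VolumeSample, rng: np.random.Generator
) -> HologramSample | VolumeSample:
    """Random right-angle rotation plus optional horizontal/vertical flips.

    The same transform is applied to both channels and, for volumes, to every
    depth slice; the label is unchanged.  Rotations are restricted to
    multiples of 90 degrees so the phase channel is never interpolated.
    """
    k = int(rng.integers(0, 4))
    hflip = bool(rng.integers(0, 2))
    vflip = bool(rng.integers(0, 2))
    if isinstance(x, VolumeSample):
        return VolumeSample(
            volume=_apply_dihedral(x.volume, k, hflip, vflip),
            depth_step_um=x.depth_step_um,
            label=x.label,
        )
    arr = x.pair.as_array(dtype=np.float64)
    arr = _apply_dihedral(arr, k, hflip, vflip)
    from .wave_optics import AmplitudePhasePair

    return HologramSample(
        pair=AmplitudePhasePair(arr[0], arr[1]),
        label=x.label,
        focus_offset_um=x.focus_offset_um,
        params=x.params,
    )


def make_defocused_test_set(
    test: list[HologramSample],
    seed: int,
    range_um: float = DEFAULT_DEFOCUS_RANGE_UM,
) -> list[HologramSample]:
    """One fixed defocus draw per test sample, deterministic given ``seed``.

    The same defocused inputs must be reused for every evaluated model so that
    robustness comparisons share identical inputs.
    """
    rng = np.random.default_rng(seed)
    out = []
    for s in test:
        if s.focus_offset_um != 0:
            raise ValueError("defocused test set must be built from in-focus samples")
        out.append(defocus_augment(s, rng, max_offset_um=range_um))
    return out


def tamura_sharpness(amplitude: np.ndarray) -> float:
    """Tamura coefficient ``sqrt(std/mean)`` of an amplitude image.

    A standard autofocus score for hologram reconstructions: the in-focus
    plane maximises amplitude contrast.
    """
    m = float(np.mean(amplitude))
    if m <= 0:
        return 0.0
    return float(np.sqrt(np.std(amplitude) / m))
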