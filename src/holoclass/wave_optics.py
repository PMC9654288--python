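"""Scalar-diffraction engine: angular-spectrum propagation of complex wavefields.

An in-line hologram records the interference of a plane reference wave with
light diffracted by micro-objects.  Numerical refocusing propagates the
recorded complex field ``u(x, y)`` over an axial distance ``z`` by multiplying
its 2D Fourier transform with the free-space transfer function

    H(f_x, f_y; z) = exp(i 2 pi z sqrt(1 / lambda^2 - f_x^2 - f_y^2))

on the propagating band ``f_x^2 + f_y^2 < 1 / lambda^2`` and zero on the
evanescent remainder.  Positive ``z`` is "forward" propagation (towards the
sensor), negative ``z`` is "backward"; the two are exact inverses on the
propagating band.

All distances are micrometres.  Fields are dimensionless complex amplitudes
sampled on a square grid with equal pixel pitch along both axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalParams",
    "ComplexField",
    "AmplitudePhasePair",
    "transfer_function",
    "propagate",
    "to_amplitude_phase",
    "from_amplitude_phase",
]


@dataclass(frozen=True)
class OpticalParams:
    """Physical sampling parameters of a wavefield grid.

    Parameters
    ----------
    wavelength_um:
        Illumination wavelength in the propagation medium, micrometres.
    pixel_pitch_um:
        Lateral sample spacing, micrometres, equal along both axes.
    """

    wavelength_um: float = 0.532
    pixel_pitch_um: float = 1.0

    def __post_init__(self) -> None:
        if not (self.wavelength_um > 0):
            raise ValueError(f"wavelength_um must be positive, got {self.wavelength_um}")
        if not (self.pixel_pitch_um > 0):
            raise ValueError(f"pixel_pitch_um must be positive, got {self.pixel_pitch_um}")


@dataclass
class ComplexField:
    """A 2D complex optical wavefield with its sampling parameters."""

    values: np.ndarray
    params: OpticalParams

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise ValueError(f"field must be 2D with each side >= 2, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2


@dataclass
class AmplitudePhasePair:
    """Polar decomposition of a complex field: modulus and argument planes."""

    amplitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        self.phase = np.asarray(self.phase, dtype=np.float64)
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase shapes differ")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative")

    def as_array(self, dtype=np.float32) -> np.ndarray:
        """Stack to a (2, H, W) array, channel 0 amplitude, channel 1 phase."""
        return np.stack([self.amplitude, self.phase]).astype(dtype)


def _frequency_grids(shape: tuple[int, int], pitch_um: float) -> tuple[np.ndarray, np.ndarray]:
    # Unshifted FFT layout, f = k / (N * pitch); reproducible bit-for-bit for
    # one FFT backend.
    fy = np.fft.fftfreq(shape[0], d=pitch_um)
    fx = np.fft.fftfreq(shape[1], d=pitch_um)
    return np.meshgrid(fy, fx, indexing="ij")


def transfer_function(
    shape: tuple[int, int], params: OpticalParams, z_um: float
) -> np.ndarray:
    """Angular-spectrum transfer function for propagation over ``z_um``.

    Returns an ``H x W`` complex array in unshifted FFT frequency layout with
    unit modulus on the propagating band and zeros on evanescent frequencies.
    """
    if not isinstance(params, OpticalParams):
        params = OpticalParams(*params)
    fy, fx = _frequency_grids(tuple(shape), params.pixel_pitch_um)
    kz_sq = 1.0 / params.wavelength_um**2 - fx**2 - fy**2
    band = kz_sq > 0
    h = np.zeros(tuple(shape), dtype=np.complex128)
    h[band] = np.exp(2j * np.pi * z_um * np.sqrt(kz_sq[band]))
    return h


def propagate(field: ComplexField, z_um: float, pad_factor: int = 1) -> ComplexField:
    """Propagate a field by ``z_um`` micrometres with the angular spectrum method.

    The FFT implies circular boundary conditions; ``pad_factor > 1`` embeds the
    field in a ``pad_factor``-times larger zero grid before propagation and
    crops the original window afterwards, approximating free-space (linear)
    diffraction when wrap-around leakage matters (e.g. point-like sources).
    """
    if pad_factor < 1 or int(pad_factor) != pad_factor:
        raise ValueError(f"pad_factor must be a positive integer, got {pad_factor}")
    values = field.values
    if not np.all(np.isfinite(values)):
        raise ValueError("cannot propagate a field with non-finite values")
    h0, w0 = values.shape
    if pad_factor > 1:
        big = np.zeros((h0 * pad_factor, w0 * pad_factor), dtype=np.complex128)
        oy = (big.shape[0] - h0) // 2
        ox = (big.shape[1] - w0) // 2
        big[oy : oy + h0, ox : ox + w0] = values
        values = big
    spectrum = np.fft.fft2(values)
    spectrum *= transfer_function(values.shape, field.params, z_um)
    out = np.fft.ifft2(spectrum)
    if pad_factor > 1:
        out = out[oy : oy + h0, ox : ox + w0]
    return ComplexField(out, field.params)


def to_amplitude_phase(field: ComplexField) -> AmplitudePhasePair:
    """Decompose ``a + ib`` into modulus ``sqrt(a^2 + b^2)`` and argument.

    The argument is the quadrant-aware arctangent in ``(-pi, pi]``; zero-valued
    pixels get phase 0 so the codec is deterministic.
    """
    amp = np.abs(field.values)
    phase = np.angle(field.values)
    phase[amp == 0] = 0.0
    # np.angle returns [-pi, pi]; fold the closed lower end onto +pi.
    phase[phase == -np.pi] = np.pi
    return AmplitudePhasePair(amp, phase)


def from_amplitude_phase(pair: AmplitudePhasePair, params: OpticalParams) -> ComplexField:
    """Recompose a complex field from amplitude and phase planes."""
    if np.any(pair.amplitude < 0):
        raise ValueError("amplitude must be non-negative")
    return ComplexField(pair.amplitude * np.exp(1j * pair.phase), params)
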