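"""Physics-based generator of labelled in-line hologram crops.

The generator emulates the kind of dataset the classifiers are built for:
background-subtracted holograms of *Phaeodactylum tricornutum* (TRC), a
fusiform alga that aggregates into clusters whose member counts concentrate
near powers of two, plus two auxiliary categories — consistently small
particles (SP) and irregular low-contrast debris (DEBRIS).

Each scene is a thin-object transmittance in the nominal focal plane: every
particle is an anti-aliased elliptical mask with an amplitude transmittance
and a phase shift, propagated to its own small axial offset so that clusters
have genuine 3D structure.  The hologram is recorded as intensity at the
sensor plane (a unit-amplitude plane reference plus the diffracted wave),
background-subtracted, re-embedded as a real-amplitude field — discarding the
sensor-plane phase exactly as an intensity-only camera does, so the twin
image is present — and finally refocused back to the object plane.  Samples
are stored as amplitude/phase pairs of that in-focus reconstruction.

Class frequencies default to halving for each doubling of cluster size,
giving the imbalanced class distribution typical of such recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .wave_optics import (
    AmplitudePhasePair,
    ComplexField,
    OpticalParams,
    from_amplitude_phase,
    propagate,
    to_amplitude_phase,
)

__all__ = [
    "CLASS_NAMES",
    "ParticleSpec",
    "SceneSpec",
    "SimulationConfig",
    "DatasetManifest",
    "HologramSample",
    "sample_scene",
    "render_object_plane",
    "simulate_hologram",
    "generate_dataset",
]

CLASS_NAMES = ("TRC1", "TRC2", "TRC4", "TRC8", "TRC16", "SP", "DEBRIS")
_TRC_SIZES = {"TRC1": 1, "TRC2": 2, "TRC4": 4, "TRC8": 8, "TRC16": 16}


@dataclass(frozen=True)
class ParticleSpec:
    """One micro-object: an elliptical thin-object mask in its own z plane."""

    center_xyz_um: tuple[float, float, float]  # lateral x, y; axial z offset
    shape: str  # rod | ellipse | blob
    size_um: tuple[float, float]  # major, minor axis lengths
    amplitude_transmittance: float
    phase_shift_rad: float
    orientation_rad: float = 0.0

    def __post_init__(self) -> None:
        if min(self.size_um) <= 0:
            raise ValueError("particle sizes must be positive")
        if not 0 <= self.amplitude_transmittance <= 1:
            raise ValueError("amplitude transmittance must be in [0, 1]")
        if self.shape not in ("rod", "ellipse", "blob"):
            raise ValueError(f"unknown particle shape {self.shape!r}")


@dataclass(frozen=True)
class SceneSpec:
    """Ground-truth description of the objects behind one hologram crop."""

    particles: tuple[ParticleSpec, ...]
    class_label: str
    sensor_distance_um: float
    params: OpticalParams
    crop_px: int = 128

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_NAMES:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.sensor_distance_um <= 0:
            raise ValueError("sensor_distance_um must be positive")


@dataclass
class HologramSample:
    """Stored record: amplitude/phase pair of a reconstruction plus metadata."""

    pair: AmplitudePhasePair
    label: str
    focus_offset_um: float
    params: OpticalParams

    def field(self) -> ComplexField:
        """Re-embed the stored pair as a complex field for further propagation."""
        return from_amplitude_phase(self.pair, self.params)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults emulate a lens-free in-line geometry."""

    optics: OpticalParams = OpticalParams()
    crop_px: int = 128
    sensor_distance_um: float = 300.0
    # per-class target counts; TRC counts halve per doubling cluster size
    class_counts: dict[str, int] = field(
        default_factory=lambda: {
            "TRC1": 320, "TRC2": 160, "TRC4": 80, "TRC8": 40, "TRC16": 20,
            "SP": 160, "DEBRIS": 80,
        }
    )
    noise_sigma: float = 0.01
    axial_jitter_um: float = 5.0
    rod_major_um: tuple[float, float] = (8.0, 15.0)
    rod_minor_um: tuple[float, float] = (2.0, 3.0)
    sp_diameter_um: tuple[float, float] = (2.0, 4.0)


@dataclass
class DatasetManifest:
    """Bookkeeping for a generated dataset."""

    records: pd.DataFrame  # columns: id, label, true_focus_um, split, seed
    class_counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.records["id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        observed = self.records["label"].value_counts().to_dict()
        if observed != {k: v for k, v in self.class_counts.items() if v}:
            raise ValueError("class_counts inconsistent with records")

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def nearest_class_size(count: int) -> int:
    """Nearest power-of-two cluster size to ``count`` (geometric distance).

    Counts that fall between categories are assigned to the closest
    neighbouring class; on a log scale the midpoints between 2^k and 2^(k+1)
    are unambiguous, e.g. 6 -> 8 and 12 -> 16.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    sizes = np.array([1, 2, 4, 8, 16])
    return int(sizes[np.argmin(np.abs(np.log(sizes) - np.log(count)))])


def _count_support(k: int) -> np.ndarray:
    """Admissible member counts for a TRC-k scene: k +- floor(k/4)."""
    lo, hi = k - k // 4, k + k // 4
    return np.arange(lo, hi + 1)


def sample_scene(
    class_label: str,
    rng: np.random.Generator,
    config: SimulationConfig | None = None,
) -> SceneSpec:
    """Draw a random scene of the given class.

    TRC scenes place ``n`` rods (``n`` drawn from the class's admissible count
    range) in a compact cluster whose lateral spread grows with ``sqrt(n)``,
    with uniform axial jitter so large conglomerates extend out of any single
    focal plane.  SP scenes hold a few discs strictly smaller than a TRC minor
    axis; DEBRIS scenes hold overlapping faint blobs.
    """
    config = config or SimulationConfig()
    if class_label not in CLASS_NAMES:
        raise ValueError(f"unknown class label {class_label!r}; expected one of {CLASS_NAMES}")
    jit = config.axial_jitter_um
    particles: list[ParticleSpec] = []
    if class_label in _TRC_SIZES:
        k = _TRC_SIZES[class_label]
        n = int(rng.choice(_count_support(k)))
        spread = 3.0 + 2.0 * np.sqrt(n)
        for _ in range(n):
            cx, cy = rng.normal(0.0, spread, size=2)
            particles.append(
                ParticleSpec(
                    center_xyz_um=(float(cx), float(cy), float(rng.uniform(-jit, jit))),
                    shape="rod",
                    size_um=(float(rng.uniform(*config.rod_major_um)),
                             float(rng.uniform(*config.rod_minor_um))),
                    amplitude_transmittance=float(rng.uniform(0.15, 0.45)),
                    phase_shift_rad=float(rng.uniform(0.0, 0.15)),
                    orientation_rad=float(rng.uniform(0, np.pi)),
                )
            )
    elif class_label == "SP":
        for _ in range(int(rng.integers(1, 4))):
            d = float(rng.uniform(*config.sp_diameter_um))
            cx, cy = rng.normal(0.0, 6.0, size=2)
            particles.append(
                ParticleSpec(
                    center_xyz_um=(float(cx), float(cy), float(rng.uniform(-jit, jit))),
                    shape="ellipse",
                    size_um=(d, d * float(rng.uniform(0.8, 1.0))),
                    amplitude_transmittance=float(rng.uniform(0.3, 0.6)),
                    phase_shift_rad=float(rng.uniform(0.0, 0.15)),
                    orientation_rad=float(rng.uniform(0, np.pi)),
                )
            )
    else:  # DEBRIS: irregular faint multi-blob clutter
        for _ in range(int(rng.integers(2, 7))):
            cx, cy = rng.normal(0.0, 12.0, size=2)
            major = float(rng.uniform(3.0, 10.0))
            particles.append(
                ParticleSpec(
                    center_xyz_um=(float(cx), float(cy), float(rng.uniform(-jit, jit))),
                    shape="blob",
                    size_um=(major, major * float(rng.uniform(0.3, 1.0))),
                    amplitude_transmittance=float(rng.uniform(0.7, 0.95)),
                    phase_shift_rad=float(rng.uniform(-0.1, 0.1)),
                    orientation_rad=float(rng.uniform(0, np.pi)),
                )
            )
    # Recentre the cluster axially: recorded crops are focused per object, so
    # the nominal reconstruction plane is the cluster's mean plane.
    if particles:
        z_bar = float(np.mean([p.center_xyz_um[2] for p in particles]))
        particles = [
            replace(p, center_xyz_um=(p.center_xyz_um[0], p.center_xyz_um[1],
                                      p.center_xyz_um[2] - z_bar))
            for p in particles
        ]
    return SceneSpec(
        particles=tuple(particles),
        class_label=class_label,
        sensor_distance_um=config.sensor_distance_um,
        params=config.optics,
        crop_px=config.crop_px,
    )


def _particle_mask(p: ParticleSpec, n: int, pitch: float) -> np.ndarray:
    """Anti-aliased elliptical mask on the crop grid (1 inside, 0 outside)."""
    coords = (np.arange(n) - n / 2 + 0.5) * pitch
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    x = xx - p.center_xyz_um[0]
    y = yy - p.center_xyz_um[1]
    c, s = np.cos(p.orientation_rad), np.sin(p.orientation_rad)
    u = c * x + s * y
    v = -s * x + c * y
    a, b = p.size_um[0] / 2, p.size_um[1] / 2
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    # soft edge about one pixel wide, in normalised radius units
    edge = pitch / min(a, b)
    return np.clip((1.0 - rho) / edge + 0.5, 0.0, 1.0)


def render_object_plane(scene: SceneSpec) -> ComplexField:
    """Render the complex transmittance of a scene in the nominal focal plane.

    Each particle's thin-object factor ``1 - (1 - t) m`` times ``exp(i phi m)``
    (``m`` its mask) is propagated to the particle's axial offset and the
    factors are multiplied, so disjoint in-plane particles compose
    multiplicatively and off-plane particles arrive defocused.
    """
    n = scene.crop_px
    pitch = scene.params.pixel_pitch_um
    field_vals = np.ones((n, n), dtype=np.complex128)
    half = n * pitch / 2
    for p in scene.particles:
        if max(abs(p.center_xyz_um[0]), abs(p.center_xyz_um[1])) > half:
            import warnings

            warnings.warn(f"particle at {p.center_xyz_um[:2]} outside the crop; clipped")
            continue
        mask = _particle_mask(p, n, pitch)
        factor = (1.0 - (1.0 - p.amplitude_transmittance) * mask) * np.exp(
            1j * p.phase_shift_rad * mask
        )
        z = p.center_xyz_um[2]
        contribution = ComplexField(factor, scene.params)
        if z != 0.0:
            contribution = propagate(contribution, z)
        field_vals *= contribution.values
    return ComplexField(field_vals, scene.params)


def simulate_hologram(
    scene: SceneSpec,
    rng: np.random.Generator | None = None,
    noise_sigma: float = 0.0,
    reconstruct: bool = True,
    autofocus_steps: int = 24,
    autofocus_step_um: float = 3.43 / 4,
) -> HologramSample:
    """Record, refocus and autofocus a hologram of the scene.

    The sensor records intensity only: ``I = |propagate(t, z_s)|^2``.  The
    stored hologram is background-subtracted (``I - 1`` for a unit plane
    reference) plus optional Gaussian sensor noise.  Re-embedding adds the
    unit background back and takes ``sqrt`` (clipped at zero), giving a
    real-amplitude sensor field whose phase is lost — which is what makes the
    twin image appear after refocusing, as in a real intensity recording.

    With ``reconstruct=True`` the recorded field is back-propagated to the
    nominal object plane and then autofocused: the plane with the highest
    Tamura amplitude contrast on a ladder of ``autofocus_steps`` steps of
    ``autofocus_step_um`` either side is stored, emulating the per-object
    focusing of real crops (``autofocus_steps=0`` disables the search).  With
    ``reconstruct=False`` the raw sensor-plane field is stored instead.
    """
    obj = render_object_plane(scene)
    sensor = propagate(obj, scene.sensor_distance_um)
    holo = sensor.intensity() - 1.0  # |reference|^2 == 1
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("noise requires a seeded rng")
        holo = holo + rng.normal(0.0, noise_sigma, holo.shape)
    amp = np.sqrt(np.clip(holo + 1.0, 0.0, None))
    recorded = ComplexField(amp.astype(np.complex128), scene.params)
    if reconstruct:
        recon = propagate(recorded, -scene.sensor_distance_um)
        if autofocus_steps > 0:
            from .volumes import tamura_sharpness  # local import: volumes imports us

            best, best_score = recon, -np.inf
            for k in range(-autofocus_steps, autofocus_steps + 1):
                cand = propagate(recon, k * autofocus_step_um) if k else recon
                score = tamura_sharpness(np.abs(cand.values))
                if score > best_score:
                    best, best_score = cand, score
            recon = best
        pair = to_amplitude_phase(recon)
    else:
        pair = to_amplitude_phase(recorded)
    return HologramSample(pair=pair, label=scene.class_label, focus_offset_um=0.0, params=scene.params)


def generate_dataset(
    config: SimulationConfig,
    master_seed: int,
) -> tuple[DatasetManifest, list[HologramSample]]:
    """Generate the full labelled dataset deterministically from one seed.

    Every sample gets its own child seed spawned from ``master_seed`` (recorded
    in the manifest), so individual samples are reproducible in isolation.
    """
    counts = {k: int(v) for k, v in config.class_counts.items() if int(v) > 0}
    if not counts or sum(counts.values()) == 0:
        raise ValueError("config must request at least one sample")
    unknown = set(counts) - set(CLASS_NAMES)
    if unknown:
        raise ValueError(f"unknown classes in config: {sorted(unknown)}")
    root = np.random.SeedSequence(master_seed)
    rows = []
    samples: list[HologramSample] = []
    i = 0
    for label in CLASS_NAMES:  # fixed class order for determinism
        for _ in range(counts.get(label, 0)):
            child = root.spawn(1)[0]
            seed = int(child.generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(seed)
            scene = sample_scene(label, rng, config)
            sample = simulate_hologram(scene, rng, noise_sigma=config.noise_sigma)
            rows.append(
                {"id": f"s{i:05d}", "label": label, "true_focus_um": 0.0,
                 "split": "", "seed": seed}
            )
            samples.append(sample)
            i += 1
    manifest = DatasetManifest(records=pd.DataFrame(rows), class_counts=counts)
    return manifest, samples
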