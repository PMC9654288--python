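"""Synthetic hologram generator: sampling contracts, physics oracles, determinism."""

import numpy as np
import pandas as pd
import pytest

from holoclass import (
    CLASS_NAMES,
    ComplexField,
    OpticalParams,
    ParticleSpec,
    SceneSpec,
    SimulationConfig,
    build_volume,
    generate_dataset,
    propagate,
    render_object_plane,
    sample_scene,
    simulate_hologram,
    tamura_sharpness,
)
from holoclass.synthetic import nearest_class_size


@pytest.fixture
def sim64() -> SimulationConfig:
    return SimulationConfig(crop_px=64)


class TestSceneSampling:
    def test_trc1_always_single_rod(self, sim64):
        for seed in range(20):
            scene = sample_scene("TRC1", np.random.default_rng(seed), sim64)
            assert len(scene.particles) == 1
            assert scene.particles[0].shape == "rod"

    def test_trc16_counts_stay_nearest_to_16(self, sim64):
        for seed in range(200):
            scene = sample_scene("TRC16", np.random.default_rng(seed), sim64)
            assert nearest_class_size(len(scene.particles)) == 16

    def test_trc4_count_distribution(self, sim64):
        # support is {3, 4, 5}: 4 +- floor(4/4); uniform draw has mean 4
        counts = [
            len(sample_scene("TRC4", np.random.default_rng(s), sim64).particles)
            for s in range(1000)
        ]
        assert set(counts) == {3, 4, 5}
        assert abs(np.mean(counts) - 4) < 0.2

    def test_sp_strictly_smaller_than_trc_minor_axis(self, sim64):
        for seed in range(20):
            scene = sample_scene("SP", np.random.default_rng(seed), sim64)
            for p in scene.particles:
                assert max(p.size_um) < min(sim64.rod_minor_um) + 2.1  # sp <= 4 um

    def test_cluster_mean_depth_is_zero(self, sim64):
        scene = sample_scene("TRC8", np.random.default_rng(3), sim64)
        zs = [p.center_xyz_um[2] for p in scene.particles]
        assert np.mean(zs) == pytest.approx(0.0, abs=1e-9)

    def test_unknown_label_rejected(self, sim64):
        with pytest.raises(ValueError, match="unknown class label"):
            sample_scene("TRC3", np.random.default_rng(0), sim64)

    def test_deterministic_given_seed(self, sim64):
        a = sample_scene("TRC4", np.random.default_rng(42), sim64)
        b = sample_scene("TRC4", np.random.default_rng(42), sim64)
        assert a == b


def _particle(cx=0.0, cy=0.0, z=0.0, t=0.0, phi=0.0, size=(20.0, 12.0), shape="ellipse"):
    return ParticleSpec(
        center_xyz_um=(cx, cy, z),
        shape=shape,
        size_um=size,
        amplitude_transmittance=t,
        phase_shift_rad=phi,
    )


def _scene(particles, optics, crop=64, sensor=300.0):
    return SceneSpec(
        particles=tuple(particles),
        class_label="TRC1",
        sensor_distance_um=sensor,
        params=optics,
        crop_px=crop,
    )


class TestRenderObjectPlane:
    def test_empty_scene_is_unit_field(self, optics):
        field = render_object_plane(_scene([], optics))
        assert np.allclose(field.values, 1.0)

    def test_opaque_particle_blocks_light(self, optics):
        field = render_object_plane(_scene([_particle(t=0.0)], optics))
        n = field.shape[0]
        assert abs(field.values[n // 2, n // 2]) < 1e-9  # fully blocked inside
        assert abs(field.values[2, 2]) == pytest.approx(1.0)  # untouched outside

    def test_disjoint_particles_compose_multiplicatively(self, optics):
        p1 = _particle(cx=-15.0, t=0.4, size=(8.0, 4.0))
        p2 = _particle(cx=15.0, t=0.7, phi=0.2, size=(6.0, 6.0))
        both = render_object_plane(_scene([p1, p2], optics)).values
        f1 = render_object_plane(_scene([p1], optics)).values
        f2 = render_object_plane(_scene([p2], optics)).values
        assert np.allclose(both, f1 * f2, atol=1e-12)

    def test_in_plane_scene_never_exceeds_unit_amplitude(self, optics):
        ps = [_particle(cx=-8, t=0.3, phi=0.5), _particle(cx=10, t=0.6, phi=-0.2)]
        field = render_object_plane(_scene(ps, optics))
        assert np.max(np.abs(field.values)) <= 1.0 + 1e-12

    def test_out_of_crop_particle_warns_and_clips(self, optics):
        with pytest.warns(UserWarning, match="outside the crop"):
            field = render_object_plane(_scene([_particle(cx=200.0, t=0.0)], optics))
        assert np.allclose(field.values, 1.0)


class TestSimulateHologram:
    def test_empty_scene_background_subtracts_to_zero(self, optics):
        sample = simulate_hologram(_scene([], optics), reconstruct=False)
        # |sensor field|^2 - |reference|^2 == 0 -> re-embedded amplitude is 1
        assert np.allclose(sample.pair.amplitude, 1.0, atol=1e-9)
        assert np.allclose(sample.pair.phase, 0.0, atol=1e-9)

    def test_refocusing_localises_particle(self, optics):
        # back-propagation concentrates the diffracted energy at the particle
        cx, cy = 5.0, -8.0
        scene = _scene([_particle(cx=cx, cy=cy, t=0.1, size=(6.0, 4.0))], optics)
        sample = simulate_hologram(scene, autofocus_steps=0)
        deviation = np.abs(sample.pair.amplitude - 1.0)
        iy, ix = np.unravel_index(np.argmax(deviation), deviation.shape)
        n = scene.crop_px
        coords = (np.arange(n) - n / 2 + 0.5) * optics.pixel_pitch_um
        assert abs(coords[ix] - cx) <= optics.pixel_pitch_um
        assert abs(coords[iy] - cy) <= optics.pixel_pitch_um

    def test_weak_scenes_superpose_linearly(self, optics):
        # first-Born regime: hologram of two weak particles ~ sum of singles
        p1 = _particle(cx=-12.0, t=0.93, phi=0.03, size=(6.0, 4.0))
        p2 = _particle(cx=13.0, cy=6.0, t=0.95, phi=0.02, size=(5.0, 5.0))
        def holo(ps):
            s = simulate_hologram(_scene(ps, optics), reconstruct=False)
            return s.pair.amplitude**2 - 1.0
        h12, h1, h2 = holo([p1, p2]), holo([p1]), holo([p2])
        err = np.linalg.norm(h12 - h1 - h2) / np.linalg.norm(h12)
        assert err < 0.10

    def test_invalid_sensor_distance_rejected(self, optics):
        with pytest.raises(ValueError, match="sensor_distance"):
            SceneSpec(particles=(), class_label="SP", sensor_distance_um=0.0,
                      params=optics, crop_px=64)

    def test_noise_requires_rng(self, optics):
        with pytest.raises(ValueError, match="rng"):
            simulate_hologram(_scene([], optics), noise_sigma=0.1)


class TestGenerateDataset:
    def test_counts_bookkeeping(self):
        cfg = SimulationConfig(crop_px=32, class_counts={"TRC1": 10, "TRC2": 5})
        manifest, samples = generate_dataset(cfg, master_seed=0)
        assert len(manifest.records) == len(samples) == 15
        assert manifest.class_counts == {"TRC1": 10, "TRC2": 5}
        assert manifest.records["id"].is_unique

    def test_same_seed_reproduces_everything(self):
        cfg = SimulationConfig(crop_px=32, class_counts={"TRC1": 4, "SP": 3})
        m1, s1 = generate_dataset(cfg, master_seed=9)
        m2, s2 = generate_dataset(cfg, master_seed=9)
        pd.testing.assert_frame_equal(m1.records, m2.records)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.pair.amplitude, b.pair.amplitude)
            assert np.array_equal(a.pair.phase, b.pair.phase)

    def test_different_seed_changes_samples(self):
        cfg = SimulationConfig(crop_px=32, class_counts={"TRC1": 2})
        _, s1 = generate_dataset(cfg, master_seed=1)
        _, s2 = generate_dataset(cfg, master_seed=2)
        assert not np.array_equal(s1[0].pair.amplitude, s2[0].pair.amplitude)

    def test_default_class_counts_are_imbalanced(self):
        counts = SimulationConfig().class_counts
        trc = [counts[f"TRC{k}"] for k in (1, 2, 4, 8, 16)]
        assert all(a > b for a, b in zip(trc, trc[1:]))

    def test_empty_config_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(SimulationConfig(class_counts={}), master_seed=0)


class TestStatisticalProperties:
    def test_amplitude_deficit_monotone_in_cluster_size(self, sim64):
        """Bigger conglomerates remove more light from the reconstruction."""
        means = []
        for label in ("TRC1", "TRC2", "TRC4", "TRC8", "TRC16"):
            deficits = []
            for i in range(100):
                rng = np.random.default_rng(10_000 + i)
                scene = sample_scene(label, rng, sim64)
                s = simulate_hologram(scene, rng, noise_sigma=sim64.noise_sigma)
                deficits.append(np.sum(np.clip(1.0 - s.pair.amplitude, 0, None)))
            means.append(np.mean(deficits))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_stored_sample_is_sharpest_on_ladder(self, sim64):
        """In-focus storage: the base slice maximises Tamura sharpness for
        >= 95% of samples across all classes."""
        hits = total = 0
        for j, label in enumerate(CLASS_NAMES):
            for i in range(10):
                rng = np.random.default_rng(20_000 + 100 * j + i)
                scene = sample_scene(label, rng, sim64)
                s = simulate_hologram(scene, rng, noise_sigma=sim64.noise_sigma)
                vol = build_volume(s)
                scores = [tamura_sharpness(vol.volume[0, d]) for d in range(13)]
                hits += int(np.argmax(scores) == 6)
                total += 1
        assert hits / total >= 0.95
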