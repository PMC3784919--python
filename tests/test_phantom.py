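"""Phantom generator: determinism, rod geometry, corruption bookkeeping."""

import numpy as np
import pytest

from histostack.core import SectionSeries, Volume3D
from histostack.metrics import ncc
from histostack.phantom import (
    CoilData,
    CorruptionSpec,
    PhantomSpec,
    add_bias_hotspot,
    corrupt_sections,
    make_phantom,
    rod_indicator,
    simulate_coils,
    virtual_section,
)
from histostack.transforms import invert, resample


class TestMakePhantom:
    def test_deterministic_per_seed(self, small_phantom):
        spec, vol, lab, _ = small_phantom
        vol2, lab2, _ = make_phantom(spec)
        assert np.array_equal(vol.data, vol2.data)
        assert np.array_equal(lab.data, lab2.data)

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(grid_dims=(16, 96, 96))

    def test_duplicate_tissue_levels_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(tissue_levels=(0, 60, 60, 200))

    def test_axial_rod_centroids_constant(self):
        spec = PhantomSpec(
            grid_dims=(40, 64, 64),
            voxel_size=(200, 150, 150),
            rod=dict(direction=(0, 0, 1), radius=400, intensity=255),
            seed=1,
        )
        _, lab, _ = make_phantom(spec)
        cents = []
        for k in range(lab.shape[0]):
            rr, cc = np.nonzero(lab.data[k] == 4)
            if rr.size:
                cents.append((cc.mean(), rr.mean()))
        cents = np.asarray(cents)
        assert np.ptp(cents, axis=0).max() < 0.5

    def test_oblique_rod_centroid_drift_matches_geometry(self):
        # direction (1, 0, 2)/sqrt(5): x drifts by voxel_size_z/2 per z step
        spec = PhantomSpec(
            grid_dims=(40, 64, 64),
            voxel_size=(200, 150, 150),
            rod=dict(
                direction=np.array([1, 0, 2]) / np.sqrt(5),
                radius=400,
                intensity=255,
            ),
            seed=1,
        )
        _, lab, _ = make_phantom(spec)
        ks, xs = [], []
        for k in range(lab.shape[0]):
            rr, cc = np.nonzero(lab.data[k] == 4)
            if rr.size:
                ks.append(k)
                xs.append(cc.mean())
        slope_vox = np.polyfit(ks, xs, 1)[0]
        expected = (200.0 / 2) / 150.0
        assert abs(slope_vox - expected) < 0.5

    def test_rod_indicator_centroids_on_axis(self):
        spec = PhantomSpec(
            grid_dims=(40, 64, 64),
            voxel_size=(200, 150, 150),
            rod=dict(direction=(1, 0, 2.5), radius=400, intensity=255),
            seed=1,
        )
        _, lab, axis = make_phantom(spec)
        soft = rod_indicator(lab, axis, 400.0)
        from histostack.metrics import rod_straightness

        assert rod_straightness(soft) < 0.2 * 150  # well under a voxel


class TestVirtualSection:
    def test_every_tenth_section_sampling_scheme(self):
        # 100 slices of 20 µm, keep every 10th -> 10 sections at 0..1800 µm
        vol = Volume3D(np.zeros((100, 32, 32)), voxel_size=(20, 100, 100))
        series, zs = virtual_section(vol, thickness=20.0, keep_every=10)
        assert len(series) == 10
        assert np.allclose(zs, np.arange(10) * 200.0)
        assert series.spacing == 200.0

    def test_identity_sampling_returns_planes(self, small_phantom):
        _, vol, _, _ = small_phantom
        series, _ = virtual_section(vol, thickness=200.0, keep_every=1)
        assert len(series) == vol.shape[0]
        assert np.array_equal(series[3].pixels, vol.data[3])

    def test_too_thick_section_rejected(self):
        vol = Volume3D(np.zeros((40, 32, 32)), voxel_size=(20, 100, 100))
        with pytest.raises(ValueError):
            virtual_section(vol, thickness=20.0 * 100, keep_every=1)

    def test_restack_round_trip(self, small_phantom):
        _, vol, _, _ = small_phantom
        series, _ = virtual_section(vol, thickness=200.0, keep_every=2)
        stacked = np.stack([np.asarray(s.pixels) for s in series])
        assert np.array_equal(stacked, vol.data[::2])


class TestCorruption:
    def test_zero_spec_is_identity(self, tissue_sections):
        cspec = CorruptionSpec(
            max_rotation=0, max_translation=0, noise_sd=0, seed=3
        )
        out, truth = corrupt_sections(tissue_sections, cspec)
        for s, o, r in zip(tissue_sections, out, truth.per_section_rigid):
            assert r.is_identity()
            assert np.allclose(o.pixels, np.asarray(s.pixels, float))

    def test_rotation_draws_within_and_spanning_range(self, tissue_sections):
        cspec = CorruptionSpec(max_rotation=10, max_translation=0, seed=4)
        _, truth = corrupt_sections(tissue_sections, cspec)
        thetas = np.array([r.theta for r in truth.per_section_rigid])
        assert np.all(np.abs(thetas) <= 10)
        # max of |U(-10,10)| over >= 20 draws exceeds 5 with prob ~1-2^-20
        assert np.abs(thetas).max() > 5

    def test_gain_stripes_generate_intensity_variation(self, tissue_sections):
        cspec = CorruptionSpec(
            max_rotation=0, max_translation=0, gain_range=(0.5, 2.0), seed=5
        )
        out, _ = corrupt_sections(tissue_sections, cspec)
        means = np.array([np.asarray(s.pixels, float).mean() for s in out])
        assert means.std() / means.mean() >= 0.2

    def test_recorded_inverse_recovers_clean_section(self, tissue_sections):
        cspec = CorruptionSpec(
            max_rotation=8,
            max_translation=1000,
            deform_amplitude=200,
            deform_wavelength=4000,
            noise_sd=0,
            seed=6,
        )
        out, truth = corrupt_sections(tissue_sections, cspec)
        i = len(out) // 2
        rec = resample(out[i], invert(truth.applied_transform(i)))
        clean = np.asarray(tissue_sections[i].pixels, float)
        # interior mask: the specimen boundary ring mixes moved-in/out
        # content and is not an interpolation artifact
        from scipy import ndimage

        m = ndimage.binary_erosion(clean > 1, iterations=3)
        assert ncc(np.asarray(rec.pixels)[m], clean[m]) > 0.99

    def test_deterministic_per_seed(self, tissue_sections):
        cspec = CorruptionSpec(max_rotation=5, max_translation=500, noise_sd=2, seed=9)
        a, _ = corrupt_sections(tissue_sections, cspec)
        b, _ = corrupt_sections(tissue_sections, cspec)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.pixels, sb.pixels)


class TestBiasHotspot:
    def test_unit_gain_is_identity(self, small_phantom):
        _, vol, _, _ = small_phantom
        out, bias = add_bias_hotspot(vol, vol.phys_center(), fwhm_mm=10, peak_gain=1.0)
        assert np.allclose(out.data, vol.data)
        assert np.allclose(bias.data, 1.0)

    def test_center_and_half_maximum_values(self):
        # odd grid so the volume centre falls exactly on a voxel centre
        vol = Volume3D(np.ones((41, 41, 41)), voxel_size=(500, 500, 500))
        cx, cy, cz = vol.phys_center()
        out, bias = add_bias_hotspot(vol, (cx, cy, cz), fwhm_mm=10, peak_gain=3.0)
        idx = vol.phys_to_index(np.array([[cx, cy, cz]])).ravel()
        k, j, i = (int(round(v)) for v in idx)
        assert bias.data[k, j, i] == pytest.approx(3.0, abs=1e-3)
        # at radius FWHM/2 the bump is at half its height
        i2 = int(round(i + 5000.0 / 500))
        assert bias.data[k, j, i2] == pytest.approx(1 + (3 - 1) / 2, abs=1e-2)


class TestSimulateCoils:
    def test_single_channel_uniform_sensitivity(self, small_phantom):
        _, vol, _, _ = small_phantom
        cd = simulate_coils(vol, C=1, noise_sd=0.0, seed=0)
        assert np.allclose(np.abs(cd.channels[0]), np.abs(vol.data))

    def test_noiseless_sos_identity(self, small_phantom):
        _, vol, _, _ = small_phantom
        cd = simulate_coils(vol, C=6, noise_sd=0.0, seed=2)
        sos = np.sqrt((np.abs(cd.channels) ** 2).sum(0))
        analytic = np.sqrt((np.abs(cd.sensitivities) ** 2).sum(0)) * np.abs(
            np.asarray(vol.data, float)
        )
        assert np.abs(sos - analytic).max() < 1e-6

    def test_same_seed_same_noise(self, small_phantom):
        _, vol, _, _ = small_phantom
        a = simulate_coils(vol, C=4, noise_sd=5.0, seed=3)
        b = simulate_coils(vol, C=4, noise_sd=5.0, seed=3)
        assert np.array_equal(a.channels, b.channels)
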