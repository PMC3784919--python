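"""Registration engines: identity recovery, ground-truth recovery, the
non-linear acceptance gate, and metric-trace behaviour."""

import numpy as np
import pytest

from histostack.core import Section2D, SectionSeries, Volume3D
from histostack.metrics import ncc
from histostack.phantom import (
    CorruptionSpec,
    PhantomSpec,
    corrupt_sections,
    make_phantom,
)
from histostack.preprocess import background_mask
from histostack.register import (
    PassSchedule,
    RigidPass,
    default_schedule,
    register_affine_3d,
    register_nonlinear_2d,
    register_rigid_2d,
)
from histostack.transforms import (
    AffineTransform3D,
    DeformationField2D,
    compose,
    map_points,
    resample,
    resample_volume,
)


@pytest.fixture(scope="module")
def mid_section(tissue_sections):
    s = tissue_sections[len(tissue_sections) // 2]
    return s.with_pixels(s.pixels, mask=background_mask(s))


class TestRigid2D:
    def test_identity_recovery(self, mid_section):
        t, trace = register_rigid_2d(mid_section, mid_section)
        assert abs(t.theta) < 0.1
        px = np.mean(mid_section.pixel_size)
        assert np.hypot(t.tx, t.ty) < 0.2 * px
        # accepted passes never decrease the NMI trace
        nmis = [p["nmi"] for p in trace]
        assert all(b >= a - 1e-12 for a, b in zip(nmis, nmis[1:]))

    def test_pure_translation_recovery(self, mid_section):
        from histostack.transforms import RigidTransform2D

        px = 120.0
        true = RigidTransform2D(tx=5 * px, ty=0.0)
        moved = resample(mid_section, true, interpolation="cubic")
        moved = moved.with_pixels(moved.pixels, mask=background_mask(moved))
        est, _ = register_rigid_2d(moved, mid_section)
        resid = compose(true, est)
        pts = np.stack(
            np.meshgrid(np.arange(20, 80, 15) * px, np.arange(20, 80, 15) * px), -1
        ).reshape(-1, 2)
        err = np.abs(map_points(resid, pts) - pts).max() / px
        assert err < 0.5

    def test_rotation_plus_translation_recovery(self, mid_section):
        from histostack.transforms import RigidTransform2D

        px = 120.0
        true = RigidTransform2D(
            theta=8.0, tx=12 * px, ty=-7 * px, center=mid_section.phys_center()
        )
        moved = resample(mid_section, true, interpolation="cubic")
        moved = moved.with_pixels(moved.pixels, mask=background_mask(moved))
        est, trace = register_rigid_2d(moved, mid_section)
        resid = compose(true, est)
        assert abs(resid.theta) < 0.5
        pts = np.stack(
            np.meshgrid(np.arange(20, 80, 15) * px, np.arange(20, 80, 15) * px), -1
        ).reshape(-1, 2)
        assert np.abs(map_points(resid, pts) - pts).max() / px < 1.0
        assert len(trace) <= 4

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            PassSchedule(passes=(), max_passes=4)
        with pytest.raises(ValueError):
            PassSchedule(passes=(RigidPass(),), max_passes=0)


class TestAffine3D:
    @pytest.fixture(scope="class")
    def volume(self):
        spec = PhantomSpec(
            grid_dims=(48, 64, 64),
            voxel_size=(300.0, 300.0, 300.0),
            n_blobs=10,
            seed=6,
        )
        vol, _, _ = make_phantom(spec)
        return vol

    def test_identity_recovery(self, volume):
        t = register_affine_3d(volume, volume)
        assert np.allclose(t.linear, np.eye(3), atol=5e-3)
        assert np.abs(t.offset).max() < 0.5 * 300

    def test_anisotropic_scale_recovery(self, volume):
        true = AffineTransform3D.from_params(
            scale=(1, 1, 1.1), center=volume.phys_center()
        )
        moved = resample_volume(volume, true)
        est = register_affine_3d(volume, moved)
        assert est.linear[2, 2] == pytest.approx(1.1, abs=0.011)

    def test_translation_recovery_within_one_voxel(self, volume):
        true = AffineTransform3D(offset=np.array([400.0, -200.0, 600.0]))
        moved = resample_volume(volume, true)
        est = register_affine_3d(volume, moved)
        assert np.abs(est.offset - true.offset).max() < 300.0

    def test_constant_volume_rejected(self, volume):
        const = volume.with_data(np.zeros_like(np.asarray(volume.data)))
        with pytest.raises(ValueError):
            register_affine_3d(const, volume)


class TestNonlinear2D:
    def test_identity_pair_yields_zero_field_not_accepted(self, mid_section):
        fld, accepted = register_nonlinear_2d(
            mid_section, mid_section, control_spacing=1000.0
        )
        assert not accepted
        assert fld.rms() < 0.2 * 120

    def test_sinusoidal_warp_recovered_and_accepted(self, mid_section):
        px = 120.0
        h, w = mid_section.shape
        yy, xx = np.mgrid[0:h, 0:w]
        ux = 3 * px * np.sin(2 * np.pi * xx / 64) * np.cos(2 * np.pi * yy / 64)
        uy = 3 * px * np.cos(2 * np.pi * xx / 64) * np.sin(2 * np.pi * yy / 64)
        true_f = DeformationField2D(
            np.stack([ux, uy]), pixel_size=mid_section.pixel_size
        )
        warped = resample(mid_section, true_f, interpolation="cubic")
        fld, accepted = register_nonlinear_2d(
            warped, mid_section, control_spacing=8 * px
        )
        assert accepted
        m = mid_section.mask
        idx = np.argwhere(m)[::7]
        pts = np.stack([idx[:, 1] * px, idx[:, 0] * px], axis=1)
        resid = map_points(compose(true_f, fld), pts) - pts
        assert np.sqrt((resid**2).sum(1).mean()) / px < 1.0

    def test_background_mismatch_rejected_with_zero_field(self, mid_section, rng):
        bad = np.asarray(mid_section.pixels, float).copy()
        bad[~mid_section.mask] = rng.uniform(0, 200, (~mid_section.mask).sum())
        sbad = Section2D(
            bad, pixel_size=mid_section.pixel_size, mask=mid_section.mask
        )
        fld, accepted = register_nonlinear_2d(
            sbad, mid_section, control_spacing=1000.0
        )
        assert not accepted
        assert fld.is_identity()

    def test_under_regularized_spacing_rejected(self, mid_section):
        with pytest.raises(ValueError):
            register_nonlinear_2d(mid_section, mid_section, control_spacing=120.0)

    def test_no_folding_under_default_regularization(self, mid_section):
        px = 120.0
        h, w = mid_section.shape
        yy, xx = np.mgrid[0:h, 0:w]
        ux = 3 * px * np.sin(2 * np.pi * xx / 64)
        uy = np.zeros_like(ux)
        warped = resample(
            mid_section,
            DeformationField2D(np.stack([ux, uy]), pixel_size=mid_section.pixel_size),
            interpolation="cubic",
        )
        fld, _ = register_nonlinear_2d(warped, mid_section, control_spacing=8 * px)
        gy = np.abs(np.gradient(fld.displacement[1] / px, axis=0)).max()
        gx = np.abs(np.gradient(fld.displacement[0] / px, axis=1)).max()
        assert max(gy, gx) < 1.0
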