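"""Stacking, slice correspondence, the guided refinement loop, and
full-resolution / template projection."""

import numpy as np
import pytest

from histostack.core import Section2D, SectionSeries, Volume3D
from histostack.metrics import ncc
from histostack.phantom import (
    CorruptionSpec,
    PhantomSpec,
    corrupt_sections,
    histology_contrast,
    make_phantom,
    mr_acquisition,
    virtual_section,
)
from histostack.preprocess import background_mask, threshold_mask
from histostack.reconstruct import (
    match_slices,
    project_to_template,
    refine,
    stack,
    stack_with_transforms,
)
from histostack.transforms import (
    AffineTransform3D,
    RigidTransform2D,
    compose,
    invert,
    map_points,
)


class TestStack:
    def test_identity_pairwise_equals_naive_stacking(self, tissue_sections):
        n = len(tissue_sections)
        pairwise = [RigidTransform2D() for _ in range(n - 1)]
        vol, absolute = stack(tissue_sections, pairwise)
        naive = np.stack([np.asarray(s.pixels, float) for s in tissue_sections])
        assert np.allclose(vol.data, naive)
        assert absolute[tissue_sections.anchor].is_identity(1e-9)

    def test_ground_truth_pairwise_restores_slab(self, tissue_sections):
        cspec = CorruptionSpec(
            max_rotation=5, max_translation=600, noise_sd=0, seed=8
        )
        corr, truth = corrupt_sections(tissue_sections, cspec)
        # exact pairwise transform i -> i+1: R_{i+1}^-1 ∘ R_i
        pairwise = [
            compose(
                invert(truth.per_section_rigid[i + 1]), truth.per_section_rigid[i]
            )
            for i in range(len(corr) - 1)
        ]
        # absolute chains must additionally undo the anchor's own offset
        vol, absolute = stack(corr, pairwise)
        a = tissue_sections.anchor
        clean = np.stack([np.asarray(s.pixels, float) for s in tissue_sections])
        # compare against the clean slab moved by the anchor perturbation
        anchor_chain = truth.per_section_rigid[a]
        ref = stack_with_transforms(
            tissue_sections, [anchor_chain] * len(corr)
        )[0]
        for k in range(2, len(corr) - 2):
            sl = np.asarray(vol.data[k])
            rf = np.asarray(ref.data[k])
            m = (sl > 1) & (rf > 1)
            assert ncc(sl[m], rf[m]) > 0.99

    def test_mismatched_count_rejected(self, tissue_sections):
        with pytest.raises(ValueError):
            stack(tissue_sections, [RigidTransform2D()])


class TestMatchSlices:
    def test_self_reference_pairs_identically(self, tissue_sections):
        vol, _ = stack_with_transforms(
            tissue_sections, [None] * len(tissue_sections)
        )
        pairs = match_slices(vol, tissue_sections, AffineTransform3D())
        for i, plane in pairs:
            if plane is None:
                continue
            a = np.asarray(tissue_sections[i].pixels, float)
            b = np.asarray(plane.pixels, float)
            assert ncc(a.ravel(), b.ravel()) > 0.999

    def test_z_offset_interpolates_between_planes(self, tissue_sections):
        vol, _ = stack_with_transforms(
            tissue_sections, [None] * len(tissue_sections)
        )
        # shift the volume by half a slice in z: each section should pair
        # with the average of two neighbouring planes
        t = AffineTransform3D(offset=np.array([0.0, 0.0, 100.0]))
        pairs = match_slices(vol, tissue_sections, t)
        i = len(tissue_sections) // 2
        plane = dict(pairs)[i]
        expected = 0.5 * (
            np.asarray(vol.data[i], float) + np.asarray(vol.data[i + 1], float)
        )
        got = np.asarray(plane.pixels, float)
        m = expected > 1
        assert ncc(got[m], expected[m]) > 0.999


@pytest.fixture(scope="module")
def guided_setup():
    spec = PhantomSpec(
        grid_dims=(44, 96, 96),
        voxel_size=(200.0, 120.0, 120.0),
        n_blobs=12,
        specimen_fraction=0.6,
        specimen_bend=300.0,
        seed=13,
    )
    vol, lab, _ = make_phantom(spec)
    hvol = histology_contrast(vol, lab)
    mr = mr_acquisition(vol)
    mask = threshold_mask(mr, method=90.0)
    mr_m = mr.with_data(np.asarray(mr.data) * (np.asarray(mask.data) > 0))
    series, _ = virtual_section(hvol, thickness=200.0, keep_every=1)
    keep = [
        i for i in range(len(series)) if np.isin(lab.data[i], [2, 3]).mean() > 0.1
    ]
    sub = SectionSeries([series[i] for i in keep], spacing=200.0)
    return vol, lab, hvol, mr_m, sub, keep


class TestRefine:
    def test_already_aligned_terminates_quickly_without_updates(self, guided_setup):
        _, _, _, mr_m, sub, _ = guided_setup
        aligned = sub.map(
            lambda s: s.with_pixels(s.pixels, mask=background_mask(s))
        )
        res = refine(aligned, mr_m, max_iter=4, tol=1e-3, nonlinear=False)
        assert res.iterations <= 3
        for rigid, _, _ in res.per_section:
            assert abs(rigid.theta) < 0.3

    def test_corrupted_phantom_recovers_geometry(self, guided_setup):
        vol, lab, hvol, mr_m, sub, keep = guided_setup
        cspec = CorruptionSpec(
            max_rotation=6,
            max_translation=900,
            deform_amplitude=200,
            deform_wavelength=5000,
            noise_sd=3,
            seed=14,
        )
        corr, _ = corrupt_sections(sub, cspec)
        corr = corr.map(lambda s: s.with_pixels(s.pixels, mask=background_mask(s)))
        res = refine(corr, mr_m, max_iter=5, tol=1e-3, nonlinear=True)
        # accepted-iteration NMI trace is non-decreasing and bounded
        assert all(
            b >= a - 1e-12 for a, b in zip(res.nmi_trace, res.nmi_trace[1:])
        )
        assert res.iterations <= 5
        m = np.zeros(vol.shape, dtype=bool)
        m[keep[0] : keep[-1] + 1] = True
        m &= np.asarray(res.volume_in_mr.data) > 0
        assert ncc(res.volume_in_mr.data[m], hvol.data[m]) > 0.95


class TestProjectToTemplate:
    def test_identity_transform_resamples_to_grid(self, tissue_sections):
        vol, _ = stack_with_transforms(
            tissue_sections, [None] * len(tissue_sections)
        )
        out = project_to_template(vol, [AffineTransform3D()], vol)
        assert np.abs(out.data - np.asarray(vol.data, float)).max() < 1e-9

    def test_affine_round_trip(self, tissue_sections):
        from histostack.phantom import mr_acquisition

        vol, _ = stack_with_transforms(
            tissue_sections, [None] * len(tissue_sections)
        )
        # band-limited content: the round trip measures the mapping, not
        # how much fine texture two linear interpolations smooth away
        vol = mr_acquisition(vol, psf_um=(200.0, 150.0, 150.0))
        t = AffineTransform3D.from_params(
            translation=(300, -200, 200),
            rotation_deg=(0, 0, 4),
            center=vol.phys_center(),
        )
        fwd = project_to_template(vol, [t], vol)
        back = project_to_template(fwd, [invert(t)], vol)
        m = (np.asarray(vol.data) > 1) & (np.asarray(back.data) > 1)
        # clip the outermost slices, which partially leave the grid
        m[:2] = m[-2:] = False
        assert ncc(back.data[m], vol.data[m]) > 0.98

    def test_landmark_chain_composition_order(self):
        a = AffineTransform3D.from_params(translation=(100, 0, 0))
        b = AffineTransform3D.from_params(rotation_deg=(0, 0, 10))
        pts = np.random.default_rng(0).uniform(-500, 500, (10, 3))
        from histostack.transforms import TransformChain

        chain = TransformChain([a, b])
        expect = map_points(a, map_points(b, pts))
        assert np.allclose(map_points(chain, pts), expect)

    def test_missing_grid_metadata_rejected(self, tissue_sections):
        vol, _ = stack_with_transforms(
            tissue_sections, [None] * len(tissue_sections)
        )
        with pytest.raises(ValueError):
            project_to_template(vol, [AffineTransform3D()], "not-a-grid")
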