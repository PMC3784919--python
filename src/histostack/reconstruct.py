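"""Pipeline orchestration: stacking registered sections into a volume,
MR reslicing and slice correspondence, the iterative MRI-guided
refinement loop, full-resolution application, and projection into a
template space.

The guiding idea: pairwise inter-section registration alone lets small
errors accumulate along the stack (the "banana effect" that bends a
straight structure into a curve); registering the evolving stack to a
3D MR reference and re-refining every section against its MR plane
anchors each section to an absolute geometry, so errors stay
independent instead of accumulating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Section2D, SectionSeries, Volume3D
from .metrics import nmi
from .register import (
    PassSchedule,
    RigidPass,
    default_schedule,
    register_affine_3d,
    register_nonlinear_2d,
    register_rigid_2d,
)
from .transforms import (
    AffineTransform3D,
    DeformationField2D,
    RigidTransform2D,
    TransformChain,
    compose,
    invert,
    resample,
    resample_volume,
)

__all__ = [
    "ReconstructionResult",
    "apply_fullres",
    "match_slices",
    "project_to_template",
    "refine",
    "stack",
]


@dataclass
class ReconstructionResult:
    """Outcome of the guided reconstruction.

    ``per_section[i]`` is ``(rigid, field_or_None, gate_accepted)``; the
    full pull-back chain for section ``i`` is ``rigid`` composed with the
    field when one was accepted.  ``nmi_trace`` holds the volume NMI of
    each accepted iteration (non-decreasing).  ``affine_only`` is set
    when a majority of non-linear gates rejected, mirroring the fallback
    to the affine-only transform chain.
    """

    volume: Volume3D
    per_section: list
    affine_mr_to_stack: Optional[AffineTransform3D]
    nmi_trace: list
    iterations: int
    affine_only: bool = False
    volume_in_mr: Optional[Volume3D] = None

    def map_to_mr(
        self, volume: Volume3D, mr_grid: Volume3D, interpolation: str = "linear"
    ) -> Volume3D:
        """Map a stack-space volume into MR space through the inverse of
        the final affine — the step that places the reconstruction in the
        reference geometry (a global affine fitted to a drifted stack
        absorbs part of the drift; undoing it restores the MR frame).
        """
        if self.affine_mr_to_stack is None:
            raise ValueError("no affine available")
        return resample_volume(
            volume,
            invert(self.affine_mr_to_stack),
            target_grid=mr_grid,
            interpolation=interpolation,
        )

    def section_transform(self, i: int):
        rigid, fld, accepted = self.per_section[i]
        if fld is not None and accepted and not self.affine_only:
            return compose(rigid, fld)
        return rigid


def stack(
    series: SectionSeries,
    pairwise: Sequence[RigidTransform2D],
    target: Optional[Section2D] = None,
) -> tuple[Volume3D, list]:
    """Stack sections into an initial 3D volume using pairwise rigid
    transforms.

    ``pairwise[i]`` must map section-``i`` coordinates into
    section-``i+1`` coordinates (the pull-back transform returned by
    registering section ``i+1`` onto section ``i``).  Absolute
    transforms are composed outward from the anchor (identity there) and
    every section is resampled exactly once onto a common in-plane grid
    (the anchor's, unless ``target`` is given).  z = index × spacing.
    """
    n = len(series)
    if len(pairwise) != n - 1:
        raise ValueError("need exactly len(sections) - 1 pairwise transforms")
    a = series.anchor
    absolute: list = [None] * n
    absolute[a] = RigidTransform2D(center=series[a].phys_center())
    for j in range(a + 1, n):
        absolute[j] = compose(pairwise[j - 1], absolute[j - 1])
    for j in range(a - 1, -1, -1):
        absolute[j] = compose(invert(pairwise[j]), absolute[j + 1])
    vol, _ = stack_with_transforms(series, absolute, target=target)
    return vol, absolute


def stack_with_transforms(
    series: SectionSeries,
    transforms: Sequence,
    target: Optional[Section2D] = None,
) -> tuple[Volume3D, Section2D]:
    """Resample every section with its (arbitrary) transform onto a
    common grid and stack along z."""
    tgt = target if target is not None else series[series.anchor]
    planes = []
    identity = RigidTransform2D(center=tgt.phys_center())
    for s, t in zip(series, transforms):
        t = t if t is not None else identity
        if isinstance(t, RigidTransform2D) and t.is_identity() and s.shape == tgt.shape:
            planes.append(np.asarray(s.pixels, dtype=float))
        else:
            planes.append(
                np.asarray(resample(s, t, target_grid=tgt).pixels, dtype=float)
            )
    sy, sx = tgt.pixel_size
    vol = Volume3D(
        data=np.stack(planes),
        voxel_size=(series.spacing, sy, sx),
        origin=(series[0].z, tgt.origin[1], tgt.origin[0]),
    )
    return vol, tgt


def match_slices(
    mri: Volume3D,
    series: SectionSeries,
    affine: AffineTransform3D,
    target: Optional[Section2D] = None,
) -> list[tuple[int, Optional[Section2D]]]:
    """Reslice the MR volume in stack space and pair each section with
    the MR plane at its z position (linear interpolation through the MR
    grid).  Sections whose z falls outside the resampled MR extent are
    flagged with ``None`` rather than failing.
    """
    tgt = target if target is not None else series[series.anchor]
    sy, sx = tgt.pixel_size
    grid = Volume3D(
        data=np.zeros((len(series),) + tgt.shape),
        voxel_size=(series.spacing, sy, sx),
        origin=(series[0].z, tgt.origin[1], tgt.origin[0]),
    )
    res = resample_volume(mri, affine, target_grid=grid, interpolation="linear")
    pairs: list[tuple[int, Optional[Section2D]]] = []
    for i, s in enumerate(series):
        plane = res.plane(i)
        if not np.any(np.asarray(plane.pixels)):
            pairs.append((i, None))
        else:
            pix = np.asarray(plane.pixels)
            plane = Section2D(
                pixels=pix,
                pixel_size=plane.pixel_size,
                index=s.index,
                z=s.z,
                origin=plane.origin,
                # masked MR volumes are zero outside the brain; restrict
                # similarity to the resliced foreground
                mask=pix > 0,
            )
            pairs.append((i, plane))
    return pairs


#: short schedule for the per-iteration guided rigid re-refinement:
#: sections are already near their MR plane, only local polish is needed
GUIDED_PASS = PassSchedule(
    passes=(RigidPass(shrinks=(2, 1), bins=64, theta_step=1.0, trans_step=2.0),),
    max_passes=2,
)


def refine(
    series: SectionSeries,
    mri: Volume3D,
    max_iter: int = 10,
    tol: float = 1e-3,
    schedule: Optional[PassSchedule] = None,
    initial_transforms: Optional[Sequence[RigidTransform2D]] = None,
    nonlinear: bool = True,
    control_spacing: Optional[float] = None,
    gate_margin: float = 0.0,
    majority_threshold: float = 0.5,
    nonlinear_iter: int = 40,
) -> ReconstructionResult:
    """Iterative MRI-guided refinement of a preprocessed section series.

    Each iteration: (a) affine-register the MR volume to the current
    stack, (b) reslice and pair MR planes with sections, (c) re-refine
    every section rigidly against its MR plane and optionally apply the
    gated non-linear step, (d) restack, (e) measure volume NMI between
    the stack and the resliced MR.  The loop stops when the NMI gain
    drops below ``tol``, an iteration fails to improve, or ``max_iter``
    is reached; the trace keeps accepted iterations only, so it is
    non-decreasing.  If the non-linear gate rejects for a majority of
    sections the result is flagged ``affine_only`` and the deformation
    fields are dropped.

    ``series`` should already be grayscale, masked and
    histogram-matched; ``mri`` bias-corrected and masked.  Without
    ``initial_transforms``, pairwise rigid registration and stacking
    provide the initial guess.
    """
    n = len(series)
    sched = schedule or default_schedule()
    if initial_transforms is None:
        pairwise = []
        for i in range(n - 1):
            t, _ = register_rigid_2d(series[i + 1], series[i], schedule=sched)
            pairwise.append(t)
        _, absolute = stack(series, pairwise)
        rigids = list(absolute)
    else:
        if len(initial_transforms) != n:
            raise ValueError("initial_transforms length mismatch")
        rigids = list(initial_transforms)
    fields: list[Optional[DeformationField2D]] = [None] * n
    gates: list[bool] = [False] * n
    tgt = series[series.anchor]
    if control_spacing is None:
        control_spacing = 12.0 * float(np.mean(tgt.pixel_size))

    def build(rs, fs, gs):
        chains = []
        for r, f, g in zip(rs, fs, gs):
            chains.append(compose(r, f) if (f is not None and g) else r)
        vol, _ = stack_with_transforms(series, chains, target=tgt)
        return vol

    vol = build(rigids, fields, gates)
    affine = None
    mr_stack = None
    nmi_trace: list[float] = []
    best = -np.inf
    iterations = 0
    for it in range(max_iter):
        affine_new = register_affine_3d(mri, vol)
        pairs = match_slices(mri, series, affine_new, target=tgt)
        if all(p is None for _, p in pairs):
            raise ValueError("degenerate MR/stack overlap: no usable MR planes")
        new_rigids = list(rigids)
        new_fields = list(fields)
        new_gates = [False] * n
        for i, plane in pairs:
            if plane is None:
                continue
            # first iteration: wide multi-pass search (initial drift and
            # twist can be large); later iterations: local polish
            sched_i = sched if it == 0 else GUIDED_PASS
            r, _ = register_rigid_2d(
                series[i], plane, schedule=sched_i, init=rigids[i]
            )
            new_rigids[i] = r
            if nonlinear:
                moving = resample(series[i], r, target_grid=tgt)
                fld, ok = register_nonlinear_2d(
                    moving,
                    plane,
                    control_spacing=control_spacing,
                    gate_margin=gate_margin,
                    n_iter=nonlinear_iter,
                )
                new_fields[i] = fld if ok else None
                new_gates[i] = ok
        vol_new = build(new_rigids, new_fields, new_gates)
        mr_grid = Volume3D(
            data=np.zeros_like(vol_new.data),
            voxel_size=vol_new.voxel_size,
            origin=vol_new.origin,
        )
        mr_stack_new = resample_volume(mri, affine_new, target_grid=mr_grid)
        score = nmi(vol_new.data, mr_stack_new.data)
        iterations = it + 1
        if not np.isfinite(best):
            # baseline: the pre-refinement stack against the same reslice
            best = nmi(vol.data, mr_stack_new.data)
        if score > best + 1e-12:
            gain = score - best
            rigids, fields, gates = new_rigids, new_fields, new_gates
            vol, affine, mr_stack = vol_new, affine_new, mr_stack_new
            nmi_trace.append(score)
            if np.isfinite(best) and gain < tol:
                break
            best = score
        else:
            if affine is None:
                affine = affine_new
            break
    n_rejected = sum(1 for g in gates if not g)
    affine_only = nonlinear and (n_rejected / n > majority_threshold)
    if affine_only:
        vol = build(rigids, [None] * n, [False] * n)
    per_section = [
        (r, f if (f is not None and g and not affine_only) else None,
         g and not affine_only)
        for r, f, g in zip(rigids, fields, gates)
    ]
    result = ReconstructionResult(
        volume=vol,
        per_section=per_section,
        affine_mr_to_stack=affine,
        nmi_trace=nmi_trace,
        iterations=iterations,
        affine_only=affine_only,
    )
    if affine is not None:
        result.volume_in_mr = result.map_to_mr(vol, mri)
    return result


def apply_fullres(
    result: ReconstructionResult, fullres: SectionSeries
) -> Volume3D:
    """Apply the estimated per-section transform chains to the original
    full-resolution sections in a single interpolation per section.

    Transforms are physical-unit maps, so they carry across resolutions
    unchanged; the output in-plane grid is the full-resolution anchor
    grid.  Physical extents must agree with the working series within 1%.
    """
    if len(fullres) != len(result.per_section):
        raise ValueError("full-resolution series length mismatch")
    work_vol = result.volume
    wext = (
        work_vol.shape[1] * work_vol.voxel_size[1],
        work_vol.shape[2] * work_vol.voxel_size[2],
    )
    s0 = fullres[0]
    fext = (s0.shape[0] * s0.pixel_size[0], s0.shape[1] * s0.pixel_size[1])
    for we, fe in zip(wext, fext):
        if abs(we - fe) / we > 0.01:
            raise ValueError(
                f"physical extent mismatch >1%: working {wext} vs full-res {fext}"
            )
    chains = [result.section_transform(i) for i in range(len(fullres))]
    vol, _ = stack_with_transforms(fullres, chains)
    return vol


def project_to_template(
    volume: Volume3D,
    transforms: Sequence,
    template_grid: Volume3D,
) -> Volume3D:
    """Project a reconstructed histology volume onto a template grid.

    ``transforms`` is the pull-back chain mapping template coordinates
    back into histology coordinates — typically
    ``[hist_from_mr, mr_from_template]`` where ``mr_from_template`` is
    the inverse of an externally estimated MR→template normalization.
    The whole chain is flattened and applied in one interpolation.
    """
    if not isinstance(template_grid, Volume3D):
        raise ValueError("template_grid must be a Volume3D with physical metadata")
    chain = TransformChain(list(transforms)) if len(transforms) != 1 else transforms[0]
    return resample_volume(volume, chain, target_grid=template_grid)
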