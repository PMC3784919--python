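"""Registration engines: multi-pass rigid 2D, affine 3D, and gated
non-linear 2D, all driven by normalized mutual information.

Design notes
------------
* The optimizer for rigid/affine parameters is Powell's derivative-free
  method over physically scaled parameters, inside a coarse-to-fine
  block-mean pyramid.  NMI is non-smooth; a derivative-free local search
  with a good pyramid initialization is robust and portable.
* Rigid passes follow a multi-pass schedule: each pass re-optimizes from
  the current estimate with its own pyramid/bin settings and is accepted
  only if it improves NMI at working resolution — once the trace
  plateaus the remaining passes are skipped.  Accepted transforms are
  composed symbolically; images are interpolated once at the end.
* The non-linear stage is a free-form deformation on a control-point
  lattice: control displacements are estimated by local block matching
  (integer NCC search with sub-pixel quadratic refinement), regularized
  by Gaussian smoothing of the lattice, and interpolated to the pixel
  grid with a cubic B-spline.  The result is accepted only when it
  improves NMI by a configurable margin; otherwise a zero field is
  returned — the affine-only fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize
from scipy.interpolate import RectBivariateSpline

from .core import Section2D, Volume3D
from .metrics import nmi
from .preprocess import downsample
from .transforms import (
    AffineTransform3D,
    DeformationField2D,
    RigidTransform2D,
    compose,
    resample,
    resample_volume,
)

__all__ = [
    "PassSchedule",
    "default_schedule",
    "register_affine_3d",
    "register_nonlinear_2d",
    "register_rigid_2d",
]


@dataclass(frozen=True)
class RigidPass:
    """One pass of the multi-pass rigid strategy."""

    shrinks: tuple[int, ...] = (4, 2, 1)
    bins: int = 64
    theta_step: float = 2.0  # degrees, initial Powell step
    trans_step: float = 4.0  # pixels at each level, initial Powell step
    xtol: float = 0.02


@dataclass(frozen=True)
class PassSchedule:
    passes: tuple[RigidPass, ...]
    max_passes: int = 4

    def __post_init__(self):
        if self.max_passes < 1:
            raise ValueError("max_passes must be >= 1")
        if not self.passes:
            raise ValueError("schedule needs at least one pass")


def default_schedule(max_passes: int = 4) -> PassSchedule:
    """Coarse wide search, medium refinement, fine local polish."""
    return PassSchedule(
        passes=(
            RigidPass(shrinks=(4, 2), bins=32, theta_step=4.0, trans_step=6.0),
            RigidPass(shrinks=(2, 1), bins=64, theta_step=1.0, trans_step=2.0),
            RigidPass(shrinks=(1,), bins=64, theta_step=0.25, trans_step=0.5, xtol=0.005),
        ),
        max_passes=max_passes,
    )


# ---------------------------------------------------------------------------
# rigid 2D
# ---------------------------------------------------------------------------


def _pyramid(section: Section2D, shrinks: Sequence[int]) -> dict[int, Section2D]:
    out = {}
    for s in sorted(set(shrinks)):
        out[s] = section if s == 1 else downsample(section, s)
    return out


class _RigidCost:
    """-NMI of (fixed, moving∘T) on one pyramid level; one interpolation
    per evaluation, evaluated over the fixed image (mask optional)."""

    def __init__(self, moving: Section2D, fixed: Section2D, bins: int, center):
        self.moving = np.asarray(moving.pixels, dtype=float)
        self.m_meta = moving
        self.fixed = np.asarray(fixed.pixels, dtype=float)
        n_eff = int(fixed.mask.sum()) if fixed.mask is not None else self.fixed.size
        # a joint histogram needs several samples per occupied bin; cap
        # the bin count by ~sqrt(N) so small/coarse levels stay smooth
        self.bins = min(bins, max(16, int(np.sqrt(max(n_eff, 1)))))
        self.center = center
        X, Y = fixed.phys_grid()
        self.pts = np.stack([X.ravel(), Y.ravel()], axis=1)
        self.shape = fixed.shape
        self.mask = fixed.mask
        sy, sx = fixed.pixel_size
        self.px = (sx + sy) / 2.0

    def warped(self, params) -> np.ndarray:
        theta, tx_px, ty_px = params
        t = RigidTransform2D(
            theta=theta, tx=tx_px * self.px, ty=ty_px * self.px, center=self.center
        )
        src = t(self.pts)
        coords = self.m_meta.phys_to_index(src)
        return ndimage.map_coordinates(
            self.moving, coords, order=1, mode="constant", cval=0.0
        ).reshape(self.shape)

    def _soft_nmi(self, a: np.ndarray, b: np.ndarray) -> float:
        """NMI from a partial-volume (bilinearly soft-binned) joint
        histogram: each sample spreads over the four neighbouring bins,
        which makes the cost smooth at sub-pixel displacements."""
        if self.mask is not None:
            a = a[self.mask]
            b = b[self.mask]
        else:
            a = a.ravel()
            b = b.ravel()
        nb = self.bins
        ra = a.max() - a.min()
        rb = b.max() - b.min()
        if ra == 0 or rb == 0:
            return 1.0
        fa = np.clip((a - a.min()) / ra * (nb - 1), 0, nb - 1 - 1e-9)
        fb = np.clip((b - b.min()) / rb * (nb - 1), 0, nb - 1 - 1e-9)
        ia = fa.astype(np.intp)
        ib = fb.astype(np.intp)
        wa = fa - ia
        wb = fb - ib
        counts = np.zeros(nb * nb)
        for da, ww_a in ((0, 1 - wa), (1, wa)):
            for db, ww_b in ((0, 1 - wb), (1, wb)):
                idx = (ia + da) * nb + (ib + db)
                counts += np.bincount(idx, weights=ww_a * ww_b, minlength=nb * nb)
        p = counts / counts.sum()
        pa = p.reshape(nb, nb).sum(axis=1)
        pb = p.reshape(nb, nb).sum(axis=0)

        def H(q):
            q = q[q > 0]
            return float(-(q * np.log2(q)).sum())

        hab = H(p)
        if hab == 0:
            return 1.0
        return (H(pa) + H(pb)) / hab

    def __call__(self, params) -> float:
        w = self.warped(params)
        return -self._soft_nmi(self.fixed, w)


def register_rigid_2d(
    moving: Section2D,
    fixed: Section2D,
    schedule: Optional[PassSchedule] = None,
    init: Optional[RigidTransform2D] = None,
) -> tuple[RigidTransform2D, list[dict]]:
    """Multi-pass rigid registration of ``moving`` onto ``fixed``.

    Returns a transform ``T`` such that ``resample(moving, T)`` aligns
    with ``fixed`` (``T`` maps fixed coordinates into moving
    coordinates), plus a per-pass trace of NMI at working resolution.
    Initialization aligns foreground centroids unless ``init`` is given.
    A pass is accepted only if it improves NMI; the loop stops at the
    first rejected pass or at ``max_passes``.
    """
    schedule = schedule or default_schedule()
    center = fixed.foreground_centroid()
    if init is None:
        mc = moving.foreground_centroid()
        fc = fixed.foreground_centroid()
        current = RigidTransform2D(
            theta=0.0, tx=mc[0] - fc[0], ty=mc[1] - fc[1], center=center
        )
    else:
        current = RigidTransform2D(
            theta=init.theta, tx=init.tx, ty=init.ty, center=init.center
        )

    eval_cost = _RigidCost(moving, fixed, bins=64, center=center)

    def nmi_of(t: RigidTransform2D) -> float:
        sy, sx = fixed.pixel_size
        px = (sx + sy) / 2.0
        # re-express about the evaluation center
        tt = RigidTransform2D.from_matrix(t.matrix, center=center)
        return -eval_cost((tt.theta, tt.tx / px, tt.ty / px))

    trace: list[dict] = []
    best_nmi = nmi_of(current)
    n_rejected_run = 0
    for n_pass in range(schedule.max_passes):
        p = schedule.passes[min(n_pass, len(schedule.passes) - 1)]
        candidate = current
        for shrink in p.shrinks:
            # keep every level at least ~32 px: coarser pyramids on small
            # inputs destroy the similarity signal entirely
            max_shrink = max(1, min(fixed.shape) // 32)
            shrink = min(shrink, max_shrink)
            f_lv = fixed if shrink == 1 else downsample(fixed, shrink)
            m_lv = moving if shrink == 1 else downsample(moving, shrink)
            cost = _RigidCost(m_lv, f_lv, bins=p.bins, center=center)
            cand = RigidTransform2D.from_matrix(candidate.matrix, center=center)
            x0 = np.array([cand.theta, cand.tx / cost.px, cand.ty / cost.px])
            if n_pass == 0 and shrink == max(p.shrinks):
                # wide search: sweep rotation at the coarsest level first
                sweep = x0[0] + np.arange(-18.0, 18.1, 3.0)
                vals = [cost((th, x0[1], x0[2])) for th in sweep]
                x0[0] = sweep[int(np.argmin(vals))]
            direc = np.diag([p.theta_step, p.trans_step, p.trans_step])
            res = optimize.minimize(
                cost,
                x0,
                method="Powell",
                options=dict(direc=direc, xtol=p.xtol, ftol=1e-6, maxiter=30),
            )
            candidate = RigidTransform2D(
                theta=float(res.x[0]),
                tx=float(res.x[1]) * cost.px,
                ty=float(res.x[2]) * cost.px,
                center=center,
            )
        cand_nmi = nmi_of(candidate)
        accepted = cand_nmi > best_nmi + 1e-9
        trace.append(
            dict(pass_index=n_pass, nmi=cand_nmi if accepted else best_nmi,
                 accepted=accepted)
        )
        if accepted:
            current, best_nmi = candidate, cand_nmi
            n_rejected_run = 0
        else:
            n_rejected_run += 1
            # plateau: a second consecutive non-improving pass ends the search
            if n_rejected_run >= 2:
                break
    return current, trace


# ---------------------------------------------------------------------------
# affine 3D
# ---------------------------------------------------------------------------


def _shrink_volume(vol: Volume3D, factor: int) -> Volume3D:
    if factor == 1:
        return vol
    nz, ny, nx = vol.shape
    f = factor
    zz, yy, xx = (nz // f) * f, (ny // f) * f, (nx // f) * f
    d = np.asarray(vol.data[:zz, :yy, :xx], dtype=float)
    d = d.reshape(zz // f, f, yy // f, f, xx // f, f).mean(axis=(1, 3, 5))
    sz, sy, sx = vol.voxel_size
    oz, oy, ox = vol.origin
    off = (f - 1) / 2
    return Volume3D(
        data=d,
        voxel_size=(sz * f, sy * f, sx * f),
        origin=(oz + off * sz, oy + off * sy, ox + off * sx),
    )


class _AffineCost:
    def __init__(self, moving: Volume3D, fixed: Volume3D, bins: int, center):
        self.moving = moving
        self.fixed = np.asarray(fixed.data, dtype=float)
        self.bins = bins
        self.center = center
        nz, ny, nx = fixed.shape
        sz, sy, sx = fixed.voxel_size
        oz, oy, ox = fixed.origin
        zzi, yyi, xxi = np.meshgrid(
            oz + np.arange(nz) * sz,
            oy + np.arange(ny) * sy,
            ox + np.arange(nx) * sx,
            indexing="ij",
        )
        self.pts = np.stack([xxi.ravel(), yyi.ravel(), zzi.ravel()], axis=1)
        self.shape = fixed.shape
        self.vox = np.mean(fixed.voxel_size)

    def transform_of(self, x) -> AffineTransform3D:
        return AffineTransform3D.from_params(
            translation=np.asarray(x[:3]) * self.vox,
            rotation_deg=x[3:6],
            scale=1.0 + np.asarray(x[6:9]),
            shear=np.asarray(x[9:12]),
            center=self.center,
        )

    #: plausibility bounds on relative scale and shear — tissue shrinkage
    #: between modalities is bounded, and unbounded scale lets the
    #: optimizer map the wrong boundary (e.g. a fluid shell) onto tissue
    SCALE_BOUND = 0.2
    SHEAR_BOUND = 0.15

    def __call__(self, x) -> float:
        penalty = 0.0
        for v in x[6:9]:
            over = abs(v) - self.SCALE_BOUND
            if over > 0:
                penalty += 100.0 * over**2
        for v in x[9:12]:
            over = abs(v) - self.SHEAR_BOUND
            if over > 0:
                penalty += 100.0 * over**2
        t = self.transform_of(x)
        src = t(self.pts)
        coords = self.moving.phys_to_index(src)
        w = ndimage.map_coordinates(
            np.asarray(self.moving.data, dtype=float),
            coords,
            order=1,
            mode="constant",
            cval=0.0,
        ).reshape(self.shape)
        try:
            return -nmi(self.fixed, w, bins=self.bins) + penalty
        except ValueError:
            return penalty


def register_affine_3d(
    moving: Volume3D,
    fixed: Volume3D,
    shrinks: Sequence[int] = (4, 2),
    bins: int = 48,
    init_params: Optional[np.ndarray] = None,
) -> AffineTransform3D:
    """12-parameter affine registration of ``moving`` onto ``fixed`` by
    NMI, coarse to fine.

    Returns the physical-space transform ``T`` (fixed → moving
    coordinates, pull-back convention).  Parameters are translation
    (voxels of the level), rotations (deg), relative scale and shear.
    """
    fdat = np.asarray(fixed.data, dtype=float)
    if fdat.max() == fdat.min() or np.asarray(moving.data).max() == np.asarray(
        moving.data
    ).min():
        raise ValueError("constant volume cannot drive NMI registration")
    center = fixed.phys_center()
    x = np.zeros(12) if init_params is None else np.asarray(init_params, float).copy()
    phys_t = np.asarray(x[:3], dtype=float)  # translation kept in µm between levels
    steps = np.array(
        [2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 0.05, 0.05, 0.05, 0.02, 0.02, 0.02]
    )
    for shrink in shrinks:
        f_lv = _shrink_volume(fixed, shrink)
        m_lv = _shrink_volume(moving, shrink)
        cost = _AffineCost(m_lv, f_lv, bins=bins, center=center)
        x[:3] = phys_t / cost.vox
        res = optimize.minimize(
            cost,
            x,
            method="Powell",
            options=dict(direc=np.diag(steps), xtol=0.005, ftol=1e-7, maxiter=40),
        )
        x = np.asarray(res.x, dtype=float)
        phys_t = x[:3] * cost.vox
    return AffineTransform3D.from_params(
        translation=phys_t,
        rotation_deg=x[3:6],
        scale=1.0 + np.asarray(x[6:9]),
        shear=np.asarray(x[9:12]),
        center=center,
    )


# ---------------------------------------------------------------------------
# non-linear 2D (gated free-form deformation)
# ---------------------------------------------------------------------------


def _demons_displacement(
    F: np.ndarray,
    M: np.ndarray,
    scales=(4, 2, 1),
    n_iter: int = 60,
    sigma_fluid: float = 1.5,
    sigma_diff: float = 1.5,
) -> np.ndarray:
    """Multi-scale demons estimation of the pull-back displacement (px)
    that warps ``M`` onto ``F``: returns ``u`` (2, H, W) in (row, col)
    pixels with ``M(x + u(x)) ~ F(x)``."""
    u = np.zeros((2, *F.shape))
    for sc in scales:
        if sc > 1:
            Fs = ndimage.zoom(ndimage.gaussian_filter(F, sc / 2), 1 / sc, order=1)
            Ms = ndimage.zoom(ndimage.gaussian_filter(M, sc / 2), 1 / sc, order=1)
        else:
            Fs, Ms = F, M
        zoom = np.array(Fs.shape) / np.array(F.shape)
        us = np.stack([ndimage.zoom(u[c], zoom, order=1) for c in range(2)]) / sc
        gy, gx = np.gradient(Fs)
        g2 = gy**2 + gx**2
        rows, cols = np.mgrid[0 : Fs.shape[0], 0 : Fs.shape[1]].astype(float)
        for _ in range(n_iter):
            Mw = ndimage.map_coordinates(
                Ms, [rows + us[0], cols + us[1]], order=1, mode="nearest"
            )
            diff = Mw - Fs
            den = g2 + diff**2 / (sc * sc)
            du_y = ndimage.gaussian_filter(
                -diff * gy / np.maximum(den, 1e-9), sigma_fluid
            )
            du_x = ndimage.gaussian_filter(
                -diff * gx / np.maximum(den, 1e-9), sigma_fluid
            )
            uy = ndimage.map_coordinates(
                us[0], [rows + du_y, cols + du_x], order=1, mode="nearest"
            ) + du_y
            ux = ndimage.map_coordinates(
                us[1], [rows + du_y, cols + du_x], order=1, mode="nearest"
            ) + du_x
            us = np.stack(
                [
                    ndimage.gaussian_filter(uy, sigma_diff),
                    ndimage.gaussian_filter(ux, sigma_diff),
                ]
            )
        back = np.array(F.shape) / np.array(Fs.shape)
        u = np.stack([ndimage.zoom(us[c] * sc, back, order=1) for c in range(2)])
        u = u[:, : F.shape[0], : F.shape[1]]
        if u.shape[1:] != F.shape:
            pad = [(0, 0), (0, F.shape[0] - u.shape[1]), (0, F.shape[1] - u.shape[2])]
            u = np.pad(u, pad, mode="edge")
    return u


def _intensity_prematch(moving: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    """Monotone remap of moving intensities onto fixed's distribution
    (mono-modalizes the pair for the intensity-difference force)."""
    src = np.sort(moving.ravel())
    dst = np.sort(fixed.ravel())
    q = np.linspace(0, 1, 257)
    return np.interp(
        moving, np.quantile(src, q), np.quantile(dst, q)
    )


def register_nonlinear_2d(
    moving: Section2D,
    fixed: Section2D,
    control_spacing: float,
    regularization_weight: float = 1.0,
    gate_margin: float = 0.0,
    n_iter: int = 60,
    bins: int = 64,
    prematch: bool = True,
    force_smoothing: float = 1.0,
) -> tuple[DeformationField2D, bool]:
    """Gated free-form deformation of ``moving`` onto ``fixed``.

    The dense displacement is estimated with a multi-scale demons scheme
    (intensity-difference forces, Gaussian fluid/diffusion regularization
    scaled by ``regularization_weight``; ``prematch`` first remaps the
    moving intensities onto the fixed distribution so the difference
    force is meaningful across staining/contrast differences).  The
    result is projected onto a cubic-B-spline control lattice of spacing
    ``control_spacing`` (µm; must exceed 4 pixels), which enforces the
    smoothness the corruption model assumes and keeps the field
    compactly parameterized.

    The field is ACCEPTED only if the post-warp NMI exceeds the pre-warp
    NMI by ``gate_margin``; otherwise a zero field is returned with
    ``accepted = False`` (the affine-only fallback).
    """
    sy, sx = fixed.pixel_size
    px = (sy + sx) / 2.0
    spacing_px = control_spacing / px
    if spacing_px < 4:
        raise ValueError("control_spacing below 4 pixels is under-regularized")
    fix = np.asarray(fixed.pixels, dtype=float)
    h, w = fix.shape
    mask = fixed.mask

    zero = DeformationField2D(
        displacement=np.zeros((2, h, w)), pixel_size=fixed.pixel_size,
        origin=fixed.origin,
    )
    base = resample(moving, zero, target_grid=fixed)
    mov = np.asarray(base.pixels, dtype=float)
    # the accept/reject decision is made on tissue: intersect the fixed
    # mask with the moving section's foreground so background content
    # (which has no true correspondence) cannot carry the gate
    gate_mask = mask
    if base.mask is not None:
        gate_mask = base.mask if gate_mask is None else (gate_mask & base.mask)
        if not gate_mask.any():
            gate_mask = mask
    nmi_before = nmi(fix, mov, bins=bins, mask=gate_mask)

    mov_force = _intensity_prematch(mov, fix) if prematch else mov
    fix_force = fix
    if force_smoothing > 0:
        # match resolutions before estimating forces: fine texture present
        # in only one image otherwise drives spurious displacements
        mov_force = ndimage.gaussian_filter(mov_force, force_smoothing)
        fix_force = ndimage.gaussian_filter(fix, force_smoothing)
    sig = 1.5 * max(regularization_weight, 1e-3)
    u_px = _demons_displacement(
        fix_force, mov_force, n_iter=n_iter, sigma_fluid=sig, sigma_diff=sig
    )
    # project the dense field onto the cubic B-spline control lattice
    s_px = max(4, int(round(spacing_px)))
    cy = np.arange(0, h + s_px - 1, s_px).clip(max=h - 1)
    cx = np.arange(0, w + s_px - 1, s_px).clip(max=w - 1)
    cy = np.unique(cy)
    cx = np.unique(cx)
    pre = max(0.5, s_px / 4.0)
    uy_s = ndimage.gaussian_filter(u_px[0], pre)
    ux_s = ndimage.gaussian_filter(u_px[1], pre)
    ky = min(3, cy.size - 1)
    kx = min(3, cx.size - 1)
    sp_y = RectBivariateSpline(cy, cx, uy_s[np.ix_(cy, cx)], kx=kx, ky=ky)
    sp_x = RectBivariateSpline(cy, cx, ux_s[np.ix_(cy, cx)], kx=kx, ky=ky)
    disp = np.stack(
        [
            sp_x(np.arange(h), np.arange(w)) * sx,
            sp_y(np.arange(h), np.arange(w)) * sy,
        ]
    )
    fld = DeformationField2D(
        displacement=disp, pixel_size=fixed.pixel_size, origin=fixed.origin
    )
    warped = np.asarray(resample(moving, fld, target_grid=fixed).pixels, dtype=float)
    nmi_after = nmi(fix, warped, bins=bins, mask=gate_mask)
    if nmi_after > nmi_before + gate_margin and not fld.is_identity(1e-9):
        return fld, True
    return zero, False
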