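"""Spatial transforms in physical units, their algebra, and resampling.

All transforms map *physical* points (µm).  Resampling is pull-back:
``resample(image, t)`` produces ``out(x) = image(t(x))`` for every output
pixel/voxel centre ``x``, so a transform returned by a registration maps
fixed-image coordinates into moving-image coordinates.  Chains of
transforms are flattened and evaluated point-wise so that any composition
costs exactly one interpolation of the image data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .core import Section2D, Volume3D

__all__ = [
    "RigidTransform2D",
    "AffineTransform3D",
    "DeformationField2D",
    "TransformChain",
    "compose",
    "invert",
    "map_points",
    "resample",
    "resample_volume",
    "rescale_transform",
]


# ---------------------------------------------------------------------------
# transform types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform2D:
    """2D rotation + translation about a pivot, acting on (x, y) in µm.

    ``T(p) = R(theta) (p - c) + c + t`` with ``c`` the pivot (``center``)
    and ``t = (tx, ty)``.  Angles are degrees, counter-clockwise.
    """

    theta: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on column vectors (x, y, 1)."""
        th = math.radians(self.theta)
        c, s = math.cos(th), math.sin(th)
        R = np.array([[c, -s], [s, c]])
        cx, cy = self.center
        b = np.array([cx + self.tx, cy + self.ty]) - R @ np.array([cx, cy])
        M = np.eye(3)
        M[:2, :2] = R
        M[:2, 2] = b
        return M

    @classmethod
    def from_matrix(
        cls, M: np.ndarray, center: tuple[float, float] = (0.0, 0.0)
    ) -> "RigidTransform2D":
        theta = math.degrees(math.atan2(M[1, 0], M[0, 0]))
        R = M[:2, :2]
        b = M[:2, 2]
        c = np.asarray(center, dtype=float)
        t = b + R @ c - c
        return cls(theta=theta, tx=float(t[0]), ty=float(t[1]), center=tuple(center))

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        M = self.matrix
        return pts @ M[:2, :2].T + M[:2, 2]

    def is_identity(self, tol: float = 1e-12) -> bool:
        return abs(self.theta) < tol and abs(self.tx) < tol and abs(self.ty) < tol


@dataclass(frozen=True)
class AffineTransform3D:
    """3D affine map ``T(p) = L p + o`` on physical (x, y, z) points, µm."""

    linear: np.ndarray = field(default_factory=lambda: np.eye(3))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "linear", np.asarray(self.linear, dtype=float))
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float))
        if self.linear.shape != (3, 3) or self.offset.shape != (3,):
            raise ValueError("linear must be 3x3 and offset length 3")
        if abs(np.linalg.det(self.linear)) < 1e-15:
            raise ValueError("singular linear part")

    @property
    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.linear
        M[:3, 3] = self.offset
        return M

    @classmethod
    def identity(cls) -> "AffineTransform3D":
        return cls()

    @classmethod
    def from_params(
        cls,
        translation=(0.0, 0.0, 0.0),
        rotation_deg=(0.0, 0.0, 0.0),
        scale=(1.0, 1.0, 1.0),
        shear=(0.0, 0.0, 0.0),
        center=(0.0, 0.0, 0.0),
    ) -> "AffineTransform3D":
        """Build from 12 parameters; rotations about x, y, z axes in turn,
        applied about ``center``."""
        rx, ry, rz = (math.radians(a) for a in rotation_deg)
        cx, sx_ = math.cos(rx), math.sin(rx)
        cy, sy_ = math.cos(ry), math.sin(ry)
        cz, sz_ = math.cos(rz), math.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx_], [0, sx_, cx]])
        Ry = np.array([[cy, 0, sy_], [0, 1, 0], [-sy_, 0, cy]])
        Rz = np.array([[cz, -sz_, 0], [sz_, cz, 0], [0, 0, 1]])
        S = np.diag(scale)
        Sh = np.array([[1, shear[0], shear[1]], [0, 1, shear[2]], [0, 0, 1]])
        L = Rz @ Ry @ Rx @ S @ Sh
        c = np.asarray(center, dtype=float)
        o = np.asarray(translation, dtype=float) + c - L @ c
        return cls(linear=L, offset=o)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.linear.T + self.offset

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            np.allclose(self.linear, np.eye(3), atol=tol)
            and np.allclose(self.offset, 0.0, atol=tol)
        )


@dataclass
class DeformationField2D:
    """Dense 2D displacement field ``T(p) = p + u(p)`` in µm.

    ``displacement`` is ``(2, H, W)``: channel 0 is the x-displacement,
    channel 1 the y-displacement, sampled on a pixel grid with the given
    ``pixel_size`` / ``origin``.  Off-grid queries use bilinear
    interpolation with edge clamping.
    """

    displacement: np.ndarray
    pixel_size: tuple[float, float] = (1.0, 1.0)
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 3 or self.displacement.shape[0] != 2:
            raise ValueError("displacement must be (2, H, W)")
        ps = np.atleast_1d(np.asarray(self.pixel_size, dtype=float))
        self.pixel_size = (float(ps[0]), float(ps[-1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.displacement.shape[1:]

    def displacement_at(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        sy, sx = self.pixel_size
        rows = (pts[:, 1] - self.origin[1]) / sy
        cols = (pts[:, 0] - self.origin[0]) / sx
        coords = np.stack([rows, cols])
        ux = ndimage.map_coordinates(
            self.displacement[0], coords, order=1, mode="nearest"
        )
        uy = ndimage.map_coordinates(
            self.displacement[1], coords, order=1, mode="nearest"
        )
        return np.stack([ux, uy], axis=1)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts + self.displacement_at(pts)

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.sum(self.displacement**2, axis=0))))

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(np.max(np.abs(self.displacement)) < tol)


@dataclass
class TransformChain:
    """Lazy composition ``(t1 ∘ t2 ∘ … ∘ tn)(x) = t1(t2(…tn(x)))``.

    Evaluated point-wise at resample time so the chain costs a single
    image interpolation regardless of length.
    """

    transforms: list

    def __post_init__(self):
        flat: list = []
        for t in self.transforms:
            if isinstance(t, TransformChain):
                flat.extend(t.transforms)
            else:
                flat.append(t)
        self.transforms = flat

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        for t in reversed(self.transforms):
            pts = t(pts)
        return pts

    def is_identity(self, tol: float = 1e-12) -> bool:
        return all(t.is_identity(tol) for t in self.transforms)


Transform2D = Union[RigidTransform2D, DeformationField2D, TransformChain]


# ---------------------------------------------------------------------------
# algebra
# ---------------------------------------------------------------------------


def _dim_of(t) -> int:
    if isinstance(t, (RigidTransform2D, DeformationField2D)):
        return 2
    if isinstance(t, AffineTransform3D):
        return 3
    if isinstance(t, TransformChain):
        dims = {_dim_of(s) for s in t.transforms}
        if len(dims) > 1:
            raise ValueError("mixed-dimension chain")
        return dims.pop() if dims else 0


def compose(a, b):
    """Return ``a ∘ b`` (``(a∘b)(x) = a(b(x))``).

    Rigid∘rigid stays rigid and affine∘affine stays affine (closed-form
    matrix products); anything involving a dense field becomes a lazy
    chain evaluated in one interpolation.
    """
    da, db = _dim_of(a), _dim_of(b)
    if da and db and da != db:
        raise ValueError(f"cannot compose {da}D with {db}D transform")
    if isinstance(a, RigidTransform2D) and isinstance(b, RigidTransform2D):
        return RigidTransform2D.from_matrix(a.matrix @ b.matrix, center=a.center)
    if isinstance(a, AffineTransform3D) and isinstance(b, AffineTransform3D):
        return AffineTransform3D(
            linear=a.linear @ b.linear, offset=a.linear @ b.offset + a.offset
        )
    return TransformChain([a, b])


def invert(t, n_iter: int = 30, tol: float = 1e-3):
    """Invert a transform.

    Rigid and affine inverses are exact.  Dense fields are inverted by
    fixed-point iteration ``v_{k+1}(x) = -u(x + v_k(x))``, which converges
    for fields satisfying the no-folding condition (|∇u| < 1); ``tol`` is
    the µm-scale stopping change per iteration.
    """
    if isinstance(t, RigidTransform2D):
        return RigidTransform2D.from_matrix(np.linalg.inv(t.matrix), center=t.center)
    if isinstance(t, AffineTransform3D):
        Li = np.linalg.inv(t.linear)
        return AffineTransform3D(linear=Li, offset=-Li @ t.offset)
    if isinstance(t, DeformationField2D):
        h, w = t.shape
        sy, sx = t.pixel_size
        X, Y = np.meshgrid(
            t.origin[0] + np.arange(w) * sx, t.origin[1] + np.arange(h) * sy
        )
        pts = np.stack([X.ravel(), Y.ravel()], axis=1)
        v = np.zeros_like(pts)
        for _ in range(n_iter):
            u = t.displacement_at(pts + v)
            v_new = -u
            delta = np.max(np.abs(v_new - v)) if v.size else 0.0
            v = v_new
            if delta < tol:
                break
        disp = np.stack([v[:, 0].reshape(h, w), v[:, 1].reshape(h, w)])
        return DeformationField2D(
            displacement=disp, pixel_size=t.pixel_size, origin=t.origin
        )
    if isinstance(t, TransformChain):
        return TransformChain([invert(s, n_iter, tol) for s in reversed(t.transforms)])
    raise TypeError(f"cannot invert {type(t).__name__}")


def map_points(t, pts: np.ndarray) -> np.ndarray:
    """Apply any transform (or chain) to an ``(N, d)`` point array."""
    return t(np.atleast_2d(np.asarray(pts, dtype=float)))


def rescale_transform(t: RigidTransform2D, factor: float) -> RigidTransform2D:
    """Revalidate a rigid transform estimated on a grid downsampled by
    ``factor``.

    Transforms live in physical µm, so the parameters are resolution
    independent: this is the identity on (theta, tx, ty, center) and only
    checks the factor is sensible.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if not isinstance(t, RigidTransform2D):
        raise TypeError("rescale_transform applies to RigidTransform2D")
    return t


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

_ORDER = {"nearest": 0, "linear": 1, "cubic": 3}


def resample(
    section: Section2D,
    t,
    target_grid: Optional[Section2D] = None,
    interpolation: str = "linear",
    cval: float = 0.0,
) -> Section2D:
    """Pull-back resample a section: ``out(x) = section(t(x))``.

    ``target_grid`` supplies the output grid and metadata (defaults to the
    input's own grid).  Out-of-domain samples get ``cval``.  Any chain of
    transforms is evaluated point-wise first, so the pixel data is
    interpolated exactly once.  ``cubic`` is available for synthesis-side
    warps that must preserve fine texture; the pipeline itself uses
    nearest/linear.
    """
    if interpolation not in _ORDER:
        raise ValueError("interpolation must be 'nearest', 'linear' or 'cubic'")
    tgt = target_grid if target_grid is not None else section
    X, Y = tgt.phys_grid()
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    src = map_points(t, pts)
    coords = section.phys_to_index(src)
    out = ndimage.map_coordinates(
        np.asarray(section.pixels, dtype=float),
        coords,
        order=_ORDER[interpolation],
        mode="constant",
        cval=cval,
    ).reshape(tgt.shape)
    if interpolation == "nearest" and np.issubdtype(section.pixels.dtype, np.integer):
        out = out.astype(section.pixels.dtype)
    new_mask = None
    if section.mask is not None:
        new_mask = (
            ndimage.map_coordinates(
                section.mask.astype(float), coords, order=0, mode="constant", cval=0.0
            ).reshape(tgt.shape)
            > 0.5
        )
    return Section2D(
        pixels=out,
        pixel_size=tgt.pixel_size,
        index=section.index,
        z=section.z,
        mask=new_mask,
        origin=tgt.origin,
    )


def resample_volume(
    volume: Volume3D,
    t,
    target_grid: Optional[Volume3D] = None,
    interpolation: str = "linear",
    cval: float = 0.0,
) -> Volume3D:
    """Pull-back resample a volume onto ``target_grid`` (µm metadata)."""
    if interpolation not in _ORDER:
        raise ValueError("interpolation must be 'nearest' or 'linear'")
    tgt = target_grid if target_grid is not None else volume
    nz, ny, nx = tgt.shape
    sz, sy, sx = tgt.voxel_size
    oz, oy, ox = tgt.origin
    # physical coordinates of every target voxel centre, (x, y, z)
    zz, yy, xx = np.meshgrid(
        oz + np.arange(nz) * sz,
        oy + np.arange(ny) * sy,
        ox + np.arange(nx) * sx,
        indexing="ij",
    )
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    src = map_points(t, pts)
    coords = volume.phys_to_index(src)
    out = ndimage.map_coordinates(
        np.asarray(volume.data, dtype=float),
        coords,
        order=_ORDER[interpolation],
        mode="constant",
        cval=cval,
    ).reshape(tgt.shape)
    if interpolation == "nearest" and np.issubdtype(volume.data.dtype, np.integer):
        out = out.astype(volume.data.dtype)
    return Volume3D(data=out, voxel_size=tgt.voxel_size, origin=tgt.origin)
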