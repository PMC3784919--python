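"""Core containers: 2D sections, 3D volumes and ordered section series.

Conventions used throughout the package:

* All physical lengths are micrometres (µm); millimetres appear only at
  NIfTI boundaries and in a few user-facing parameters that are
  conventionally quoted in mm (bias-filter FWHM, coil profile scale).
* Arrays are indexed ``(row, col)`` for sections and ``(z, y, x)`` for
  volumes.  Physical points are ``(x, y)`` / ``(x, y, z)`` vectors.
* Pixel/voxel *centres* sit on the physical grid: the centre of pixel
  ``(r, c)`` is at ``origin + (c * sx, r * sy)``.  Indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = ["Section2D", "Volume3D", "SectionSeries"]


def _as_pair(v) -> tuple[float, float]:
    a = np.atleast_1d(np.asarray(v, dtype=float))
    if a.size == 1:
        return (float(a[0]), float(a[0]))
    if a.size != 2:
        raise ValueError("expected a scalar or a length-2 sequence")
    return (float(a[0]), float(a[1]))


@dataclass
class Section2D:
    """One digitized histology section or a resliced MR plane.

    Parameters
    ----------
    pixels
        ``(H, W)`` grayscale or ``(H, W, 3)`` RGB intensity grid.
    pixel_size
        Physical pixel size in µm, scalar or ``(sy, sx)``.
    index
        Position of the section in its series.
    z
        Through-plane physical position in µm.
    mask
        Optional ``(H, W)`` boolean foreground mask.
    origin
        Physical position ``(x0, y0)`` of pixel ``(0, 0)``'s centre, µm.
    """

    pixels: np.ndarray
    pixel_size: tuple[float, float] = (1.0, 1.0)
    index: int = 0
    z: float = 0.0
    mask: Optional[np.ndarray] = None
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2D (gray) or 3D (RGB)")
        self.pixel_size = _as_pair(self.pixel_size)
        if min(self.pixel_size) <= 0:
            raise ValueError("pixel_size must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape[:2]:
                raise ValueError("mask shape does not match pixels")
        self.origin = _as_pair(self.origin)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3

    def phys_center(self) -> tuple[float, float]:
        """Physical (x, y) of the image centre."""
        h, w = self.shape
        sy, sx = self.pixel_size
        return (self.origin[0] + (w - 1) / 2 * sx, self.origin[1] + (h - 1) / 2 * sy)

    def phys_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical coordinates of every pixel centre as ``(X, Y)`` grids."""
        h, w = self.shape
        sy, sx = self.pixel_size
        x = self.origin[0] + np.arange(w) * sx
        y = self.origin[1] + np.arange(h) * sy
        return np.meshgrid(x, y)

    def phys_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map ``(N, 2)`` physical (x, y) points to fractional (row, col)."""
        pts = np.asarray(pts, dtype=float)
        sy, sx = self.pixel_size
        rows = (pts[:, 1] - self.origin[1]) / sy
        cols = (pts[:, 0] - self.origin[0]) / sx
        return np.stack([rows, cols], axis=0)

    def with_pixels(self, pixels: np.ndarray, **kw) -> "Section2D":
        return replace(self, pixels=pixels, **kw)

    def foreground_centroid(self) -> tuple[float, float]:
        """Physical (x, y) centroid of the mask (or intensity-weighted)."""
        if self.mask is not None and self.mask.any():
            rr, cc = np.nonzero(self.mask)
        else:
            g = self.pixels if not self.is_rgb else self.pixels.mean(axis=2)
            w = np.abs(np.asarray(g, dtype=float))
            tot = w.sum()
            if tot == 0:
                return self.phys_center()
            rr, cc = np.indices(self.shape).reshape(2, -1)
            wts = w.ravel()
            sy, sx = self.pixel_size
            x = self.origin[0] + float((cc * wts).sum() / tot) * sx
            y = self.origin[1] + float((rr * wts).sum() / tot) * sy
            return (x, y)
        sy, sx = self.pixel_size
        return (
            self.origin[0] + float(cc.mean()) * sx,
            self.origin[1] + float(rr.mean()) * sy,
        )


@dataclass
class Volume3D:
    """A 3D image with anisotropic voxel sizes on an axis-aligned grid.

    ``data`` is indexed ``(z, y, x)``; ``voxel_size`` and ``origin`` follow
    the same axis order, in µm.  The grid-to-physical map is
    ``phys = origin + index * voxel_size`` per axis (voxel centres).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size))
        if len(vs) == 1:
            vs = vs * 3
        if len(vs) != 3 or min(vs) <= 0:
            raise ValueError("voxel_size must be 3 positive values (z, y, x)")
        self.voxel_size = vs
        og = tuple(float(v) for v in np.atleast_1d(self.origin))
        if len(og) == 1:
            og = og * 3
        self.origin = og

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def phys_center(self) -> tuple[float, float, float]:
        """Physical (x, y, z) of the grid centre."""
        nz, ny, nx = self.shape
        sz, sy, sx = self.voxel_size
        oz, oy, ox = self.origin
        return (
            ox + (nx - 1) / 2 * sx,
            oy + (ny - 1) / 2 * sy,
            oz + (nz - 1) / 2 * sz,
        )

    def phys_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map ``(N, 3)`` physical (x, y, z) points to fractional (z, y, x)."""
        pts = np.asarray(pts, dtype=float)
        sz, sy, sx = self.voxel_size
        oz, oy, ox = self.origin
        iz = (pts[:, 2] - oz) / sz
        iy = (pts[:, 1] - oy) / sy
        ix = (pts[:, 0] - ox) / sx
        return np.stack([iz, iy, ix], axis=0)

    def index_to_phys(self, idx: np.ndarray) -> np.ndarray:
        """Map ``(N, 3)`` fractional (z, y, x) indices to physical (x, y, z)."""
        idx = np.asarray(idx, dtype=float)
        sz, sy, sx = self.voxel_size
        oz, oy, ox = self.origin
        return np.stack(
            [ox + idx[:, 2] * sx, oy + idx[:, 1] * sy, oz + idx[:, 0] * sz], axis=1
        )

    def plane(self, k: int) -> Section2D:
        """Extract axial plane ``k`` as a section with inherited metadata."""
        sz, sy, sx = self.voxel_size
        oz, oy, ox = self.origin
        return Section2D(
            pixels=self.data[k],
            pixel_size=(sy, sx),
            index=k,
            z=oz + k * sz,
            origin=(ox, oy),
        )

    def with_data(self, data: np.ndarray) -> "Volume3D":
        return replace(self, data=data)


@dataclass
class SectionSeries:
    """An ordered, uniformly spaced series of sections.

    ``spacing`` is the physical distance in µm between retained sections
    (e.g. 200 µm when every 10th 20 µm section is kept).  ``anchor`` is the
    index held fixed (identity transform) when the series is stacked.
    """

    sections: list[Section2D]
    spacing: float
    anchor: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sections:
            raise ValueError("series must contain at least one section")
        idx = [s.index for s in self.sections]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("section indices must be strictly increasing")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.anchor is None:
            self.anchor = len(self.sections) // 2
        if not (0 <= self.anchor < len(self.sections)):
            raise ValueError("anchor outside series")

    def __len__(self) -> int:
        return len(self.sections)

    def __getitem__(self, i: int) -> Section2D:
        return self.sections[i]

    def __iter__(self):
        return iter(self.sections)

    def map(self, fn) -> "SectionSeries":
        return SectionSeries(
            sections=[fn(s) for s in self.sections],
            spacing=self.spacing,
            anchor=self.anchor,
        )
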