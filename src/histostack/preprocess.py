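"""Section preprocessing: grayscale conversion, background masking,
downsampling, histogram matching, reference selection, and volume-mask
thresholding/transfer for formalin removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .core import Section2D, SectionSeries, Volume3D
from .transforms import AffineTransform3D, resample_volume

__all__ = [
    "MorphologyParams",
    "background_mask",
    "downsample",
    "match_histogram",
    "rgb_to_gray",
    "select_reference",
    "threshold_mask",
    "transfer_mask",
]


@dataclass(frozen=True)
class MorphologyParams:
    erode_radius: int = 2
    dilate_radius: int = 2
    min_component_fraction: float = 0.05

    def __post_init__(self):
        if self.erode_radius < 0 or self.dilate_radius < 0:
            raise ValueError("radii must be non-negative")
        if not (0 < self.min_component_fraction <= 1):
            raise ValueError("min_component_fraction must be in (0, 1]")


def rgb_to_gray(section: Section2D) -> Section2D:
    """Equal-weight channel mean, rounded half-away-from-zero.

    8-bit input yields 8-bit output.
    """
    if not section.is_rgb or section.pixels.shape[2] != 3:
        raise ValueError("expected an RGB section with exactly 3 channels")
    mean = np.asarray(section.pixels, dtype=float).mean(axis=2)
    gray = np.floor(mean + 0.5)  # half-away-from-zero for non-negative data
    if np.issubdtype(section.pixels.dtype, np.integer):
        gray = gray.astype(section.pixels.dtype)
    return section.with_pixels(gray)


def background_mask(
    section: Section2D, params: MorphologyParams = MorphologyParams()
) -> np.ndarray:
    """Tissue foreground mask: Otsu threshold, erosion, connected-component
    pruning, dilation.

    Components smaller than ``min_component_fraction`` of the largest are
    dropped (isolated scanner noise).  An all-background image yields an
    empty mask with a warning.
    """
    if section.is_rgb:
        raise ValueError("background_mask expects a grayscale section")
    img = np.asarray(section.pixels, dtype=float)
    if img.max() == img.min():
        if img.max() != 0:
            warnings.warn("constant non-zero image; mask is everything")
            return np.ones(img.shape, dtype=bool)
        warnings.warn("all-background image; returning empty mask")
        return np.zeros(img.shape, dtype=bool)
    t = filters.threshold_otsu(img)
    fg = img > t
    if params.erode_radius > 0:
        fg = morphology.erosion(fg, morphology.disk(params.erode_radius))
    lab = measure.label(fg, connectivity=2)
    if lab.max() == 0:
        warnings.warn("mask empty after erosion")
        return np.zeros(img.shape, dtype=bool)
    sizes = np.bincount(lab.ravel())[1:]
    keep = np.nonzero(sizes >= params.min_component_fraction * sizes.max())[0] + 1
    fg = np.isin(lab, keep)
    if params.dilate_radius > 0:
        fg = morphology.dilation(fg, morphology.disk(params.dilate_radius))
    return fg


def downsample(section: Section2D, factor: int) -> Section2D:
    """Block-mean downsample by an integer factor.

    Equivalent to bilinear interpolation at half-pixel phase for factor 2
    with better anti-aliasing; odd trailing rows/columns are cropped.
    The recorded pixel size is multiplied by the factor.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    h, w = section.shape
    if factor > h or factor > w:
        raise ValueError("factor exceeds image dimensions")
    if factor == 1:
        return section
    hh, ww = (h // factor) * factor, (w // factor) * factor
    img = np.asarray(section.pixels[:hh, :ww], dtype=float)
    if section.is_rgb:
        blocks = img.reshape(hh // factor, factor, ww // factor, factor, -1)
        out = blocks.mean(axis=(1, 3))
    else:
        out = img.reshape(hh // factor, factor, ww // factor, factor).mean(axis=(1, 3))
    sy, sx = section.pixel_size
    mask = None
    if section.mask is not None:
        m = section.mask[:hh, :ww].astype(float)
        mask = m.reshape(hh // factor, factor, ww // factor, factor).mean(
            axis=(1, 3)
        ) > 0.5
    # block centre of block (0,0) sits at pixel index (factor-1)/2
    oy = section.origin[1] + (factor - 1) / 2 * sy
    ox = section.origin[0] + (factor - 1) / 2 * sx
    return Section2D(
        pixels=out,
        pixel_size=(sy * factor, sx * factor),
        index=section.index,
        z=section.z,
        mask=mask,
        origin=(ox, oy),
    )


def _masked_values(section: Section2D) -> np.ndarray:
    img = np.asarray(section.pixels, dtype=float)
    if section.mask is not None and section.mask.any():
        return img[section.mask]
    return img.ravel()


def _entropy(values: np.ndarray, bins: int = 64) -> float:
    h, _ = np.histogram(values, bins=bins)
    p = h[h > 0] / h.sum()
    return float(-(p * np.log2(p)).sum())


def select_reference(series: SectionSeries, override: Optional[int] = None) -> int:
    """Pick a reference section for histogram matching.

    Automated stand-in for a manual choice: among sections whose masked
    entropy is at or above the series median (good contrast), return the
    one whose masked mean is closest to the series median mean (smooth,
    typical staining); ties break to the lowest index.  ``override``
    short-circuits the heuristic.
    """
    if override is not None:
        if not (0 <= override < len(series)):
            raise ValueError("override index outside series")
        return override
    means = np.array([_masked_values(s).mean() for s in series])
    ents = np.array([_entropy(_masked_values(s)) for s in series])
    med_mean = np.median(means)
    med_ent = np.median(ents)
    candidates = np.nonzero(ents >= med_ent)[0]
    if candidates.size == 0:
        candidates = np.arange(len(series))
    best = candidates[np.argmin(np.abs(means[candidates] - med_mean))]
    return int(best)


def match_histogram(section: Section2D, reference: Section2D) -> Section2D:
    """Monotone CDF mapping of foreground intensities onto the reference's
    foreground distribution; background pixels pass through as 0.

    The mapping is value-based (every occurrence of a source value maps
    to the same output), exact for integer-valued inputs matched to
    themselves, and idempotent.
    """
    if section.is_rgb or reference.is_rgb:
        raise ValueError("match_histogram expects grayscale sections")
    for s in (section, reference):
        if s.mask is not None and not s.mask.any():
            raise ValueError("empty foreground")
    src = _masked_values(section)
    ref = np.sort(_masked_values(reference))
    if src.size == 0 or ref.size == 0:
        raise ValueError("empty foreground")
    vals, counts = np.unique(src, return_counts=True)
    # midpoint CDF: a tie block maps to the reference quantile at its
    # centre, not its upper edge (unbiased for heavily tied histograms)
    cdf = (np.cumsum(counts) - counts / 2.0) / src.size
    # step quantile function of the reference: Q(q) = ref_sorted[ceil(q m)-1]
    idx = np.clip(np.ceil(cdf * ref.size).astype(int) - 1, 0, ref.size - 1)
    mapped = ref[idx]
    img = np.asarray(section.pixels, dtype=float)
    out = np.interp(img, vals, mapped)  # monotone; exact at the knots
    if section.mask is not None:
        out = np.where(section.mask, out, 0.0)
    return section.with_pixels(out)


def threshold_mask(
    volume: Volume3D,
    method: Union[str, float] = "otsu",
    closing_radius: int = 1,
    exclude_zero: bool = False,
) -> Volume3D:
    """Binary brain mask of a volume by thresholding.

    ``method`` is ``"otsu"`` or a fixed numeric threshold; voxels at or
    above threshold are foreground.  With ``exclude_zero`` the Otsu
    threshold is computed over non-zero voxels only, so a large empty
    background does not dominate the histogram and the threshold falls
    between the fluid (formalin) and tissue classes.  The largest 3D
    connected component is retained and morphologically closed — the
    formalin-removal mask of the low-field acquisition.
    """
    data = np.asarray(volume.data, dtype=float)
    if method == "otsu":
        vals = data[data > 0] if exclude_zero else data
        if vals.size == 0 or vals.max() == vals.min():
            raise ValueError("constant volume: Otsu threshold undefined")
        t = filters.threshold_otsu(vals)
        mask = data > t
    else:
        t = float(method)
        mask = data >= t
    if mask.any():
        lab = measure.label(mask, connectivity=3)
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (np.argmax(sizes) + 1)
        if closing_radius > 0:
            mask = morphology.closing(mask, morphology.ball(closing_radius))
    return Volume3D(
        data=mask.astype(np.uint8),
        voxel_size=volume.voxel_size,
        origin=volume.origin,
    )


def transfer_mask(
    mask: Volume3D, transform: AffineTransform3D, target_grid: Volume3D
) -> Volume3D:
    """Resample a binary mask onto another grid through an affine map
    (nearest neighbour; outside-grid voxels become 0).

    ``transform`` maps target-grid physical points into mask space
    (pull-back), i.e. the affine from the registration of the mask's
    volume onto the target volume.
    """
    out = resample_volume(mask, transform, target_grid, interpolation="nearest")
    data = (np.asarray(out.data) > 0.5).astype(np.uint8)
    if not data.any():
        warnings.warn("transferred mask is empty (moved outside target grid)")
    return Volume3D(
        data=data, voxel_size=target_grid.voxel_size, origin=target_grid.origin
    )
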