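"""Similarity and texture measures used as cost functions and QC.

* ``nmi`` — normalized mutual information in the Studholme form
  ``(H(A) + H(B)) / H(A, B)``, entropies in bits, range [1, 2].  This is
  the cost function of every registration stage and the convergence
  monitor of the iterative reconstruction.  A second normalization,
  ``nmi_ratio = MI / H(A, B)`` in [0, 1], is exposed for comparability
  with tools that report NMI on a unit scale.
* ``ncc`` — Pearson correlation of masked intensities.
* ``glcm_homogeneity`` — Haralick inverse-difference-moment texture
  statistic; near 1 for smooth images, used to quantify bias-field
  correction quality.
* ``snr`` — mean(signal ROI) / sd(noise ROI) with an optional Rayleigh
  correction for magnitude-image backgrounds.
* ``rod_straightness`` — RMS deviation of per-slice rod centroids from a
  total-least-squares line; the "banana effect" statistic.

All metrics are pure functions of their inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Volume3D

__all__ = [
    "GLCMParams",
    "SimilarityReport",
    "glcm_homogeneity",
    "joint_histogram",
    "ncc",
    "nmi",
    "nmi_ratio",
    "rod_straightness",
    "similarity_report",
    "snr",
]

# the four standard distance-1 offsets (dy, dx): E, SE, S, SW neighbours
DEFAULT_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


@dataclass(frozen=True)
class GLCMParams:
    levels: int = 64
    offsets: tuple = DEFAULT_OFFSETS
    symmetric: bool = True

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if not self.offsets:
            raise ValueError("offsets must be non-empty")


@dataclass(frozen=True)
class SimilarityReport:
    nmi: float
    ncc: float
    bins: int
    n_pixels: int


def _masked_pair(a, b, mask):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share dimensions")
    if mask is None:
        return a.ravel(), b.ravel()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a.shape:
        raise ValueError("mask shape mismatch")
    if not mask.any():
        raise ValueError("empty mask")
    return a[mask], b[mask]


def joint_histogram(
    a: np.ndarray, b: np.ndarray, bins: int = 64, mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Joint count histogram of two equally shaped images.

    Bin edges span each image's masked intensity range independently;
    counts sum to the number of masked pixels.
    """
    av, bv = _masked_pair(a, b, mask)
    # degenerate (constant) marginals still need a valid binning
    ra = (av.min(), av.max()) if av.min() < av.max() else (av.min() - 0.5, av.max() + 0.5)
    rb = (bv.min(), bv.max()) if bv.min() < bv.max() else (bv.min() - 0.5, bv.max() + 0.5)
    h, _, _ = np.histogram2d(av, bv, bins=bins, range=(ra, rb))
    return h


def _entropies(counts: np.ndarray) -> tuple[float, float, float]:
    p = counts / counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        def H(q):
            q = q[q > 0]
            return float(-(q * np.log2(q)).sum())

        return H(p.sum(axis=1)), H(p.sum(axis=0)), H(p.ravel())


def nmi(
    a: np.ndarray, b: np.ndarray, bins: int = 64, mask: Optional[np.ndarray] = None
) -> float:
    """Normalized mutual information, Studholme form (H(A)+H(B))/H(A,B).

    Lies in [1, 2]: 1 for independent (or constant) images, 2 for a
    deterministic one-to-one intensity relationship.
    """
    counts = joint_histogram(a, b, bins=bins, mask=mask)
    ha, hb, hab = _entropies(counts)
    if hab == 0.0:
        warnings.warn("both images constant on mask; NMI defined as 1")
        return 1.0
    return (ha + hb) / hab


def nmi_ratio(
    a: np.ndarray, b: np.ndarray, bins: int = 64, mask: Optional[np.ndarray] = None
) -> float:
    """Alternative normalization MI / H(A,B), in [0, 1]."""
    counts = joint_histogram(a, b, bins=bins, mask=mask)
    ha, hb, hab = _entropies(counts)
    if hab == 0.0:
        warnings.warn("both images constant on mask; ratio defined as 0")
        return 0.0
    return (ha + hb - hab) / hab


def ncc(a: np.ndarray, b: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Pearson correlation of masked intensities (normalized cross
    correlation), in [-1, 1]."""
    av, bv = _masked_pair(a, b, mask)
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("ncc undefined for constant input")
    av = av - av.mean()
    bv = bv - bv.mean()
    return float((av @ bv) / (np.linalg.norm(av) * np.linalg.norm(bv)))


def similarity_report(
    a: np.ndarray, b: np.ndarray, bins: int = 64, mask: Optional[np.ndarray] = None
) -> SimilarityReport:
    av, _ = _masked_pair(a, b, mask)
    return SimilarityReport(
        nmi=nmi(a, b, bins=bins, mask=mask),
        ncc=ncc(a, b, mask=mask),
        bins=bins,
        n_pixels=int(av.size),
    )


def _quantize(image: np.ndarray, levels: int, mask: np.ndarray) -> np.ndarray:
    vals = image[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return np.zeros_like(image, dtype=np.intp)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def glcm_homogeneity(
    image: np.ndarray,
    params: GLCMParams = GLCMParams(),
    mask: Optional[np.ndarray] = None,
) -> float:
    """Haralick homogeneity Σ p(i,j)/(1+(i-j)²), averaged over offsets.

    The image is quantized to ``params.levels`` gray levels over the
    masked range; co-occurrence is counted symmetrically for each
    distance-1 offset and normalized per offset.  1.0 for a constant
    image, small for high-frequency texture.
    """
    image = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    q = _quantize(image, params.levels, mask)
    total = 0.0
    for dy, dx in params.offsets:
        h, w = image.shape
        ys = slice(max(0, -dy), min(h, h - dy))
        xs = slice(max(0, -dx), min(w, w - dx))
        ys2 = slice(max(0, dy), min(h, h + dy))
        xs2 = slice(max(0, dx), min(w, w + dx))
        m = mask[ys, xs] & mask[ys2, xs2]
        if m.sum() < 2:
            raise ValueError(f"fewer than 2 masked pairs for offset {(dy, dx)}")
        i = q[ys, xs][m]
        j = q[ys2, xs2][m]
        counts = np.zeros((params.levels, params.levels))
        np.add.at(counts, (i, j), 1.0)
        if params.symmetric:
            counts = counts + counts.T
        p = counts / counts.sum()
        ii, jj = np.indices(counts.shape)
        total += float((p / (1.0 + (ii - jj) ** 2)).sum())
    return total / len(params.offsets)


#: mean/sd ratio of a Rayleigh background relative to the underlying
#: complex-noise sigma: sd(Rayleigh) = sigma * sqrt(2 - pi/2) ≈ 0.655 sigma
RAYLEIGH_SD_FACTOR = float(np.sqrt(2.0 - np.pi / 2.0))


def snr(
    volume,
    signal_mask: np.ndarray,
    noise_mask: np.ndarray,
    rayleigh_correct: bool = False,
) -> float:
    """SNR = mean(signal voxels) / sd(noise voxels).

    With ``rayleigh_correct`` the noise sd is divided by √(2-π/2) ≈ 0.655,
    converting a magnitude-image (Rayleigh) background spread into the
    underlying complex-noise sigma.
    """
    data = volume.data if isinstance(volume, Volume3D) else np.asarray(volume)
    signal_mask = np.asarray(signal_mask, dtype=bool)
    noise_mask = np.asarray(noise_mask, dtype=bool)
    if not signal_mask.any() or not noise_mask.any():
        raise ValueError("signal and noise masks must be non-empty")
    sd = float(np.asarray(data, dtype=float)[noise_mask].std())
    if sd == 0:
        raise ValueError("noise region has zero spread")
    if rayleigh_correct:
        sd = sd / RAYLEIGH_SD_FACTOR
    return float(np.asarray(data, dtype=float)[signal_mask].mean() / sd)


def rod_straightness(
    label_volume: Volume3D,
    rod_label: Optional[int] = None,
    min_slices: int = 5,
    min_mass_fraction: float = 0.3,
) -> float:
    """RMS perpendicular residual (µm) of per-slice rod centroids about
    their total-least-squares line — the banana-effect statistic.

    With ``rod_label`` the rod is the set of voxels carrying that label;
    with ``rod_label=None`` the data is treated as a non-negative soft
    rod indicator (e.g. a linearly resampled binary mask) and centroids
    are intensity-weighted, which keeps the statistic sub-voxel after
    resampling.  Slices whose rod mass falls below ``min_mass_fraction``
    of the median slice mass are dropped (clipped cross-sections bias
    the centroid).  The best-fit 3D line comes from an SVD of the
    centred centroid cloud.
    """
    data = np.asarray(label_volume.data, dtype=float)
    sz, sy, sx = label_volume.voxel_size
    oz, oy, ox = label_volume.origin
    if rod_label is not None:
        w = (data == rod_label).astype(float)
    else:
        w = np.clip(data, 0.0, None)
    masses = w.sum(axis=(1, 2))
    present = masses > 0
    if present.any():
        cutoff = min_mass_fraction * np.median(masses[present])
    else:
        cutoff = np.inf
    pts = []
    rr_idx, cc_idx = np.indices(data.shape[1:])
    for k in range(data.shape[0]):
        if masses[k] <= cutoff:
            continue
        wk = w[k]
        pts.append(
            [
                ox + (cc_idx * wk).sum() / masses[k] * sx,
                oy + (rr_idx * wk).sum() / masses[k] * sy,
                oz + k * sz,
            ]
        )
    if len(pts) < min_slices:
        raise ValueError(
            f"rod present in only {len(pts)} slices (need >= {min_slices})"
        )
    P = np.asarray(pts)
    Pc = P - P.mean(axis=0)
    _, _, vt = np.linalg.svd(Pc, full_matrices=False)
    d = vt[0]
    perp = Pc - np.outer(Pc @ d, d)
    return float(np.sqrt(np.mean(np.sum(perp**2, axis=1))))
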