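"""Ground-truth digital phantoms for the reconstruction pipeline.

The generator emulates the artifact taxonomy the pipeline addresses
rather than any particular anatomy: a specimen embedded in a "formalin"
compartment, smooth internal structures (ellipsoidal blobs standing in
for white-matter features), an optional straight rod whose obliqueness
makes accumulated alignment drift visible (the banana-effect probe),
per-section rigid misalignment and smooth in-plane distortion, staining
gain/gamma "stripes", a radially decreasing multiplicative intensity
hotspot, and multi-channel complex receive images with smooth coil
sensitivities and (coupled) Gaussian noise.  Every perturbation applied
is recorded so downstream stages can be scored against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import Section2D, SectionSeries, Volume3D
from .transforms import (
    DeformationField2D,
    RigidTransform2D,
    TransformChain,
    compose,
    resample,
)

__all__ = [
    "CoilData",
    "CorruptionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "add_bias_hotspot",
    "corrupt_sections",
    "histology_contrast",
    "mr_acquisition",
    "rod_indicator",
    "make_phantom",
    "simulate_coils",
    "virtual_section",
]

# label-volume compartments
LABEL_BACKGROUND = 0
LABEL_FORMALIN = 1
LABEL_GM = 2
LABEL_WM = 3
LABEL_ROD = 4


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity description of a synthetic specimen.

    ``grid_dims`` / ``voxel_size`` follow (z, y, x) array order; voxel
    sizes are µm.  ``tissue_levels`` gives the intensity of the
    background, formalin, gray-matter and white-matter compartments, in
    that order.  ``rod`` optionally embeds a straight cylinder
    (direction as an (x, y, z) vector, radius in µm) — oblique directions
    are the banana-effect test case.
    """

    grid_dims: tuple[int, int, int] = (64, 96, 96)
    voxel_size: tuple[float, float, float] = (200.0, 150.0, 150.0)
    n_blobs: int = 12
    #: blob semi-axis range as a fraction of the specimen scale, and the
    #: per-axis (z, y, x) aspect applied on top; short z-spans make
    #: adjacent sections share little beyond the outline, as real
    #: sections spaced many cell layers apart do
    blob_size_range: tuple[float, float] = (0.05, 0.14)
    blob_aspect: tuple[float, float, float] = (2.0, 1.0, 1.0)
    rod: Optional[dict] = None
    tissue_levels: tuple[float, float, float, float] = (0.0, 60.0, 120.0, 200.0)
    #: specimen half-extent as a fraction of the grid half-extent; leave
    #: margin when sections will be corrupted by large placement offsets
    specimen_fraction: float = 0.70
    #: sagitta (µm) of a parabolic bow of the specimen axis along z, in x,
    #: spanning the specimen's own z-extent: anatomy is generically curved
    #: through the sectioning direction, and this curvature is what
    #: pairwise stacking silently straightens — bending any truly straight
    #: structure inside (the banana effect)
    specimen_bend: float = 0.0
    texture_amplitude: float = 0.15
    #: cellular-texture correlation length, µm (z, y, x): in-plane texture is
    #: smooth at the scanning resolution but decorrelates between sections
    #: spaced farther apart than a few cell layers
    texture_scale: tuple[float, float, float] = (60.0, 250.0, 250.0)
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_dims) != 3 or min(self.grid_dims) < 32:
            raise ValueError("grid_dims must be 3 values, each >= 32")
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel sizes must be positive")
        if len(set(self.tissue_levels)) != len(self.tissue_levels):
            raise ValueError("tissue levels must be pairwise distinct")
        if self.rod is not None:
            d = np.asarray(self.rod["direction"], dtype=float)
            if np.linalg.norm(d) == 0:
                raise ValueError("rod direction must be non-zero")
            if self.rod.get("radius", 0) <= 0:
                raise ValueError("rod radius must be positive")


@dataclass(frozen=True)
class CorruptionSpec:
    """Per-section corruption model.

    Rigid offsets are drawn uniformly in ±max_rotation (degrees) and
    ±max_translation (µm); with ``random_walk`` the translations
    accumulate section to section (the drift regime that produces the
    banana effect in reference-free stacking).  Smooth in-plane
    distortion is a band-limited random field of the stated amplitude
    and wavelength (µm).  Staining variation is modelled as
    ``g * (I/I_max)^gamma * I_max`` with per-section uniform draws, then
    additive Gaussian noise.
    """

    max_rotation: float = 5.0
    max_translation: float = 1500.0
    deform_amplitude: float = 0.0
    deform_wavelength: float = 4000.0
    gain_range: tuple[float, float] = (1.0, 1.0)
    gamma_range: tuple[float, float] = (1.0, 1.0)
    noise_sd: float = 0.0
    random_walk: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("max_rotation", "max_translation", "deform_amplitude",
                     "deform_wavelength", "noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")


@dataclass
class PhantomTruth:
    """Everything that was done to the clean sections, for scoring.

    ``per_section_rigid[i]`` and ``per_section_field[i]`` are the
    pull-back maps used to create corrupted section ``i``:
    ``corrupted(x) = clean(R(x + u(x)))`` — so a registration of the
    corrupted section back onto the clean one should recover the inverse
    of ``compose(R, D)``.
    """

    per_section_rigid: list
    per_section_field: list
    per_section_gain_gamma: list
    bias_field: Optional[Volume3D] = None
    sensitivities: Optional[np.ndarray] = None
    rod_axis: Optional[tuple[np.ndarray, np.ndarray]] = None

    def applied_transform(self, i: int):
        """The full pull-back chain applied to section ``i``."""
        r = self.per_section_rigid[i]
        f = self.per_section_field[i]
        return r if f is None else compose(r, f)


@dataclass
class CoilData:
    """Multi-channel complex image data on a common grid."""

    channels: np.ndarray  # (C, Z, Y, X) complex
    voxel_size: tuple[float, float, float]
    noise_sd: np.ndarray  # per-channel scalar
    sensitivities: Optional[np.ndarray] = None  # (C, Z, Y, X) complex, truth

    def __post_init__(self):
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 4 or self.channels.shape[0] < 1:
            raise ValueError("channels must be (C, Z, Y, X) with C >= 1")
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (self.channels.shape[0],)
        ).copy()

    @property
    def C(self) -> int:
        return self.channels.shape[0]


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------


def _phys_grids(dims, voxel_size):
    nz, ny, nx = dims
    sz, sy, sx = voxel_size
    z = np.arange(nz) * sz
    y = np.arange(ny) * sy
    x = np.arange(nx) * sx
    return np.meshgrid(z, y, x, indexing="ij")


def make_phantom(spec: PhantomSpec):
    """Build a structured phantom volume.

    Returns ``(volume, labels, rod_axis)``: the intensity volume, the
    compartment label volume (background / formalin / GM / WM / rod) and,
    if a rod was requested, its axis as ``(point, unit_direction)`` in
    physical (x, y, z) µm (else ``None``).  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.grid_dims
    sz, sy, sx = spec.voxel_size
    Z, Y, X = _phys_grids(spec.grid_dims, spec.voxel_size)
    cz, cy, cx = (nz - 1) / 2 * sz, (ny - 1) / 2 * sy, (nx - 1) / 2 * sx
    ez, ey, ex = (nz - 1) / 2 * sz, (ny - 1) / 2 * sy, (nx - 1) / 2 * sx

    # specimen ellipsoid inside a formalin shell ~1.3x its half-extent;
    # its axis bows parabolically in x across the specimen's z-extent by
    # `specimen_bend` (true anatomical curvature through the sectioning
    # direction); the bow is the full sagitta between poles and centre
    f = spec.specimen_fraction
    fo = min(1.31 * f, 0.95)
    u = (Z - cz) / (f * ez)
    Xc = X - spec.specimen_bend * np.clip(1.0 - u**2, 0.0, 1.0)
    r2 = (
        ((Z - cz) / (f * ez)) ** 2
        + ((Y - cy) / (f * ey)) ** 2
        + ((Xc - cx) / (f * ex)) ** 2
    )
    r2_outer = (
        ((Z - cz) / (fo * ez)) ** 2
        + ((Y - cy) / (fo * ey)) ** 2
        + ((Xc - cx) / (fo * ex)) ** 2
    )
    labels = np.full(spec.grid_dims, LABEL_BACKGROUND, dtype=np.uint8)
    labels[r2_outer <= 1.0] = LABEL_FORMALIN
    specimen = r2 <= 1.0
    labels[specimen] = LABEL_GM

    # ellipsoidal "white matter" blobs with random 3D orientations:
    # real anatomy runs obliquely through the sectioning direction, so
    # blob cross-sections drift and deform from slice to slice
    for _ in range(spec.n_blobs):
        c = np.array([cz, cy, cx]) + (rng.uniform(-0.64 * f, 0.64 * f, 3)) * np.array(
            [ez, ey, ex]
        )
        radii = rng.uniform(*spec.blob_size_range, 3) * np.array(
            [min(ez, ey, ex) * f / 0.7] * 3
        ) * np.asarray(spec.blob_aspect, dtype=float)
        # random 3D rotation from a QR decomposition of a Gaussian matrix
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        d = np.stack([Z - c[0], Y - c[1], Xc - c[2]])  # (3, nz, ny, nx)
        dr = np.einsum("ij,jklm->iklm", Q, d)
        b = (
            (dr[0] / radii[0]) ** 2
            + (dr[1] / radii[1]) ** 2
            + (dr[2] / radii[2]) ** 2
        ) <= 1.0
        labels[b & specimen] = LABEL_WM

    rod_axis = None
    if spec.rod is not None:
        d = np.asarray(spec.rod["direction"], dtype=float)  # (x, y, z)
        d = d / np.linalg.norm(d)
        # axis point: volume centre plus an optional (x, y, z) µm offset —
        # off-centre rods feel accumulated rotation drift, centred ones
        # only translation drift
        p0 = np.array([cx, cy, cz]) + np.asarray(
            spec.rod.get("offset", (0.0, 0.0, 0.0)), dtype=float
        )
        radius = float(spec.rod["radius"])
        # perpendicular distance of every voxel centre from the axis
        Px, Py, Pz = X - p0[0], Y - p0[1], Z - p0[2]
        proj = Px * d[0] + Py * d[1] + Pz * d[2]
        dist2 = (
            (Px - proj * d[0]) ** 2
            + (Py - proj * d[1]) ** 2
            + (Pz - proj * d[2]) ** 2
        )
        rod = (dist2 <= radius**2) & specimen
        labels[rod] = LABEL_ROD
        rod_axis = (p0, d)

    levels = dict(
        zip(
            (LABEL_BACKGROUND, LABEL_FORMALIN, LABEL_GM, LABEL_WM),
            spec.tissue_levels,
        )
    )
    vol = np.zeros(spec.grid_dims, dtype=float)
    for lab, lev in levels.items():
        vol[labels == lab] = lev
    if spec.rod is not None:
        vol[labels == LABEL_ROD] = float(
            spec.rod.get("intensity", max(spec.tissue_levels) * 1.2)
        )
    # stained tissue is textured at the cellular scale; modulate the
    # tissue compartments with smooth 3D noise so in-plane structure is
    # dense (and consistent between adjacent sections)
    if spec.texture_amplitude > 0:
        ts = np.broadcast_to(np.asarray(spec.texture_scale, dtype=float), (3,))
        sig = [t / v for t, v in zip(ts, spec.voxel_size)]
        tex = ndimage.gaussian_filter(rng.standard_normal(spec.grid_dims), sig)
        tex = tex / max(np.abs(tex).max(), 1e-12)
        tissue = labels >= LABEL_GM
        vol = np.where(tissue, vol * (1.0 + spec.texture_amplitude * tex), vol)
    # light smoothing for realistic partial-volume gradients (labels stay crisp)
    vol = ndimage.gaussian_filter(vol, sigma=0.6)
    return (
        Volume3D(data=vol, voxel_size=spec.voxel_size),
        Volume3D(data=labels, voxel_size=spec.voxel_size),
        rod_axis,
    )


def histology_contrast(
    volume: Volume3D, labels: Volume3D, keep=(LABEL_GM, LABEL_WM, LABEL_ROD)
) -> Volume3D:
    """Specimen-only contrast for cutting virtual histology sections.

    A stained section holds extracted tissue on a scanner background;
    the formalin compartment exists only in the MR images of the fixated
    specimen.  This zeroes every non-tissue compartment so sections cut
    from the result have the background statistics of a flat-bed scan.
    """
    m = np.isin(np.asarray(labels.data), keep)
    return volume.with_data(np.where(m, np.asarray(volume.data, dtype=float), 0.0))


def rod_indicator(
    like: Volume3D,
    axis: tuple[np.ndarray, np.ndarray],
    radius: float,
    edge: Optional[float] = None,
) -> Volume3D:
    """Anti-aliased soft rod mask on the grid of ``like``.

    ``axis`` is ``(point, unit_direction)`` in physical (x, y, z) µm as
    returned by ``make_phantom``.  Voxels ramp linearly from 1 inside to
    0 outside across an ``edge``-wide band (default: one in-plane voxel),
    which keeps per-slice centroids sub-voxel accurate — use this, not
    the binary label, when measuring rod straightness after resampling.
    """
    p0, d = np.asarray(axis[0], dtype=float), np.asarray(axis[1], dtype=float)
    if edge is None:
        edge = float(min(like.voxel_size[1:]))
    Z, Y, X = _phys_grids(like.shape, like.voxel_size)
    Z = Z + like.origin[0]
    Y = Y + like.origin[1]
    X = X + like.origin[2]
    Px, Py, Pz = X - p0[0], Y - p0[1], Z - p0[2]
    proj = Px * d[0] + Py * d[1] + Pz * d[2]
    dist = np.sqrt(
        (Px - proj * d[0]) ** 2
        + (Py - proj * d[1]) ** 2
        + (Pz - proj * d[2]) ** 2
    )
    soft = np.clip((radius + edge / 2 - dist) / edge, 0.0, 1.0)
    return Volume3D(data=soft, voxel_size=like.voxel_size, origin=like.origin)


def mr_acquisition(
    volume: Volume3D, psf_um: tuple[float, float, float] = (160.0, 120.0, 120.0)
) -> Volume3D:
    """Emulate the resolution of an MR acquisition of the phantom.

    An MR image is the specimen convolved with the acquisition
    point-spread function, so sub-voxel cellular texture is averaged
    away while macrostructure survives; the returned volume is the
    phantom blurred with a Gaussian PSF of the given FWHM-like scale
    (µm, (z, y, x)).  Use this — not the raw phantom — as the guiding
    reference so plane reslicing behaves like real MR data.
    """
    sig = [p / v for p, v in zip(psf_um, volume.voxel_size)]
    return volume.with_data(
        ndimage.gaussian_filter(np.asarray(volume.data, dtype=float), sigma=sig)
    )


def virtual_section(
    volume: Volume3D,
    thickness: float,
    keep_every: int = 1,
    axis: int = 0,
    nearest: bool = False,
) -> tuple[SectionSeries, np.ndarray]:
    """Cut a volume into virtual sections and keep every k-th.

    ``thickness`` (µm) must be an integer multiple of the voxel size
    along the sectioning axis; a section averages the planes inside its
    slab (``nearest`` keeps label volumes crisp by taking the first plane
    instead).  With keep_every=10 and 20 µm sections, the retained
    spacing is the 200 µm scheme of every-10th-section staining.
    Returns the series and the physical z positions of retained sections.
    """
    if axis != 0:
        data = np.moveaxis(volume.data, axis, 0)
        vs = list(volume.voxel_size)
        vs.insert(0, vs.pop(axis))
        volume = Volume3D(data=data, voxel_size=tuple(vs))
    sz, sy, sx = volume.voxel_size
    m = thickness / sz
    if abs(m - round(m)) > 1e-9:
        raise ValueError("thickness must be an integer multiple of the voxel size")
    m = int(round(m))
    if keep_every < 1:
        raise ValueError("keep_every must be >= 1")
    nz = volume.shape[0]
    step = keep_every * m
    n_sections = nz // step
    if n_sections < 1:
        raise ValueError("axis extent smaller than one section")
    sections, zs = [], []
    for i in range(n_sections):
        j = i * step
        slab = volume.data[j : j + m]
        pix = slab[0] if (nearest or m == 1) else slab.mean(axis=0)
        z = volume.origin[0] + j * sz
        sections.append(
            Section2D(
                pixels=np.asarray(pix),
                pixel_size=(sy, sx),
                index=i,
                z=z,
                origin=(volume.origin[2], volume.origin[1]),
            )
        )
        zs.append(z)
    series = SectionSeries(sections=sections, spacing=keep_every * thickness)
    return series, np.asarray(zs)


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------


def _bandlimited_field(shape, pixel_size, amplitude, wavelength, rng):
    """Smooth random displacement field with max |u| = amplitude (µm)."""
    h, w = shape
    sy, sx = pixel_size
    if wavelength <= 4 * max(sy, sx):
        raise ValueError("deform_wavelength must exceed 4x the in-plane pixel size")
    sigma_px = wavelength / (2 * np.pi) / np.array([sy, sx])
    disp = np.empty((2, h, w))
    for c in range(2):
        noise = rng.standard_normal((h, w))
        f = ndimage.gaussian_filter(noise, sigma=sigma_px)
        disp[c] = f
    peak = np.max(np.abs(disp))
    if peak > 0:
        disp *= amplitude / peak
    return disp


def corrupt_sections(
    series: SectionSeries, cspec: CorruptionSpec
) -> tuple[SectionSeries, PhantomTruth]:
    """Independently perturb each section, recording everything applied.

    Per section: a rigid transform drawn uniformly within the spec's
    ranges (cumulative when ``random_walk``), an optional band-limited
    smooth deformation, gain/gamma intensity distortion, then Gaussian
    noise.  Deterministic per seed.  A zero-range spec yields identity
    corruption.
    """
    rng = np.random.default_rng(cspec.seed)
    rigids, fields, gains = [], [], []
    out = []
    walk = np.zeros(2)
    i_max = max(
        (float(np.max(s.pixels)) for s in series if np.max(s.pixels) > 0),
        default=1.0,
    )
    for s in series:
        theta = rng.uniform(-cspec.max_rotation, cspec.max_rotation)
        t = rng.uniform(-cspec.max_translation, cspec.max_translation, 2)
        if cspec.random_walk:
            walk = walk + t
            t = walk.copy()
        rig = RigidTransform2D(
            theta=theta, tx=float(t[0]), ty=float(t[1]), center=s.phys_center()
        )
        chain = rig
        fld = None
        if cspec.deform_amplitude > 0:
            disp = _bandlimited_field(
                s.shape, s.pixel_size, cspec.deform_amplitude,
                cspec.deform_wavelength, rng,
            )
            fld = DeformationField2D(
                displacement=disp, pixel_size=s.pixel_size, origin=s.origin
            )
            chain = compose(rig, fld)
        g = rng.uniform(*cspec.gain_range)
        gam = rng.uniform(*cspec.gamma_range)
        if chain is rig and rig.is_identity():
            pix = np.asarray(s.pixels, dtype=float)
            warped = s.with_pixels(pix)
        else:
            # cubic sampling: the corrupted section stands in for a
            # physically misplaced (lossless) section, so the synthesis
            # warp should degrade texture as little as possible
            warped = resample(s, chain, interpolation="cubic")
        pix = np.asarray(warped.pixels, dtype=float)
        if g != 1.0 or gam != 1.0:
            pix = g * np.power(np.clip(pix, 0, None) / i_max, gam) * i_max
        if cspec.noise_sd > 0:
            pix = pix + rng.normal(0.0, cspec.noise_sd, pix.shape)
        out.append(warped.with_pixels(pix))
        rigids.append(rig)
        fields.append(fld)
        gains.append((g, gam))
    truth = PhantomTruth(
        per_section_rigid=rigids,
        per_section_field=fields,
        per_section_gain_gamma=gains,
    )
    return SectionSeries(out, spacing=series.spacing, anchor=series.anchor), truth


# ---------------------------------------------------------------------------
# MR-style corruptions
# ---------------------------------------------------------------------------


def add_bias_hotspot(
    volume: Volume3D,
    center: Sequence[float],
    fwhm_mm: float,
    peak_gain: float,
) -> tuple[Volume3D, Volume3D]:
    """Multiply a volume by a Gaussian intensity "hotspot".

    The bias bump is 1 far from ``center`` (physical (x, y, z) µm) and
    ``peak_gain`` at it, with the stated FWHM (mm).  Returns the biased
    volume and the bias field itself for oracle use.
    """
    if peak_gain <= 0 or fwhm_mm <= 0:
        raise ValueError("peak_gain and fwhm must be positive")
    fwhm = fwhm_mm * 1000.0
    Z, Y, X = _phys_grids(volume.shape, volume.voxel_size)
    cx, cy, cz = center
    r2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
    bump = np.exp(-4.0 * np.log(2.0) * r2 / fwhm**2)
    bias = 1.0 + (peak_gain - 1.0) * bump
    return (
        Volume3D(
            data=np.asarray(volume.data, dtype=float) * bias,
            voxel_size=volume.voxel_size,
            origin=volume.origin,
        ),
        Volume3D(data=bias, voxel_size=volume.voxel_size, origin=volume.origin),
    )


#: relative strength of the fixed inter-channel noise coupling used by
#: simulate_coils; receive arrays are never noise-independent in practice,
#: which is precisely why eigenvector coil combination whitens by the
#: noise covariance before weighting
DEFAULT_NOISE_COUPLING = 0.5


def simulate_coils(
    volume: Volume3D,
    C: int,
    profile_scale_mm: float = 15.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    noise_coupling: float = DEFAULT_NOISE_COUPLING,
) -> CoilData:
    """Simulate a C-channel receive array over a volume.

    Channel ``c`` is ``s_c * volume + noise`` with smooth complex
    sensitivities: Gaussian magnitude profiles of scale
    ``profile_scale_mm`` centred at points spread around the volume
    surface, and mild random linear phase ramps.  Channel noise is
    complex Gaussian of marginal sd ``noise_sd`` with inter-channel
    correlation induced by a fixed random coupling matrix of relative
    strength ``noise_coupling``.  ``C = 1`` uses a uniform unit
    sensitivity.  Deterministic per seed.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    rng = np.random.default_rng(seed)
    nz, ny, nx = volume.shape
    Z, Y, X = _phys_grids(volume.shape, volume.voxel_size)
    cx, cy, cz = volume.phys_center()
    extent = np.array(
        [
            (nx - 1) * volume.voxel_size[2],
            (ny - 1) * volume.voxel_size[1],
            (nz - 1) * volume.voxel_size[0],
        ]
    )
    sens = np.empty((C, nz, ny, nx), dtype=complex)
    if C == 1:
        sens[0] = 1.0
    else:
        scale = profile_scale_mm * 1000.0
        # Fibonacci spiral of channel centres on the bounding ellipsoid
        ga = np.pi * (3.0 - np.sqrt(5.0))
        for c in range(C):
            u = (c + 0.5) / C
            phi = np.arccos(1 - 2 * u)
            th = ga * c
            n = np.array(
                [np.sin(phi) * np.cos(th), np.sin(phi) * np.sin(th), np.cos(phi)]
            )
            ctr = np.array([cx, cy, cz]) + 0.55 * extent * n
            r2 = (X - ctr[0]) ** 2 + (Y - ctr[1]) ** 2 + (Z - ctr[2]) ** 2
            mag = np.exp(-r2 / (2 * scale**2))
            k = rng.normal(0, 0.5 / scale, 3)
            phase = k[0] * (X - cx) + k[1] * (Y - cy) + k[2] * (Z - cz)
            phase = phase + rng.uniform(0, 2 * np.pi)
            sens[c] = mag * np.exp(1j * phase)
    channels = sens * np.asarray(volume.data, dtype=float)[None]
    if noise_sd > 0:
        # neighbour-ring coupling: adjacent elements of a receive array
        # share substantial noise (inductive coupling), distant ones do not
        L = np.eye(C, dtype=complex)
        if C > 1:
            for c in range(C):
                L[c, (c + 1) % C] += noise_coupling * np.exp(
                    1j * rng.uniform(0, 2 * np.pi)
                )
                L[c, (c - 1) % C] += noise_coupling * np.exp(
                    1j * rng.uniform(0, 2 * np.pi)
                )
        # normalize rows so each channel keeps marginal sd = noise_sd
        L = L / np.linalg.norm(L, axis=1, keepdims=True)
        g = (
            rng.standard_normal((C, nz * ny * nx))
            + 1j * rng.standard_normal((C, nz * ny * nx))
        ) * (noise_sd / np.sqrt(2.0))
        channels = channels + (L @ g).reshape(C, nz, ny, nx)
    return CoilData(
        channels=channels,
        voxel_size=volume.voxel_size,
        noise_sd=np.full(C, float(noise_sd)),
        sensitivities=sens,
    )
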