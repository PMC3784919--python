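"""Readers/writers for every artifact the pipeline touches.

Volumes travel as NIfTI-1 (voxel sizes stored as mm pixdims; the package
works in µm internally).  Sections travel as 8/16-bit PNG or TIFF next
to a CSV manifest carrying the physical metadata a flat-bed scan has no
header for.  Transforms serialize as small structured text files;
deformation fields as 2-channel NIfTI.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .core import Section2D, SectionSeries, Volume3D
from .transforms import AffineTransform3D, DeformationField2D, RigidTransform2D

__all__ = [
    "RunConfig",
    "load_transform",
    "read_series",
    "read_volume",
    "save_transform",
    "write_report",
    "write_series",
    "write_volume",
]

MANIFEST_COLUMNS = ["filename", "index", "z_um", "pixel_size_y_um", "pixel_size_x_um"]


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


def write_volume(volume: Volume3D, path: Union[str, Path]) -> Path:
    """Write a volume as NIfTI-1; µm voxel sizes become mm pixdims."""
    path = Path(path)
    sz, sy, sx = volume.voxel_size
    oz, oy, ox = volume.origin
    aff = np.diag([sx / 1000.0, sy / 1000.0, sz / 1000.0, 1.0])
    aff[:3, 3] = [ox / 1000.0, oy / 1000.0, oz / 1000.0]
    # internal (z, y, x) -> on-disk (x, y, z)
    img = nib.Nifti1Image(np.asarray(volume.data).T, aff)
    img.header.set_xyzt_units(xyz="mm")
    nib.save(img, str(path))
    return path


def read_volume(path: Union[str, Path]) -> Volume3D:
    """Read a NIfTI-1 volume; mm pixdims become µm voxel sizes."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError("invalid (non-positive) pixdim in NIfTI header")
    origin = img.affine[:3, 3]
    return Volume3D(
        data=np.asarray(data).T,
        voxel_size=(zooms[2] * 1000.0, zooms[1] * 1000.0, zooms[0] * 1000.0),
        origin=(origin[2] * 1000.0, origin[1] * 1000.0, origin[0] * 1000.0),
    )


# ---------------------------------------------------------------------------
# section series
# ---------------------------------------------------------------------------


def write_series(
    series: SectionSeries, out_dir: Union[str, Path], prefix: str = "section"
) -> Path:
    """Write sections as PNG (8/16-bit as appropriate) plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in series:
        fname = f"{prefix}_{s.index:04d}.png"
        pix = np.asarray(s.pixels)
        if np.issubdtype(pix.dtype, np.integer):
            img = pix.astype(np.uint16 if pix.max() > 255 else np.uint8)
        else:
            lo, hi = float(pix.min()), float(pix.max())
            scale = 65535.0 / (hi - lo) if hi > lo else 0.0
            img = ((pix - lo) * scale).astype(np.uint16)
        iio.imwrite(out_dir / fname, img)
        rows.append(
            dict(
                filename=fname,
                index=s.index,
                z_um=s.z,
                pixel_size_y_um=s.pixel_size[0],
                pixel_size_x_um=s.pixel_size[1],
            )
        )
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.attrs["spacing_um"] = series.spacing
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w") as fh:
        fh.write(f"# spacing_um={series.spacing}\n")
        df.to_csv(fh, index=False)
    return manifest


def read_series(manifest_path: Union[str, Path]) -> SectionSeries:
    """Load a section series from a manifest CSV.

    Errors name the offending row for missing files, duplicate indices
    or inconsistent pixel sizes.
    """
    manifest_path = Path(manifest_path)
    spacing = None
    with open(manifest_path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        for tok in first[1:].strip().split():
            if tok.startswith("spacing_um="):
                spacing = float(tok.split("=", 1)[1])
    df = pd.read_csv(manifest_path, skiprows=skip)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if df["index"].duplicated().any():
        dup = df.loc[df["index"].duplicated(), "filename"].iloc[0]
        raise ValueError(f"duplicate section index at row for '{dup}'")
    df = df.sort_values("index").reset_index(drop=True)
    ps = df[["pixel_size_y_um", "pixel_size_x_um"]].to_numpy()
    if not np.allclose(ps, ps[0]):
        bad = int(np.argmax(np.any(~np.isclose(ps, ps[0]), axis=1)))
        raise ValueError(
            f"inconsistent pixel sizes at row for '{df['filename'][bad]}'"
        )
    sections = []
    for _, row in df.iterrows():
        p = manifest_path.parent / str(row["filename"])
        if not p.exists():
            raise FileNotFoundError(f"section file missing: '{row['filename']}'")
        pix = iio.imread(p)
        sections.append(
            Section2D(
                pixels=pix,
                pixel_size=(row["pixel_size_y_um"], row["pixel_size_x_um"]),
                index=int(row["index"]),
                z=float(row["z_um"]),
            )
        )
    if spacing is None:
        zs = df["z_um"].to_numpy(dtype=float)
        spacing = float(np.diff(zs).mean()) if len(zs) > 1 else 1.0
    return SectionSeries(sections=sections, spacing=spacing)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def save_transform(t, path: Union[str, Path]) -> Path:
    """Serialize a transform as structured text (µm / degrees).

    Deformation fields go to a sibling 2-channel NIfTI referenced from
    the text file.
    """
    path = Path(path)
    if isinstance(t, RigidTransform2D):
        payload = dict(
            type="rigid2d", theta_deg=t.theta, tx_um=t.tx, ty_um=t.ty,
            center_um=list(t.center),
        )
    elif isinstance(t, AffineTransform3D):
        payload = dict(
            type="affine3d",
            linear=t.linear.tolist(),
            offset_um=t.offset.tolist(),
        )
    elif isinstance(t, DeformationField2D):
        nii = path.with_suffix(".field.nii")
        h, w = t.shape
        arr = np.moveaxis(t.displacement, 0, -1)[None]  # (1, H, W, 2)
        sy, sx = t.pixel_size
        aff = np.diag([sx / 1000.0, sy / 1000.0, 1.0, 1.0])
        aff[:2, 3] = [t.origin[0] / 1000.0, t.origin[1] / 1000.0]
        nib.save(nib.Nifti1Image(np.transpose(arr, (2, 1, 0, 3)), aff), str(nii))
        payload = dict(
            type="field2d",
            field_file=nii.name,
            pixel_size_um=list(t.pixel_size),
            origin_um=list(t.origin),
        )
    else:
        raise TypeError(f"cannot serialize {type(t).__name__}")
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_transform(path: Union[str, Path]):
    path = Path(path)
    payload = json.loads(path.read_text())
    kind = payload["type"]
    if kind == "rigid2d":
        return RigidTransform2D(
            theta=payload["theta_deg"],
            tx=payload["tx_um"],
            ty=payload["ty_um"],
            center=tuple(payload["center_um"]),
        )
    if kind == "affine3d":
        return AffineTransform3D(
            linear=np.asarray(payload["linear"]),
            offset=np.asarray(payload["offset_um"]),
        )
    if kind == "field2d":
        img = nib.load(str(path.parent / payload["field_file"]))
        arr = np.asanyarray(img.dataobj)  # (W, H, 1, 2)
        disp = np.moveaxis(np.transpose(arr, (2, 1, 0, 3))[0], -1, 0)
        return DeformationField2D(
            displacement=disp,
            pixel_size=tuple(payload["pixel_size_um"]),
            origin=tuple(payload["origin_um"]),
        )
    raise ValueError(f"unknown transform type '{kind}'")


# ---------------------------------------------------------------------------
# run configuration and reports
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run; every field has a
    default and the object round-trips losslessly through JSON."""

    downsample_factor: int = 2
    erode_radius: int = 2
    dilate_radius: int = 2
    min_component_fraction: float = 0.05
    histogram_reference: Optional[int] = None
    bias_fwhm_mm: float = 5.0
    max_passes: int = 4
    refine_tol: float = 1e-3
    refine_max_iter: int = 10
    gate_margin: float = 0.0
    majority_threshold: float = 0.5
    nonlinear: bool = True
    control_spacing_um: Optional[float] = None
    seed: int = 0
    out_dir: str = "histostack_out"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def write_report(result, out_dir: Union[str, Path], config: Optional[RunConfig] = None):
    """Write the reconstruction report: iteration NMI trace (CSV),
    per-section transforms and gate decisions, config snapshot, volume."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        dict(iteration=np.arange(1, len(result.nmi_trace) + 1), nmi=result.nmi_trace)
    ).to_csv(out_dir / "nmi_trace.csv", index=False)
    gate_rows = []
    tdir = out_dir / "transforms"
    tdir.mkdir(exist_ok=True)
    for i, (rigid, fld, accepted) in enumerate(result.per_section):
        save_transform(rigid, tdir / f"section_{i:04d}_rigid.json")
        if fld is not None:
            save_transform(fld, tdir / f"section_{i:04d}_field.json")
        gate_rows.append(dict(section=i, nonlinear_accepted=bool(accepted)))
    pd.DataFrame(gate_rows).to_csv(out_dir / "gates.csv", index=False)
    if result.affine_mr_to_stack is not None:
        save_transform(result.affine_mr_to_stack, out_dir / "affine_mr_to_stack.json")
    if config is not None:
        (out_dir / "config.json").write_text(config.to_json())
    write_volume(result.volume, out_dir / "reconstruction.nii")
    meta = dict(
        iterations=result.iterations,
        affine_only=bool(result.affine_only),
        final_nmi=result.nmi_trace[-1] if result.nmi_trace else None,
    )
    (out_dir / "summary.json").write_text(json.dumps(meta, indent=1))
    return out_dir
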