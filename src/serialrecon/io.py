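"""File IO: NIfTI volumes and fields, numbered section images, landmarks, transforms.

Pixel sizes stored in file headers are authoritative.  Volumes are stored
with the array axis order ``(ML, AP, DV)`` and an affine of the form
``diag(spacing) @ index + origin`` — no axis flips are introduced, so a
round trip preserves both geometry and data layout.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import (
    AffineTransform3D,
    DisplacementField,
    LandmarkSet,
    RigidTransform2D,
    SectionSeries,
    Volume3D,
)

__all__ = [
    "save_volume",
    "load_volume",
    "save_field",
    "load_field",
    "save_section_series",
    "load_section_series",
    "save_landmarks",
    "load_landmarks",
    "save_rigid_series",
    "load_rigid_series",
    "save_affine",
    "load_affine",
]


def _affine_from_geometry(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_volume(volume: Volume3D, path) -> None:
    img = nib.Nifti1Image(
        np.asarray(volume.values, dtype=np.float32),
        _affine_from_geometry(volume.spacing, volume.origin),
    )
    img.header.set_zooms(tuple(volume.spacing) + ((1.0,) if volume.values.ndim == 4 else ()))
    nib.save(img, str(path))


def load_volume(path) -> Volume3D:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    aff = img.affine
    spacing = np.abs(np.diag(aff)[:3])
    origin = aff[:3, 3]
    return Volume3D(data, spacing, origin)


def save_field(field: DisplacementField, path) -> None:
    """Vector-valued NIfTI, one component per spatial axis, in mm."""
    aff = np.eye(4)
    aff[: field.ndim, : field.ndim] = np.diag(field.spacing)
    aff[: field.ndim, 3] = field.origin
    img = nib.Nifti1Image(np.asarray(field.vectors, dtype=np.float32), aff)
    nib.save(img, str(path))


def load_field(path) -> DisplacementField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    ndim = data.shape[-1]
    aff = img.affine
    return DisplacementField(data, np.abs(np.diag(aff)[:ndim]), aff[:ndim, 3])


def save_section_series(series: SectionSeries, directory, fmt: str = "tiff") -> None:
    """Numbered image files plus a JSON geometry sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt == "tiff":
        import tifffile

        for i, sec in enumerate(series.sections):
            tifffile.imwrite(directory / f"section_{i:04d}.tif", np.asarray(sec, dtype=np.float32))
    elif fmt == "png":
        import imageio.v3 as iio

        for i, sec in enumerate(series.sections):
            arr = np.asarray(sec)
            lo, hi = arr.min(), arr.max()
            scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
            iio.imwrite(
                directory / f"section_{i:04d}.png",
                (scaled * 65535).astype(np.uint16),
            )
    else:
        raise ValueError("fmt must be 'tiff' or 'png'")
    sidecar = {
        "pixel_size_mm": series.pixel_size,
        "thickness_mm": series.thickness,
        "interleave": series.interleave,
        "parity": series.parity,
        "qc_flags": [bool(f) for f in series.qc_flags],
        "format": fmt,
    }
    (directory / "series.json").write_text(json.dumps(sidecar, indent=2))


def load_section_series(directory) -> SectionSeries:
    directory = Path(directory)
    sidecar = json.loads((directory / "series.json").read_text())
    fmt = sidecar.get("format", "tiff")
    ext = {"tiff": ".tif", "png": ".png"}[fmt]
    paths = sorted(directory.glob(f"section_*{ext}"))
    if fmt == "tiff":
        import tifffile

        sections = [tifffile.imread(p).astype(float) for p in paths]
    else:
        import imageio.v3 as iio

        sections = [np.asarray(iio.imread(p), dtype=float) for p in paths]
    return SectionSeries(
        sections,
        pixel_size=sidecar["pixel_size_mm"],
        thickness=sidecar["thickness_mm"],
        interleave=sidecar["interleave"],
        parity=sidecar["parity"],
        qc_flags=sidecar["qc_flags"],
    )


def save_landmarks(landmarks: LandmarkSet, path) -> None:
    df = pd.DataFrame(
        {
            "name": landmarks.names,
            "x_mm": landmarks.coords[:, 0],
            "y_mm": landmarks.coords[:, 1],
            "z_mm": landmarks.coords[:, 2],
        }
    )
    df.to_csv(path, index=False)


def load_landmarks(path) -> LandmarkSet:
    df = pd.read_csv(path)
    return LandmarkSet(
        list(df["name"].astype(str)),
        df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
    )


def _rigid_to_dict(T: RigidTransform2D) -> dict:
    return {
        "type": "rigid2d",
        "theta_rad": float(T.theta),
        "t_mm": [float(v) for v in T.t],
        "center_mm": [float(v) for v in T.center],
    }


def _rigid_from_dict(d: dict) -> RigidTransform2D:
    return RigidTransform2D(d["theta_rad"], np.asarray(d["t_mm"]), np.asarray(d["center_mm"]))


def save_rigid_series(transforms, path, reference_index: int = 0) -> None:
    payload = {
        "type": "rigid2d_series",
        "reference_index": int(reference_index),
        "transforms": [_rigid_to_dict(T) for T in transforms],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_rigid_series(path):
    payload = json.loads(Path(path).read_text())
    transforms = [_rigid_from_dict(d) for d in payload["transforms"]]
    return transforms, payload.get("reference_index", 0)


def save_affine(T: AffineTransform3D, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "type": "affine3d",
                "matrix": T.linear.tolist(),
                "translation": T.translation.tolist(),
            },
            indent=2,
        )
    )


def load_affine(path) -> AffineTransform3D:
    d = json.loads(Path(path).read_text())
    return AffineTransform3D(np.asarray(d["matrix"]), np.asarray(d["translation"]))
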