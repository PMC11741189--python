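"""Reading and writing the pipeline's on-disk formats.

Images are single-plane grayscale TIFF (8- or 16-bit unsigned, or 32-float);
masks are written as 8-bit TIFF with foreground 255.  Tables are plain CSV.
Distinct exception types separate unreadable files, non-grayscale content
and shape mismatches so a batch runner can report them differently.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imageops import BinaryMask, ImagePlane
from .nuclei import Nucleus, NucleusSet

__all__ = [
    "FieldIOError",
    "UnreadableFileError",
    "NotGrayscaleError",
    "ShapeMismatchError",
    "read_plane",
    "load_field",
    "save_plane",
    "save_mask",
    "nuclei_to_dataframe",
    "nuclei_from_dataframe",
]


class FieldIOError(Exception):
    """Base class for field input problems."""


class UnreadableFileError(FieldIOError):
    """File missing or not parseable as TIFF."""


class NotGrayscaleError(FieldIOError):
    """File is multi-plane or has a color/sample axis."""


class ShapeMismatchError(FieldIOError):
    """Paired channels disagree in shape."""


_BIT_DEPTH = {np.uint8: 8, np.uint16: 16}


def read_plane(path: str | Path, pixel_size: float) -> ImagePlane:
    """Read one single-plane grayscale TIFF with calibration attached."""
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise UnreadableFileError(f"cannot read {path}: {exc}") from exc
    if data.ndim != 2:
        raise NotGrayscaleError(
            f"{path}: expected single-plane grayscale, got array of shape {data.shape}"
        )
    bit_depth = _BIT_DEPTH.get(data.dtype.type, 32)
    return ImagePlane(data.astype(np.float64), bit_depth, pixel_size)


def load_field(
    dapi_path: str | Path, bodipy_path: str | Path, pixel_size: float
) -> tuple[ImagePlane, ImagePlane]:
    """Load a paired DAPI/BODIPY field, enforcing equal shapes."""
    dapi = read_plane(dapi_path, pixel_size)
    bodipy = read_plane(bodipy_path, pixel_size)
    if dapi.shape != bodipy.shape:
        raise ShapeMismatchError(
            f"channel shapes differ: {dapi_path} is {dapi.shape}, {bodipy_path} is {bodipy.shape}"
        )
    return dapi, bodipy


def save_plane(path: str | Path, img: ImagePlane) -> None:
    dtype = {8: np.uint8, 16: np.uint16}.get(img.bit_depth, np.float32)
    tifffile.imwrite(Path(path), img.pixels.astype(dtype))


def save_mask(path: str | Path, mask: BinaryMask) -> None:
    tifffile.imwrite(Path(path), (mask.pixels.astype(np.uint8) * 255))


def nuclei_to_dataframe(nuclei: NucleusSet) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "field_id": nuclei.field_id,
            "nucleus_id": range(nuclei.count),
            "row": [n.centroid[0] for n in nuclei.nuclei],
            "col": [n.centroid[1] for n in nuclei.nuclei],
            "est_radius_um": [n.est_radius_um for n in nuclei.nuclei],
        }
    )


def nuclei_from_dataframe(
    df: pd.DataFrame, shape: tuple[int, int], pixel_size: float
) -> NucleusSet:
    field_id = str(df["field_id"].iloc[0]) if len(df) else ""
    nuclei = [
        Nucleus((float(r.row), float(r.col)), float(r.est_radius_um)) for r in df.itertuples()
    ]
    return NucleusSet(nuclei, field_id, shape, pixel_size)
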