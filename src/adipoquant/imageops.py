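"""Low-level grayscale image primitives shared by the two segmentation pipelines.

Each primitive corresponds to one named step of an interactive image-analysis
workflow: flat background offset subtraction, rolling-ball background
correction, Gaussian low-pass filtering, image subtraction, manual
thresholding, and particle (connected-component) analysis.

Conventions
-----------
* Pixel data are stored as ``float64`` regardless of the declared bit depth;
  ``bit_depth`` records the intensity semantics (8- and 16-bit planes must
  stay within ``[0, 2**bit_depth - 1]``; 32 means unbounded float, which may
  be negative after image subtraction).
* Thresholding keeps the lower bound: foreground is ``pixels >= t``.
* Particle perimeters use the Crofton estimator so that the circularity
  ``4*pi*area / perimeter**2`` of a rasterized disk approaches 1; circularity
  is clipped to ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.morphology import disk as _disk_footprint
from skimage.morphology import opening as _grey_opening

__all__ = [
    "ImagePlane",
    "BinaryMask",
    "Particle",
    "ParticleTable",
    "subtract_constant",
    "subtract_rolling_ball",
    "gaussian_blur",
    "subtract_images",
    "apply_threshold",
    "connected_particles",
]

BitDepth = Literal[8, 16, 32]


@dataclass
class ImagePlane:
    """One 2-D grayscale channel with bit-depth semantics and spatial calibration.

    Parameters
    ----------
    pixels
        2-D array of intensities; stored as float64.
    bit_depth
        8, 16 (bounded integer-like intensities) or 32 (signed float plane).
    pixel_size
        Physical calibration in micrometres per pixel (> 0).
    """

    pixels: np.ndarray
    bit_depth: BitDepth = 16
    pixel_size: float = 0.31

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError(f"expected a 2-D plane, got shape {self.pixels.shape}")
        if self.bit_depth not in (8, 16, 32):
            raise ValueError(f"bit_depth must be 8, 16 or 32, got {self.bit_depth}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.bit_depth in (8, 16):
            lo, hi = self.pixels.min(), self.pixels.max()
            if lo < 0 or hi > 2**self.bit_depth - 1:
                raise ValueError(
                    f"{self.bit_depth}-bit plane holds intensities outside "
                    f"[0, {2**self.bit_depth - 1}]: range [{lo}, {hi}]"
                )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, bit_depth: BitDepth | None = None) -> "ImagePlane":
        """New plane with the same calibration but different pixel data."""
        return ImagePlane(pixels, bit_depth or self.bit_depth, self.pixel_size)


@dataclass
class BinaryMask:
    """Boolean foreground mask sharing the shape contract of its source plane."""

    pixels: np.ndarray
    pixel_size: float = 0.31

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D mask, got shape {self.pixels.shape}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Particle:
    """One connected component of a binary mask, with shape descriptors."""

    label: int
    area_px: int
    area_um2: float
    centroid: tuple[float, float]  # (row, col), pixels
    perimeter_px: float
    circularity: float
    equivalent_diameter_um: float


@dataclass
class ParticleTable:
    """Ordered list of particles from one mask, labels contiguous from 1."""

    particles: list[Particle] = field(default_factory=list)
    shape: tuple[int, int] = (0, 0)
    pixel_size: float = 0.31

    def __len__(self) -> int:
        return len(self.particles)

    def __iter__(self) -> Iterator[Particle]:
        return iter(self.particles)

    @property
    def areas_px(self) -> np.ndarray:
        return np.array([p.area_px for p in self.particles], dtype=int)

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([p.area_um2 for p in self.particles], dtype=float)

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of (row, col) centroids in pixel coordinates."""
        if not self.particles:
            return np.empty((0, 2))
        return np.array([p.centroid for p in self.particles], dtype=float)

    @property
    def circularities(self) -> np.ndarray:
        return np.array([p.circularity for p in self.particles], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [p.label for p in self.particles],
                "area_px": [p.area_px for p in self.particles],
                "area_um2": [p.area_um2 for p in self.particles],
                "equiv_diam_um": [p.equivalent_diameter_um for p in self.particles],
                "circularity": [p.circularity for p in self.particles],
                "row": [p.centroid[0] for p in self.particles],
                "col": [p.centroid[1] for p in self.particles],
                "perimeter_px": [p.perimeter_px for p in self.particles],
            }
        )


def subtract_constant(img: ImagePlane, value: float) -> ImagePlane:
    """Subtract a flat intensity offset, clamping the result at zero.

    ``out = max(img - value, 0)``; shape, calibration and bit depth are
    preserved.
    """
    if value < 0:
        raise ValueError(f"offset must be >= 0, got {value}")
    return img.with_pixels(np.maximum(img.pixels - value, 0.0))


def subtract_rolling_ball(img: ImagePlane, radius: int) -> ImagePlane:
    """Remove smooth background via grayscale opening with a disk element.

    The background estimate is the morphological opening of the image with a
    disk of the given radius (the rolling-ball convention for single-plane
    grayscale data); the result ``img - opening`` is non-negative and bounded
    by the input everywhere, and preserves features narrower than roughly
    twice the radius.

    The disk is applied through an exact "crosses" decomposition, which makes
    the opening fast for large radii without changing the result.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    footprint = _disk_footprint(int(radius), decomposition="crosses")
    background = _grey_opening(img.pixels, footprint)
    return img.with_pixels(img.pixels - background)


def gaussian_blur(img: ImagePlane, sigma: float) -> ImagePlane:
    """Isotropic Gaussian low-pass filter with reflective boundary handling.

    Reflection avoids the dark frame a zero-padded blur would introduce,
    which would otherwise create spurious difference-of-Gaussian foreground
    along the image border.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    blurred = ndimage.gaussian_filter(img.pixels, sigma=sigma, mode="reflect")
    return img.with_pixels(blurred)


def subtract_images(a: ImagePlane, b: ImagePlane) -> ImagePlane:
    """Signed elementwise difference ``a - b`` as a 32-float plane.

    Negative values are preserved (no clipping): the manual threshold that
    consumes this image decides foreground on the signed values.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.pixel_size != b.pixel_size:
        raise ValueError(f"pixel_size mismatch: {a.pixel_size} vs {b.pixel_size}")
    return ImagePlane(a.pixels - b.pixels, 32, a.pixel_size)


def apply_threshold(img: ImagePlane, t: float) -> BinaryMask:
    """Manual threshold: foreground is every pixel with intensity ``>= t``."""
    return BinaryMask(img.pixels >= t, img.pixel_size)


def _crofton_perimeter(labels: np.ndarray, index: np.ndarray) -> np.ndarray:
    # regionprops computes perimeter_crofton per region on its own bbox crop,
    # which matches the whole-image estimator because padding is implicit.
    return np.array([r.perimeter_crofton for r in measure.regionprops(labels)])


def connected_particles(mask: BinaryMask, connectivity: int = 8) -> ParticleTable:
    """Particle analysis: one record per connected foreground component.

    Parameters
    ----------
    mask
        Binary foreground mask.
    connectivity
        4 (edge-connected) or 8 (edge- or corner-connected, the de-facto
        default of interactive particle analyzers).
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    skimage_conn = 1 if connectivity == 4 else 2
    labels = measure.label(mask.pixels, connectivity=skimage_conn)
    table = ParticleTable([], mask.shape, mask.pixel_size)
    if labels.max() == 0:
        return table
    px = mask.pixel_size
    for region in measure.regionprops(labels):
        area_px = int(region.area)
        perim = float(region.perimeter_crofton)
        if perim > 0:
            circ = min(4.0 * np.pi * area_px / perim**2, 1.0)
        else:  # single pixel: Crofton perimeter can degenerate; treat as round
            circ = 1.0
        area_um2 = area_px * px**2
        table.particles.append(
            Particle(
                label=int(region.label),
                area_px=area_px,
                area_um2=area_um2,
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                perimeter_px=perim,
                circularity=float(circ),
                equivalent_diameter_um=2.0 * float(np.sqrt(area_um2 / np.pi)),
            )
        )
    return table
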