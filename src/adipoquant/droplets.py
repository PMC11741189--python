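"""Lipid-droplet segmentation in the BODIPY channel.

The pipeline runs a fixed sequence: cast to the 16-bit intensity scale,
rolling-ball background correction (radius 50 px) against hazy
autofluorescence, a duplicate-blur-subtract (difference-of-Gaussian)
enhancement with sigma 4 px, a manual threshold of 3 intensity units applied
to the signed 32-float difference image, binarization, and particle
analysis.  Touching droplets are not split: the workflow contains no
watershed step, so validation data keep a minimum droplet spacing.

The threshold lives on the difference image, whose scale is set by the
droplet amplitude rather than the source bit depth; 8-bit inputs are first
rescaled to the 16-bit range (x257) so the same default threshold applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imageops import (
    BinaryMask,
    ImagePlane,
    ParticleTable,
    apply_threshold,
    connected_particles,
    gaussian_blur,
    subtract_images,
    subtract_rolling_ball,
)

__all__ = ["DropletConfig", "DropletSegmentation", "MeanDropletSize", "segment_droplets", "mean_droplet_area"]


@dataclass
class DropletConfig:
    """Parameters of the droplet segmentation sequence.

    Attributes
    ----------
    rolling_ball_radius
        Disk radius (px) of the background opening.
    blur_sigma
        Gaussian sigma (px) of the duplicate-blur step.
    threshold
        Manual threshold (intensity units) on the 32-float difference image.
    connectivity
        4 or 8 for the particle analysis.
    min_area_px
        Minimum particle area kept (default 1 = no filtering).
    """

    rolling_ball_radius: int = 50
    blur_sigma: float = 4.0
    threshold: float = 3.0
    connectivity: int = 8
    min_area_px: int = 1

    def __post_init__(self) -> None:
        if self.rolling_ball_radius < 1:
            raise ValueError("rolling_ball_radius must be >= 1")
        if self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be > 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")


@dataclass
class DropletSegmentation:
    """Binary droplet mask plus its particle table for one field."""

    mask: BinaryMask
    particles: ParticleTable
    config_used: DropletConfig
    field_id: str = ""


def _to_16bit_scale(img: ImagePlane) -> ImagePlane:
    """Bring the plane to the 16-bit intensity range.

    8-bit planes are multiplied by 257 (255 -> 65535); 16-bit and float
    planes pass through unchanged.
    """
    if img.bit_depth == 8:
        return ImagePlane(img.pixels * 257.0, 16, img.pixel_size)
    return img


def segment_droplets(
    bodipy: ImagePlane, cfg: DropletConfig | None = None, field_id: str = ""
) -> DropletSegmentation:
    """Run the full droplet segmentation sequence on one BODIPY plane.

    Order: 16-bit cast -> rolling ball -> difference of Gaussians
    (corrected minus its blur, kept signed as 32-float) -> manual threshold
    -> connected-component particle analysis.  Deterministic.
    """
    cfg = cfg or DropletConfig()
    img16 = _to_16bit_scale(bodipy)
    corrected = subtract_rolling_ball(img16, cfg.rolling_ball_radius)
    blurred = gaussian_blur(corrected, cfg.blur_sigma)
    difference = subtract_images(corrected, blurred)
    mask = apply_threshold(difference, cfg.threshold)
    particles = connected_particles(mask, cfg.connectivity)
    if cfg.min_area_px > 1 and len(particles):
        kept = [p for p in particles if p.area_px >= cfg.min_area_px]
        # drop the filtered pixels from the mask and relabel contiguously
        from skimage import measure as _measure

        labels = _measure.label(mask.pixels, connectivity=1 if cfg.connectivity == 4 else 2)
        keep_labels = {p.label for p in kept}
        mask = BinaryMask(np.isin(labels, list(keep_labels)), mask.pixel_size)
        particles = connected_particles(mask, cfg.connectivity)
    return DropletSegmentation(mask, particles, cfg, field_id)


@dataclass(frozen=True)
class MeanDropletSize:
    """Field-level droplet size summary.

    ``n = 0`` flags a field with no particles; the means are then NaN rather
    than zero so empty fields cannot silently drag a condition average down.
    """

    mean_area_um2: float
    mean_equiv_diam_um: float
    n: int

    @property
    def has_particles(self) -> bool:
        return self.n > 0


def mean_droplet_area(seg: DropletSegmentation) -> MeanDropletSize:
    """Arithmetic mean particle area (and equivalent diameter) for a field."""
    n = len(seg.particles)
    if n == 0:
        return MeanDropletSize(float("nan"), float("nan"), 0)
    areas = seg.particles.areas_um2
    diams = np.array([p.equivalent_diameter_um for p in seg.particles])
    return MeanDropletSize(float(areas.mean()), float(diams.mean()), n)
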