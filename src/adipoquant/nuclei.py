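"""Nuclei counting from the DAPI channel.

The channel is pre-processed exactly as in the droplet workflow's sibling
procedure — a flat background offset of 50 intensity units is subtracted,
then a Gaussian low-pass with sigma 4 px smooths the plane — and nuclei are
then detected with a classical multi-scale Laplacian-of-Gaussian blob
detector with non-maximum suppression.  The detector carries an explicit
accuracy contract (exact on non-overlapping nuclei; <= 5 % relative count
error at <= 10 % pairwise overlap) validated against simulated fields with
known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist
from skimage.feature import blob_log, peak_local_max
from skimage.filters import threshold_otsu

from .imageops import ImagePlane, gaussian_blur, subtract_constant

__all__ = ["Nucleus", "NucleusSet", "NucleiConfig", "preprocess_dapi", "detect_nuclei"]


@dataclass(frozen=True)
class Nucleus:
    """One detected nucleus: centroid in pixel coordinates, radius estimate in um."""

    centroid: tuple[float, float]  # (row, col)
    est_radius_um: float


@dataclass
class NucleusSet:
    """All nuclei detected in one field."""

    nuclei: list[Nucleus] = field(default_factory=list)
    field_id: str = ""
    shape: tuple[int, int] = (0, 0)
    pixel_size: float = 0.31

    @property
    def count(self) -> int:
        return len(self.nuclei)

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of (row, col) centroids in pixels."""
        if not self.nuclei:
            return np.empty((0, 2))
        return np.array([n.centroid for n in self.nuclei], dtype=float)


@dataclass
class NucleiConfig:
    """Parameters of the DAPI pre-processing and nucleus detection.

    Attributes
    ----------
    background_value
        Flat offset subtracted from the whole image (intensity units).
    blur_sigma
        Gaussian low-pass sigma in pixels.
    min_separation_um
        Non-maximum-suppression radius; two detections closer than this are
        merged (default 6 um, below the typical ~8-12 um murine nucleus
        diameter, so double detections inside one nucleus are suppressed).
    expected_radius_um
        Prior nucleus radius used to pick the blob-detector scale range.
    detection
        "log_blobs" (multi-scale Laplacian of Gaussian, default) or
        "maxima_watershed" (regional maxima with distance suppression).
    intensity_floor
        "otsu" to derive the minimum peak intensity from the preprocessed
        histogram, or a fixed number for degenerate histograms.
    """

    background_value: float = 50.0
    blur_sigma: float = 4.0
    min_separation_um: float = 6.0
    expected_radius_um: float = 5.0
    detection: Literal["log_blobs", "maxima_watershed"] = "log_blobs"
    intensity_floor: float | Literal["otsu"] = "otsu"

    def __post_init__(self) -> None:
        for name in ("background_value", "blur_sigma", "min_separation_um", "expected_radius_um"):
            if getattr(self, name) < 0 or (name != "background_value" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.detection not in ("log_blobs", "maxima_watershed"):
            raise ValueError(f"unknown detection mode {self.detection!r}")


def preprocess_dapi(img: ImagePlane, cfg: NucleiConfig | None = None) -> ImagePlane:
    """Background-offset subtraction followed by Gaussian smoothing.

    The order is fixed: subtract first, blur second.  With the offset at 0
    this reduces to a pure blur.
    """
    cfg = cfg or NucleiConfig()
    out = img
    if cfg.background_value > 0:
        out = subtract_constant(out, cfg.background_value)
    return gaussian_blur(out, cfg.blur_sigma)


def _intensity_floor(pixels: np.ndarray, cfg: NucleiConfig) -> float:
    if cfg.intensity_floor == "otsu":
        if pixels.max() <= pixels.min():
            return np.inf  # flat image: nothing can clear the floor
        return float(threshold_otsu(pixels))
    return float(cfg.intensity_floor)


def _nms(peaks: np.ndarray, scores: np.ndarray, min_dist_px: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns indices of kept peaks."""
    order = np.argsort(scores)[::-1]
    kept: list[int] = []
    for i in order:
        if all(np.hypot(*(peaks[i] - peaks[j])) >= min_dist_px for j in kept):
            kept.append(i)
    return np.array(sorted(kept), dtype=int)


def detect_nuclei(img: ImagePlane, cfg: NucleiConfig | None = None, field_id: str = "") -> NucleusSet:
    """Detect nuclei in a preprocessed DAPI plane.

    One detection per locally maximal blob above the intensity floor, with
    non-maximum suppression at ``min_separation_um``.  Deterministic for a
    fixed input and configuration; an empty (flat) image yields an empty set.
    Nuclei touching the image border are kept.
    """
    cfg = cfg or NucleiConfig()
    px = img.pixel_size
    pixels = img.pixels
    floor = _intensity_floor(pixels, cfg)
    empty = NucleusSet([], field_id, img.shape, px)
    if not np.isfinite(floor):
        return empty

    min_sep_px = cfg.min_separation_um / px
    if cfg.detection == "log_blobs":
        peak = pixels.max()
        exp_r_px = cfg.expected_radius_um / px
        blobs = blob_log(
            pixels / peak,
            min_sigma=0.35 * exp_r_px,
            max_sigma=1.1 * exp_r_px,
            num_sigma=5,
            threshold=0.02,
            # radius-overlap pruning would merge genuinely overlapping nuclei;
            # the explicit min-separation NMS below is the only suppression
            overlap=1.0,
        )
        if blobs.size == 0:
            return empty
        coords = blobs[:, :2]
        sigmas = blobs[:, 2]
        values = pixels[coords[:, 0].astype(int), coords[:, 1].astype(int)]
        ok = values >= floor
        coords, sigmas, values = coords[ok], sigmas[ok], values[ok]
        if coords.size == 0:
            return empty
        keep = _nms(coords, values, min_sep_px)
        nuclei = [
            Nucleus((float(r), float(c)), float(np.sqrt(2.0) * s * px))
            for (r, c), s in zip(coords[keep], sigmas[keep])
        ]
    else:  # maxima_watershed: regional maxima with distance suppression
        coords = peak_local_max(
            pixels, min_distance=max(int(round(min_sep_px)), 1), threshold_abs=floor
        )
        if coords.size == 0:
            return empty
        nuclei = [
            Nucleus((float(r), float(c)), cfg.min_separation_um / 2.0) for r, c in coords
        ]

    # enforce the pairwise-separation invariant exactly (greedy NMS above is
    # already consistent; this guards the maxima path too)
    pts = np.array([n.centroid for n in nuclei])
    if len(pts) > 1:
        d = cdist(pts, pts)
        np.fill_diagonal(d, np.inf)
        order = np.argsort([-pixels[int(r), int(c)] for r, c in pts])
        keep_mask = np.ones(len(pts), bool)
        for i in order:
            if not keep_mask[i]:
                continue
            close = np.where(d[i] < min_sep_px)[0]
            for j in close:
                if keep_mask[j] and j != i and d[i, j] < min_sep_px:
                    # keep the brighter of the pair (i comes first in order)
                    keep_mask[j] = False
        nuclei = [n for n, k in zip(nuclei, keep_mask) if k]

    return NucleusSet(nuclei, field_id, img.shape, px)
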