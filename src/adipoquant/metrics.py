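"""Field-level adipocyte metrics.

Three headline quantities per field:

* adipocyte classification — a nucleus is called an adipocyte when enough
  distinct, sufficiently circular lipid droplets lie within a search radius
  of it (the automated surrogate for the manual call "positive BODIPY
  staining surrounding a DAPI-labelled nucleus, with distinct circular
  droplets rather than hazy or irregular signal");
* differentiation efficiency — adipocytes divided by total nuclei;
* per-cell lipid content — percent of a cell region covered by droplet-mask
  pixels, averaged over five cells sampled one per image region (four corner
  quadrants plus an equal-area centred square).

Per-field metrics aggregate across the images of a condition as
mean +/- SEM (sd / sqrt(n)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .droplets import DropletSegmentation, mean_droplet_area
from .imageops import BinaryMask
from .nuclei import Nucleus, NucleusSet

__all__ = [
    "AdipocyteRule",
    "DiskRegion",
    "CellRecord",
    "FieldMetrics",
    "ConditionSummary",
    "classify_adipocytes",
    "differentiation_efficiency",
    "sample_cells",
    "cell_lipid_content",
    "field_metrics",
    "summarize_condition",
]


@dataclass
class AdipocyteRule:
    """Decision rule for calling a nucleus an adipocyte.

    A nucleus is an adipocyte iff at least ``min_droplets`` particles have
    their centroid within ``search_radius_um`` of the nucleus centroid AND
    the mean circularity of those particles is at least ``min_circularity``
    (rejecting hazy, irregularly shaped signal).  Each nucleus is classified
    independently; a droplet may count toward several nearby nuclei.
    """

    search_radius_um: float = 15.0
    min_droplets: int = 3
    min_circularity: float = 0.6

    def __post_init__(self) -> None:
        if self.search_radius_um <= 0 or self.min_droplets <= 0:
            raise ValueError("search_radius_um and min_droplets must be positive")
        if not 0.0 <= self.min_circularity <= 1.0:
            raise ValueError("min_circularity must lie in [0, 1]")


@dataclass(frozen=True)
class DiskRegion:
    """Disk-shaped stand-in for a manually traced cell perimeter."""

    center: tuple[float, float]  # (row, col), pixels
    radius_um: float

    def rasterize(self, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
        """Boolean mask of the disk clipped to the image bounds."""
        r_px = self.radius_um / pixel_size
        r0, c0 = self.center
        rr = np.arange(shape[0])[:, None] - r0
        cc = np.arange(shape[1])[None, :] - c0
        return rr**2 + cc**2 <= r_px**2


@dataclass
class CellRecord:
    """One nucleus with its adipocyte call and (optional) lipid content."""

    nucleus: Nucleus
    is_adipocyte: bool
    cell_region: DiskRegion | None = None
    lipid_content_pct: float | None = None


@dataclass
class FieldMetrics:
    """Derived metrics for one image field."""

    field_id: str
    n_nuclei: int
    n_adipocytes: int
    differentiation_efficiency: float  # fraction in [0, 1]; NaN when no nuclei
    mean_droplet_area_um2: float
    mean_equiv_diam_um: float
    mean_lipid_content_pct: float


@dataclass
class ConditionSummary:
    """Mean +/- SEM of each metric across the fields of one condition."""

    condition: str
    fields: list[FieldMetrics]
    stats: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    # metric name -> (mean, sem, n); sem is NaN for a single field

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"condition": self.condition, "metric": m, "mean": mu, "sem": se, "n_fields": n}
            for m, (mu, se, n) in self.stats.items()
        ]
        return pd.DataFrame(rows)


def classify_adipocytes(
    nuclei: NucleusSet, seg: DropletSegmentation, rule: AdipocyteRule | None = None
) -> list[CellRecord]:
    """Classify every nucleus of a field by the droplet-proximity rule.

    The cell region attached to each record is a disk of the rule's search
    radius around the nucleus — the automated stand-in for a manually traced
    cell perimeter, used downstream for lipid content.
    """
    rule = rule or AdipocyteRule()
    if nuclei.field_id and seg.field_id and nuclei.field_id != seg.field_id:
        raise ValueError(
            f"field mismatch: nuclei from {nuclei.field_id!r}, segmentation from {seg.field_id!r}"
        )
    px = nuclei.pixel_size
    centroids = seg.particles.centroids  # (m, 2) px
    circ = seg.particles.circularities
    records: list[CellRecord] = []
    for nuc in nuclei.nuclei:
        region = DiskRegion(nuc.centroid, rule.search_radius_um)
        if len(centroids) == 0:
            records.append(CellRecord(nuc, False, region))
            continue
        d_um = np.hypot(*(centroids - np.array(nuc.centroid)).T) * px
        near = d_um <= rule.search_radius_um
        is_adipo = bool(
            near.sum() >= rule.min_droplets and circ[near].mean() >= rule.min_circularity
        )
        records.append(CellRecord(nuc, is_adipo, region))
    return records


def differentiation_efficiency(records: Sequence[CellRecord]) -> float:
    """Fraction of cells classified as adipocytes, in [0, 1]."""
    if len(records) == 0:
        raise ValueError("no cells: differentiation efficiency is undefined")
    return sum(r.is_adipocyte for r in records) / len(records)


def _five_regions(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Region centers and an assignment helper for the five-region scheme.

    Four corner quadrants plus a centred square of equal area (side
    ``sqrt(H*W/5)``); a nucleus inside the central square belongs to the
    centre region, otherwise to its quadrant, so the five regions partition
    the field.
    """
    h, w = shape
    side = np.sqrt(h * w / 5.0)
    centers = np.array(
        [
            [h / 4, w / 4],  # top left
            [h / 4, 3 * w / 4],  # top right
            [3 * h / 4, w / 4],  # bottom left
            [3 * h / 4, 3 * w / 4],  # bottom right
            [h / 2, w / 2],  # center
        ]
    )
    return centers, np.array([h, w, side])


def _assign_region(pts: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    side = np.sqrt(h * w / 5.0)
    in_center = (np.abs(pts[:, 0] - h / 2) <= side / 2) & (np.abs(pts[:, 1] - w / 2) <= side / 2)
    quad = 2 * (pts[:, 0] >= h / 2).astype(int) + (pts[:, 1] >= w / 2).astype(int)
    return np.where(in_center, 4, quad)


def sample_cells(nuclei: NucleusSet, n: int = 5, seed: int = 0) -> list[int]:
    """Select nuclei for lipid-content measurement, one per image region.

    The field is split into four corner quadrants plus an equal-area centred
    square; one nucleus is drawn uniformly at random (seeded) from each
    region.  A region without nuclei falls back to the unsampled nucleus
    nearest its centre.  With ``n`` different from 5 the draw is a plain
    seeded uniform sample without replacement.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    count = nuclei.count
    if count == 0:
        return []
    if count < n:
        warnings.warn(
            f"only {count} nuclei available for a sample of {n}; returning all", stacklevel=2
        )
        return list(range(count))
    pts = nuclei.centroids
    if n != 5:
        return sorted(rng.choice(count, size=n, replace=False).tolist())

    centers, _ = _five_regions(nuclei.shape)
    region_of = _assign_region(pts, nuclei.shape)
    chosen: list[int] = []
    empty_regions: list[int] = []
    for region in range(5):
        candidates = [i for i in np.flatnonzero(region_of == region) if i not in chosen]
        if candidates:
            chosen.append(int(rng.choice(candidates)))
        else:
            empty_regions.append(region)
    for region in empty_regions:
        remaining = [i for i in range(count) if i not in chosen]
        if not remaining:
            break
        d = cdist(pts[remaining], centers[region][None, :]).ravel()
        chosen.append(int(remaining[int(np.argmin(d))]))
    return sorted(chosen)


def cell_lipid_content(
    cell_region: DiskRegion | BinaryMask, seg: DropletSegmentation
) -> float:
    """Percent of the cell region covered by droplet-mask pixels, in [0, 100]."""
    if isinstance(cell_region, BinaryMask):
        region = cell_region.pixels
    else:
        region = cell_region.rasterize(seg.mask.shape, seg.mask.pixel_size)
    area = int(region.sum())
    if area == 0:
        raise ValueError("cell region has zero area inside the image")
    return 100.0 * float((seg.mask.pixels & region).sum()) / area


def field_metrics(
    nuclei: NucleusSet,
    seg: DropletSegmentation,
    records: Sequence[CellRecord],
    sampled_ids: Sequence[int],
    field_id: str | None = None,
) -> FieldMetrics:
    """Assemble counts, efficiency, droplet size and sampled lipid content."""
    n_adipo = sum(r.is_adipocyte for r in records)
    eff = n_adipo / len(records) if records else float("nan")
    size = mean_droplet_area(seg)
    contents = []
    for i in sampled_ids:
        rec = records[i]
        if rec.lipid_content_pct is None:
            rec.lipid_content_pct = cell_lipid_content(rec.cell_region, seg)
        contents.append(rec.lipid_content_pct)
    return FieldMetrics(
        field_id=field_id if field_id is not None else nuclei.field_id,
        n_nuclei=len(records),
        n_adipocytes=n_adipo,
        differentiation_efficiency=eff,
        mean_droplet_area_um2=size.mean_area_um2,
        mean_equiv_diam_um=size.mean_equiv_diam_um,
        mean_lipid_content_pct=float(np.mean(contents)) if contents else float("nan"),
    )


_METRIC_FIELDS = (
    "n_nuclei",
    "n_adipocytes",
    "differentiation_efficiency",
    "mean_droplet_area_um2",
    "mean_equiv_diam_um",
    "mean_lipid_content_pct",
)


def summarize_condition(fields: Sequence[FieldMetrics], label: str) -> ConditionSummary:
    """Mean and SEM (sd/sqrt(n), ddof=1) per metric across a condition's fields.

    At least three fields per condition is the intended design; fewer raises
    a warning, not an error.  With a single field the SEM is undefined (NaN).
    """
    if len(fields) == 0:
        raise ValueError("cannot summarize an empty list of fields")
    if len(fields) < 3:
        warnings.warn(
            f"condition {label!r} has only {len(fields)} field(s); at least 3 intended",
            stacklevel=2,
        )
    summary = ConditionSummary(label, list(fields))
    n = len(fields)
    for name in _METRIC_FIELDS:
        values = np.array([getattr(f, name) for f in fields], dtype=float)
        mean = float(np.nanmean(values))
        if n > 1:
            sem = float(np.nanstd(values, ddof=1) / np.sqrt(np.sum(~np.isnan(values))))
        else:
            sem = float("nan")
        summary.stats[name] = (mean, sem, n)
    return summary
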