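"""Synthetic two-channel confocal fields with complete ground truth.

The generator emulates a 20x confocal field of adherent cells undergoing
adipogenesis: the DAPI channel holds elliptical-to-round nuclei rendered as
Gaussian intensity profiles on a flat background; the BODIPY channel holds
clusters of bright, anti-aliased circular lipid droplets around the nuclei
of differentiated cells, a hazy large-scale autofluorescence background, and
sensor noise (Poisson shot noise at a configurable photon gain plus Gaussian
read noise).  Non-differentiated cells carry no droplets but share the haze.

Every rendered object is recorded in a :class:`FieldGroundTruth`: per-cell
centres, radii and adipocyte status; per-droplet owner, centre, radius and
rendered pixel area (pixels whose centre lies inside the disk, i.e. the
noiseless pre-quantisation droplet mask); and per-cell lipid content
computed on the true masks.  Fields are bit-reproducible given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .imageops import ImagePlane

__all__ = [
    "SimParams",
    "CellTruth",
    "DropletTruth",
    "FieldGroundTruth",
    "PlacementError",
    "generate_field",
    "generate_dataset",
    "brown_preset",
    "white_preset",
]


class PlacementError(RuntimeError):
    """Raised when cells or droplets cannot be placed after bounded retries."""


@dataclass
class SimParams:
    """Conditions of one simulated field.

    Geometry defaults emulate a 20x confocal field (1024 x 1024 px at
    0.31 um/px, ~317 um across) of adherent murine cells: nucleus radii
    ~N(5, 0.8) um, droplets placed in a perinuclear annulus (6-14 um) of
    their owner cell, droplet diameters lognormal within 1-6 um.  Intensity
    defaults put the droplet amplitude far above the background noise floor
    (frame-averaged confocal detection), consistent with a workflow that
    segments on a small fixed threshold.
    """

    shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.31  # um/px
    bit_depth: int = 16
    n_cells: int = 150
    differentiated_fraction: float = 0.4
    # nuclei
    nucleus_radius_um_mean: float = 5.0
    nucleus_radius_um_sd: float = 0.8
    nucleus_min_gap_um: float = 8.0  # extra centre spacing beyond touching radii
    nucleus_overlap_fraction: float = 0.0  # fraction of nuclei placed overlapping a neighbour
    nucleus_amplitude: float = 400.0
    dapi_background: float = 40.0
    # droplets
    droplets_per_adipocyte_mean: float = 12.0
    droplets_per_adipocyte_min: int = 3
    droplet_diam_um_median: float = 3.0
    droplet_diam_sigma_log: float = 0.3
    droplet_diam_um_min: float = 1.0
    droplet_diam_um_max: float = 6.0
    annulus_inner_um: float = 6.0
    annulus_outer_um: float = 14.0
    droplet_min_gap_px: float = 4.0  # edge-to-edge spacing between droplets
    droplet_clearance_um: float = 15.0  # min distance to any non-owner nucleus
    droplet_amplitude: float = 120.0
    amplitude_jitter: float = 0.1
    bodipy_background: float = 5.0
    # haze: smooth random field, spatial scale > 100 px
    haze_amplitude_frac: float = 0.15  # fraction of droplet amplitude
    haze_sigma_px: float = 60.0
    # debris mode: irregular low-circularity blobs exercising the shape criterion
    n_debris: int = 0
    debris_amplitude: float = 100.0
    # noise: counts = gain * Poisson(ideal / gain) + N(0, read_noise_sd)
    photon_gain: float = 0.01
    read_noise_sd: float = 0.5
    # truth bookkeeping
    cell_radius_um: float = 15.0  # disk used for true per-cell lipid content
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.differentiated_fraction <= 1.0:
            raise ValueError("differentiated_fraction must lie in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("pixel_size", "nucleus_radius_um_mean", "droplet_diam_um_median", "cell_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.annulus_inner_um >= self.annulus_outer_um:
            raise ValueError("annulus_inner_um must be < annulus_outer_um")

    @property
    def expected_background_sd(self) -> float:
        """Predicted intensity sd of the BODIPY background.

        Shot noise at the mean background level, read noise, and the 1/12
        variance of quantisation to integer intensities.
        """
        level = self.bodipy_background + 0.5 * self.haze_amplitude_frac * self.droplet_amplitude
        return float(np.sqrt(self.photon_gain * level + self.read_noise_sd**2 + 1.0 / 12.0))

    @property
    def expected_snr(self) -> float:
        """Droplet amplitude over predicted background noise sd."""
        return self.droplet_amplitude / self.expected_background_sd


@dataclass(frozen=True)
class CellTruth:
    center: tuple[float, float]  # (row, col) px
    radius_um: float
    is_adipocyte: bool
    lipid_content_pct: float  # on true masks, within the true cell disk


@dataclass(frozen=True)
class DropletTruth:
    owner: int  # index into cells
    center: tuple[float, float]  # (row, col) px
    radius_px: float
    area_px: int  # rendered area of the noiseless droplet mask


@dataclass
class FieldGroundTruth:
    """Complete per-cell / per-droplet truth for one synthetic field."""

    cells: list[CellTruth] = field(default_factory=list)
    droplets: list[DropletTruth] = field(default_factory=list)
    droplet_mask: np.ndarray | None = None  # noiseless pre-quantisation mask
    params: SimParams | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_adipocytes(self) -> int:
        return sum(c.is_adipocyte for c in self.cells)

    @property
    def differentiated_fraction(self) -> float:
        return self.n_adipocytes / self.n_cells if self.cells else float("nan")

    @property
    def nucleus_centers(self) -> np.ndarray:
        if not self.cells:
            return np.empty((0, 2))
        return np.array([c.center for c in self.cells])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.cells):
            rows.append(
                {
                    "record": "cell",
                    "id": i,
                    "row": c.center[0],
                    "col": c.center[1],
                    "radius": c.radius_um,
                    "is_adipocyte": int(c.is_adipocyte),
                    "lipid_content_pct": c.lipid_content_pct,
                    "owner": -1,
                    "area_px": -1,
                }
            )
        for j, d in enumerate(self.droplets):
            rows.append(
                {
                    "record": "droplet",
                    "id": j,
                    "row": d.center[0],
                    "col": d.center[1],
                    "radius": d.radius_px,
                    "is_adipocyte": -1,
                    "lipid_content_pct": float("nan"),
                    "owner": d.owner,
                    "area_px": d.area_px,
                }
            )
        return pd.DataFrame(rows)


def _place_nuclei(p: SimParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Place nucleus centres (px) and radii (um) by rejection sampling."""
    h, w = p.shape
    px = p.pixel_size
    margin = (p.annulus_outer_um + p.droplet_diam_um_max / 2) / px + 3
    if h - 2 * margin <= 1 or w - 2 * margin <= 1:
        raise PlacementError(f"image {p.shape} too small for margin {margin:.0f} px")
    n_overlap = int(round(p.nucleus_overlap_fraction * p.n_cells))
    n_main = p.n_cells - n_overlap
    centers: list[np.ndarray] = []
    radii: list[float] = []

    def _radius() -> float:
        r = rng.normal(p.nucleus_radius_um_mean, p.nucleus_radius_um_sd)
        return float(np.clip(r, 0.4 * p.nucleus_radius_um_mean, 2.0 * p.nucleus_radius_um_mean))

    attempts = 0
    cap = 300 * max(p.n_cells, 1)
    while len(centers) < n_main:
        attempts += 1
        if attempts > cap:
            raise PlacementError(
                f"placed only {len(centers)}/{n_main} nuclei after {cap} attempts"
            )
        c = rng.uniform([margin, margin], [h - margin, w - margin])
        r = _radius()
        ok = True
        for cj, rj in zip(centers, radii):
            if np.hypot(*(c - cj)) * px < r + rj + p.nucleus_min_gap_um:
                ok = False
                break
        if ok:
            centers.append(c)
            radii.append(r)
    # overlapping subset: attach each to a randomly chosen placed nucleus at a
    # centre distance of 0.7-0.9 of the touching distance
    while len(centers) < p.n_cells:
        attempts += 1
        if attempts > cap:
            raise PlacementError("could not place overlapping nuclei")
        anchor = int(rng.integers(len(centers)))
        r = _radius()
        frac = rng.uniform(0.7, 0.9)
        d_px = frac * (radii[anchor] + r) / px
        theta = rng.uniform(0, 2 * np.pi)
        c = centers[anchor] + d_px * np.array([np.sin(theta), np.cos(theta)])
        if not (margin <= c[0] <= h - margin and margin <= c[1] <= w - margin):
            continue
        ok = True
        for j, (cj, rj) in enumerate(zip(centers, radii)):
            if j == anchor:
                continue
            if np.hypot(*(c - cj)) * px < r + rj + p.nucleus_min_gap_um:
                ok = False
                break
        if ok:
            centers.append(c)
            radii.append(r)
    return np.array(centers).reshape(-1, 2), np.array(radii)


def _place_droplets(
    p: SimParams,
    rng: np.random.Generator,
    centers: np.ndarray,
    adipocyte: np.ndarray,
) -> tuple[list[DropletTruth], np.ndarray]:
    """Place droplets in the perinuclear annulus of each adipocyte.

    Radial positions are drawn from a triangular law peaking at the inner
    annulus radius (droplets cluster perinuclearly).  Droplets stay inside
    their owner's cytoplasm: closer to the owner's nucleus than to any other
    and at least ``droplet_clearance_um`` from every non-owner nucleus (a
    neighbouring cell's nuclear region and perinuclear space cannot host
    this cell's droplets).  Droplets keep an edge-to-edge spacing of at
    least ``droplet_min_gap_px`` from every other droplet in the field.
    """
    h, w = p.shape
    px = p.pixel_size
    import math

    n = len(centers)
    adipo_idx = np.flatnonzero(adipocyte)
    if adipo_idx.size == 0:
        return [], adipocyte.copy()
    # pairwise nucleus distances (um) to restrict per-attempt checks to the
    # few nuclei/droplet clouds that can actually conflict
    diff = centers[:, None, :] - centers[None, :, :]
    dist_um = np.hypot(diff[..., 0], diff[..., 1]) * px
    reach_um = p.annulus_outer_um + p.droplet_diam_um_max / 2
    clearance_px = p.droplet_clearance_um / px

    cap = int(adipo_idx.size * (p.droplets_per_adipocyte_mean * 4 + 20))
    buf_c = np.empty((cap, 2))
    buf_r = np.empty(cap)
    n_placed = 0
    cell_droplets: list[list[int]] = [[] for _ in range(n)]
    truths: list[DropletTruth] = []

    log_median = np.log(p.droplet_diam_um_median)

    def _try_cell(i: int) -> list[DropletTruth] | None:
        nonlocal n_placed, buf_c, buf_r, cap
        saved_n_placed = n_placed
        foreign = np.flatnonzero(
            (dist_um[i] <= p.annulus_outer_um + p.droplet_clearance_um) & (np.arange(n) != i)
        )
        fc = centers[foreign]
        neigh = [
            k
            for j in range(n)
            if j != i and cell_droplets[j] and dist_um[i, j] <= 2 * reach_um + 2
            for k in cell_droplets[j]
        ]
        neigh_idx = np.array(neigh, dtype=int)
        own: list[int] = []
        local: list[DropletTruth] = []
        target = max(p.droplets_per_adipocyte_min, int(rng.poisson(p.droplets_per_adipocyte_mean)))
        placed_for_cell = 0
        attempts = 0
        ci0, ci1 = centers[i]
        while placed_for_cell < target and attempts < 400 * target:
            attempts += 1
            diam = math.exp(rng.normal(log_median, p.droplet_diam_sigma_log))
            diam = min(max(diam, p.droplet_diam_um_min), p.droplet_diam_um_max)
            r_px = diam / 2 / px
            rad_um = rng.triangular(p.annulus_inner_um, p.annulus_inner_um, p.annulus_outer_um)
            theta = rng.uniform(0, 2 * np.pi)
            c0 = ci0 + (rad_um / px) * math.sin(theta)
            c1 = ci1 + (rad_um / px) * math.cos(theta)
            if not (r_px + 2 <= c0 <= h - r_px - 3 and r_px + 2 <= c1 <= w - r_px - 3):
                continue
            # cytoplasm ownership: closer to the owner nucleus than any other
            # and clear of every non-owner nucleus' perinuclear space
            if foreign.size:
                d_f = np.hypot(fc[:, 0] - c0, fc[:, 1] - c1)
                fmin = d_f.min()
                if fmin < clearance_px or fmin <= rad_um / px:
                    continue
            check = own if neigh_idx.size == 0 else list(neigh_idx) + own
            if check:
                idx = np.asarray(check, dtype=int)
                gap = (
                    np.hypot(buf_c[idx, 0] - c0, buf_c[idx, 1] - c1) - buf_r[idx] - r_px
                )
                if gap.min() < p.droplet_min_gap_px:
                    continue
            if n_placed == cap:  # very heavy Poisson tail: grow the buffers
                buf_c = np.concatenate([buf_c, np.empty_like(buf_c)])
                buf_r = np.concatenate([buf_r, np.empty_like(buf_r)])
                cap *= 2
            buf_c[n_placed] = (c0, c1)
            buf_r[n_placed] = r_px
            own.append(n_placed)
            local.append(DropletTruth(int(i), (float(c0), float(c1)), float(r_px), 0))
            n_placed += 1
            placed_for_cell += 1
        if placed_for_cell < p.droplets_per_adipocyte_min:
            n_placed = saved_n_placed  # roll back partial placement
            return None
        cell_droplets[i] = own
        return local

    # differentiation requires cytoplasmic room: a cell that cannot host the
    # minimum droplet count under the clearance constraints yields adipocyte
    # status to another cell, keeping the true differentiated count exact
    final_adipo = adipocyte.copy()
    pool = [int(j) for j in range(n) if not adipocyte[j]]
    rng.shuffle(pool)
    for i in adipo_idx:
        i = int(i)
        placed = _try_cell(i)
        while placed is None:
            final_adipo[i] = False
            if not pool:
                raise PlacementError(
                    f"could not place the minimum {p.droplets_per_adipocyte_min} droplets "
                    f"for {int(final_adipo.sum()) + 1} adipocytes; field too crowded"
                )
            i = pool.pop()
            final_adipo[i] = True
            placed = _try_cell(i)
        truths.extend(placed)
    return truths, final_adipo


def _render_droplets(
    p: SimParams, rng: np.random.Generator, droplets: list[DropletTruth], bodipy: np.ndarray
) -> tuple[np.ndarray, list[DropletTruth]]:
    """Add anti-aliased disks to the BODIPY plane; return the true mask and
    droplets with rendered areas filled in."""
    h, w = p.shape
    mask = np.zeros((h, w), bool)
    out: list[DropletTruth] = []
    for d in droplets:
        amp = p.droplet_amplitude * (1 + rng.uniform(-p.amplitude_jitter, p.amplitude_jitter))
        r0, c0 = d.center
        rad = d.radius_px
        lo_r, hi_r = int(np.floor(r0 - rad - 2)), int(np.ceil(r0 + rad + 2)) + 1
        lo_c, hi_c = int(np.floor(c0 - rad - 2)), int(np.ceil(c0 + rad + 2)) + 1
        rr = np.arange(lo_r, hi_r)[:, None] - r0
        cc = np.arange(lo_c, hi_c)[None, :] - c0
        dist = np.hypot(rr, cc)
        coverage = np.clip(rad + 0.5 - dist, 0.0, 1.0)  # 1-px linear edge ramp
        bodipy[lo_r:hi_r, lo_c:hi_c] += amp * coverage
        inside = dist <= rad
        mask[lo_r:hi_r, lo_c:hi_c] |= inside
        out.append(dataclasses.replace(d, area_px=int(inside.sum())))
    return mask, out


def _render_debris(p: SimParams, rng: np.random.Generator, bodipy: np.ndarray) -> None:
    """Irregular, low-circularity blobs: short random walks of small disks."""
    h, w = p.shape
    margin = 30
    yy, xx = np.mgrid[-3:4, -3:4]
    stamp = (yy**2 + xx**2 <= 9).astype(float)
    for _ in range(p.n_debris):
        pos = rng.uniform([margin, margin], [h - margin, w - margin])
        canvas = np.zeros((h, w))
        for _step in range(rng.integers(8, 20)):
            r, c = int(pos[0]), int(pos[1])
            if 4 <= r < h - 4 and 4 <= c < w - 4:
                canvas[r - 3 : r + 4, c - 3 : c + 4] = np.maximum(
                    canvas[r - 3 : r + 4, c - 3 : c + 4], stamp
                )
            pos = pos + rng.normal(0, 3.0, 2)
        bodipy += p.debris_amplitude * canvas


def _apply_noise(p: SimParams, rng: np.random.Generator, ideal: np.ndarray) -> np.ndarray:
    """Poisson shot noise at the photon gain plus Gaussian read noise, then
    quantisation to the configured bit depth."""
    lam = np.clip(ideal, 0, None) / p.photon_gain
    noisy = p.photon_gain * rng.poisson(lam).astype(np.float64)
    noisy += rng.normal(0.0, p.read_noise_sd, size=ideal.shape)
    top = 2**p.bit_depth - 1
    return np.clip(np.round(noisy), 0, top)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    return rr**2 + cc**2 <= radius_px**2


def generate_field(p: SimParams) -> tuple[ImagePlane, ImagePlane, FieldGroundTruth]:
    """Render one two-channel field and its ground truth, deterministically."""
    rng = np.random.default_rng(p.seed)
    h, w = p.shape
    px = p.pixel_size

    if p.n_cells > 0:
        centers, radii_um = _place_nuclei(p, rng)
    else:
        centers, radii_um = np.empty((0, 2)), np.empty(0)
    n_adipo = int(round(p.differentiated_fraction * p.n_cells))
    adipocyte = np.zeros(p.n_cells, bool)
    adipocyte[rng.permutation(p.n_cells)[:n_adipo]] = True

    # DAPI: flat background + Gaussian-profile nuclei
    dapi = np.full((h, w), p.dapi_background, dtype=np.float64)
    for (r0, c0), r_um in zip(centers, radii_um):
        sigma = r_um / px / 2.0  # Gaussian sigma = half the nominal radius
        amp = p.nucleus_amplitude * (1 + rng.uniform(-p.amplitude_jitter, p.amplitude_jitter))
        ext = int(np.ceil(4 * sigma))
        lo_r, hi_r = max(int(r0) - ext, 0), min(int(r0) + ext + 1, h)
        lo_c, hi_c = max(int(c0) - ext, 0), min(int(c0) + ext + 1, w)
        rr = np.arange(lo_r, hi_r)[:, None] - r0
        cc = np.arange(lo_c, hi_c)[None, :] - c0
        dapi[lo_r:hi_r, lo_c:hi_c] += amp * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))

    # BODIPY: flat base + smooth haze + droplets (+ optional debris)
    bodipy = np.full((h, w), p.bodipy_background, dtype=np.float64)
    if p.haze_amplitude_frac > 0:
        haze = ndimage.gaussian_filter(rng.standard_normal((h, w)), p.haze_sigma_px, mode="reflect")
        haze -= haze.min()
        peak = haze.max()
        if peak > 0:
            haze *= p.haze_amplitude_frac * p.droplet_amplitude / peak
        bodipy += haze
    if p.n_cells and adipocyte.any():
        droplet_specs, adipocyte = _place_droplets(p, rng, centers, adipocyte)
    else:
        droplet_specs = []
    true_mask, droplets = _render_droplets(p, rng, droplet_specs, bodipy)
    if p.n_debris > 0:
        _render_debris(p, rng, bodipy)

    cells: list[CellTruth] = []
    cell_r_px = p.cell_radius_um / px
    for i, ((r0, c0), r_um) in enumerate(zip(centers, radii_um)):
        disk = _disk_mask((h, w), (r0, c0), cell_r_px)
        content = 100.0 * float((true_mask & disk).sum()) / float(disk.sum())
        cells.append(CellTruth((float(r0), float(c0)), float(r_um), bool(adipocyte[i]), content))

    dapi_plane = ImagePlane(_apply_noise(p, rng, dapi), p.bit_depth, px)
    bodipy_plane = ImagePlane(_apply_noise(p, rng, bodipy), p.bit_depth, px)
    truth = FieldGroundTruth(cells, droplets, true_mask, p)
    return dapi_plane, bodipy_plane, truth


def brown_preset(**overrides) -> SimParams:
    """Multilocular tendency: more, smaller droplets per cell (preset only,
    no biological claim)."""
    base = dict(
        droplets_per_adipocyte_mean=20.0,
        droplet_diam_um_median=2.0,
        droplet_diam_um_max=4.0,
    )
    base.update(overrides)
    return SimParams(**base)


def white_preset(**overrides) -> SimParams:
    """Unilocular tendency: fewer, larger droplets per cell."""
    base = dict(
        droplets_per_adipocyte_mean=6.0,
        droplets_per_adipocyte_min=3,
        droplet_diam_um_median=4.0,
    )
    base.update(overrides)
    return SimParams(**base)


def _field_seed(base_seed: int, cond_idx: int, field_idx: int) -> int:
    ss = np.random.SeedSequence(base_seed, spawn_key=(cond_idx, field_idx))
    return int(ss.generate_state(1)[0] % 2**31)


def generate_dataset(
    conditions: list[tuple[str, SimParams]],
    fields_per_condition: int,
    base_seed: int,
    out_dir: str | Path,
) -> dict:
    """Write TIFF pairs, per-field truth CSVs and a manifest to ``out_dir``.

    Per-field seeds derive deterministically from ``base_seed``; identical
    arguments reproduce identical bytes.  Returns the manifest dict.
    """
    if fields_per_condition < 1:
        raise ValueError("fields_per_condition must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dtype = {8: np.uint8, 16: np.uint16}
    manifest: dict = {"base_seed": base_seed, "fields": []}
    for ci, (label, params) in enumerate(conditions):
        safe = label.replace(" ", "_")
        for fi in range(fields_per_condition):
            seed = _field_seed(base_seed, ci, fi)
            p = dataclasses.replace(params, seed=seed)
            dapi, bodipy, truth = generate_field(p)
            field_id = f"{safe}_{fi:02d}"
            files = {
                "dapi": f"{field_id}_dapi.tif",
                "bodipy": f"{field_id}_bodipy.tif",
                "truth": f"{field_id}_truth.csv",
            }
            dt = dtype.get(p.bit_depth, np.float32)
            tifffile.imwrite(out / files["dapi"], dapi.pixels.astype(dt))
            tifffile.imwrite(out / files["bodipy"], bodipy.pixels.astype(dt))
            truth.to_dataframe().to_csv(out / files["truth"], index=False)
            entry = {
                "field_id": field_id,
                "condition": label,
                "seed": seed,
                "files": files,
                "n_cells": truth.n_cells,
                "n_adipocytes": truth.n_adipocytes,
                "pixel_size": p.pixel_size,
            }
            manifest["fields"].append(entry)
        manifest.setdefault("conditions", {})[label] = dataclasses.asdict(params)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
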