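# Methods

`adipoquant` re-implements, as a tested library, the confocal-image
quantification workflows used to score in-vitro adipogenesis of iPSC-derived
pre-differentiated cells (PDiPSCs), together with the 2^−ΔΔCt fold-change
computation used for the accompanying qPCR readouts. Because the original
confocal images are human-scored and not deposited, every quantitative
contract is validated against a synthetic-field generator with complete
ground truth.

## Image model and pipelines

Inputs are paired single-plane grayscale TIFFs: a DAPI channel (nuclei) and
a BODIPY channel (neutral-lipid droplets), with a µm/px calibration supplied
by configuration (default 0.31 µm/px, typical of a 20× confocal field).
Intensities are carried as float64 with explicit bit-depth semantics; 8- and
16-bit planes are bounded, 32-float planes may be negative (required after
image subtraction).

**Nuclei counting.** The DAPI plane is pre-processed by subtracting a flat
background offset of 50 intensity units (clamped at zero) and smoothing with
a Gaussian of σ = 4 px — subtract first, blur second. Counting then uses a
multi-scale Laplacian-of-Gaussian blob detector with greedy non-maximum
suppression at a 6 µm separation (below the ~8–12 µm murine nucleus
diameter, so one nucleus cannot yield two detections). The original workflow
used a pretrained deep segmentation plugin for this step; a learned model is
deliberately out of scope here, so the classical detector carries an
explicit accuracy contract instead: exact counts on non-overlapping nuclei,
≤ 5 % relative error when 10 % of nuclei overlap a neighbour, mean centroid
error ≤ 2 px. The intensity floor defaults to Otsu's threshold on the
pre-processed plane with a fixed-value override for degenerate histograms.
Border-touching nuclei are counted.

**Droplet segmentation.** The BODIPY plane runs through a fixed sequence:
cast to the 16-bit intensity range (8-bit inputs ×257), rolling-ball
background correction with radius 50 px, duplicate–blur–subtract enhancement
(the plane minus its σ = 4 px Gaussian blur, kept signed as 32-float), a
manual threshold of 3 intensity units, and connected-component particle
analysis (8-connectivity default). The rolling ball is implemented as
grayscale morphological opening with a disk structuring element, applied
through an exact "crosses" footprint decomposition for speed; the result is
non-negative, bounded by the input, and idempotent. The difference image is
where the fixed threshold lives: smooth residual background (haze the
opening cannot fully flatten) cancels in the difference, so the operating
point depends on droplet amplitude rather than illumination. Touching
droplets are not split — the workflow has no watershed step — so validation
fields keep a minimum droplet spacing of 4 px. Particle circularity uses the
Crofton perimeter estimator (4π·area/perimeter², clipped to [0, 1]), which
brings rasterized disks close to 1; a 1-px-wide streak scores < 0.3.

**Field metrics.** A nucleus is called an adipocyte when ≥ 3 particles lie
within 15 µm of its centroid and those particles' mean circularity is
≥ 0.6 — the automated surrogate for the manual call ("positive BODIPY
staining surrounding a DAPI-labelled nucleus, with distinct circular
droplets rather than hazy, irregular signal"). Droplets may count toward
several nuclei; nuclei are classified independently. Differentiation
efficiency is adipocytes over total nuclei. Per-cell lipid content is the
percentage of a cell region covered by droplet-mask pixels; with no traced
perimeter available the cell region is a disk of the search radius around
the nucleus. Five cells per field are sampled, one from each of five image
regions — the four corner quadrants plus an equal-area centred square (a
reading of "five quadrants" that makes the regions a partition); a region
without nuclei falls back to the unsampled nucleus nearest its centre; the
draw is seeded and logged. Conditions aggregate per-field metrics as
mean ± SEM (sd/√n), warning when fewer than three fields are supplied.

**qPCR.** Per sample, ΔCt = Ct(target) − Ct(reference gene, e.g. 18S rRNA);
ΔΔCt subtracts the arithmetic mean control-group ΔCt per gene; the fold
change is 2^−ΔΔCt. Technical replicates are averaged to one Ct per
sample × gene first. The control group's geometric-mean fold is exactly 1
by construction, and adding a constant to all of one sample's Ct values
(target and reference alike) leaves its fold unchanged — both are tested.
Group summaries report SEM on the fold scale (matching the figure-legend
convention) and on the log2 scale. Efficiency-corrected models (Pfaffl) are
out of scope.

## The synthetic-field generator

The generator is first-class, tested code: it renders a 1024 × 1024 px field
at 0.31 µm/px containing `n_cells` (default 150) adherent cells, a
configurable fraction of which are differentiated. Nuclei are Gaussian
intensity profiles (radius ~ N(5, 0.8) µm, σ = radius/2) on a flat DAPI
background of 40; adipocytes carry Poisson(12)-many (min 3) circular
droplets with lognormal diameters (median 3 µm, σ_log 0.3, clipped to
1–6 µm) placed in a perinuclear annulus 6–14 µm from the nucleus centre;
the BODIPY channel adds a smooth haze field (Gaussian-filtered noise,
σ = 60 px, amplitude 15 % of the droplet amplitude) and both channels get
Poisson shot noise (photon gain 0.01 counts/photon, emulating frame-averaged
confocal detection), Gaussian read noise (sd 0.5) and integer quantisation.
Ground truth records every cell, droplet, the noiseless droplet mask, and
per-cell lipid content computed on that mask. Fields are bit-reproducible
from the seed; placement failures after bounded retries raise an explicit
error rather than silently dropping objects.

Three geometric choices matter and were fixed once as the study conditions:

* **Nucleus spacing.** Centres keep a gap of 8 µm beyond touching radii
  (near-confluent adherent spacing). Fields stressing the nuclei-count
  contract with 200 nuclei use a 2 µm gap — with the default gap, 200
  non-overlapping cells exceed the random-packing limit of the field.
* **Perinuclear clustering.** Radial droplet positions follow a triangular
  law peaking at the inner annulus radius: droplets crowd the nucleus, as in
  early multilocular adipocytes, rather than spreading uniformly.
* **Cytoplasm exclusivity.** A droplet must be closer to its owner's nucleus
  than to any other and at least 15 µm from every non-owner nucleus. The
  default clearance equals the classifier's search radius: the generator
  emulates fields in which droplet ownership is visually unambiguous, which
  is also the regime in which the manual scoring the rule stands in for is
  itself reliable. Consequently, recovery results on these fields say
  nothing about crowded fields where droplet clouds genuinely interleave
  between nuclei — there, any proximity rule (and a human rater) would face
  ambiguous assignments. Lowering `droplet_clearance_um` produces such
  fields for robustness exploration. Because differentiation requires
  cytoplasmic room, a cell so boxed in by neighbours that it cannot host the
  minimum droplet count under these constraints yields its adipocyte status
  to another randomly chosen cell; the true differentiated count stays
  exact, and a field where no cell can host the droplets raises an explicit
  placement error.

The noise defaults keep the background sd at ≈ 0.6 intensity units so the
fixed manual threshold of 3 sits > 4σ above the noise floor. This is not
incidental: a fixed threshold of 3 on a 16-bit difference image is only a
sane operating point when acquisition noise is well below it, which
constrains what the original images must have looked like. The predicted
background sd includes shot noise at the mean background level, read noise,
and the 1/12 quantisation variance, and is verified against measurement
within 10 %.

What the generator does **not** emulate: optical PSF blur of droplet edges
(droplets are anti-aliased hard disks), z-structure, uneven illumination
beyond the smooth haze, staining variability, mitotic/apoptotic nuclei, and
real cell shapes (truth cell regions are disks). Passing recovery tests
therefore demonstrates that the pipeline implements its stated operations
correctly and recovers truth under controlled imaging physics — not that it
reproduces human scoring of real micrographs.

## Numerical choices

* Threshold convention: foreground is ≥ t (the lower bound is included).
* Blur boundary handling: reflection, avoiding dark-frame artifacts that
  would create spurious difference-of-Gaussian foreground at edges.
* The difference image is never clipped; only the threshold decides
  foreground.
* No particle size filter by default (`min_area_px = 1`), matching a
  workflow that states none.
* Empty particle tables yield an explicit "no particles" status (NaN means,
  n = 0), never a zero that could drag a condition average down.
* Degenerate inputs: flat DAPI planes return zero nuclei; an empty cell
  list is an error for efficiency (undefined), a warning for sampling.
* Greedy non-maximum suppression keeps the brighter of two conflicting
  detections; ties are resolved by detection order, which is deterministic.

## Problem sizes in the test suite

Unit tests run on 512-px fields with ~30 cells; the end-to-end acceptance
tests use the full study conditions (1024-px fields, 150–200 cells, 20
fields per differentiation level, 1 000 random masks against the flood-fill
oracle, 10 000 sampling draws). `scripts/acceptance.py` recomputes the same
quantities at a reduced field count per setting (printed in its JSON `n`
fields) so a complete from-scratch reproduction stays desk-scale.

## Known limitations

* The adipocyte rule's parameters (15 µm, 3 droplets, circularity 0.6) are
  surrogates validated only against the simulator; they are not claimed to
  reproduce human judgments on real images.
* Droplet sizes below ~2 px diameter segment unreliably (the difference-of-
  Gaussian ring erodes them); the generator's 1 µm minimum diameter at
  0.31 µm/px sits just above this.
* Whether printed droplet "size" means area (µm²) or equivalent diameter
  (µm) is ambiguous in the field; both are always reported.
* The LoG detector undercounts heavily overlapped nuclei (> ~10 % overlap
  fraction); the contract is scoped accordingly.
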