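# adipoquant

Quantification of in-vitro adipogenesis from two-channel confocal
micrographs, for labs differentiating iPSC-derived or MEF-derived
pre-adipocytes and scoring them with BODIPY (neutral-lipid droplets) and
DAPI (nuclei) staining. The package turns the interactive ImageJ-style
workflows such experiments rely on into a tested, scriptable pipeline, and
adds the 2^−ΔΔCt relative-expression computation used for the accompanying
qPCR readouts.

## What it computes

Given a paired field (DAPI + BODIPY single-plane grayscale TIFF, µm/px
calibration):

* **Nuclei count** — DAPI is background-subtracted (flat offset 50) and
  Gaussian-smoothed (σ = 4 px), then nuclei are detected with a
  multi-scale Laplacian-of-Gaussian blob detector with non-maximum
  suppression (exact on non-overlapping nuclei; ≤ 5 % error at ≤ 10 %
  overlap, validated against simulated ground truth).
* **Lipid-droplet segmentation** — 16-bit cast → rolling-ball background
  correction (radius 50 px, grayscale opening with a disk) → the image
  minus its σ = 4 px blur, kept signed → manual threshold 3 → particle
  analysis (areas, centroids, Crofton-perimeter circularity, equivalent
  diameters).
* **Differentiation efficiency** — a nucleus is an adipocyte when ≥ 3
  particles of mean circularity ≥ 0.6 lie within 15 µm; efficiency =
  adipocytes / nuclei.
* **Per-cell lipid content** — % of a cell region covered by droplet
  pixels, for 5 cells sampled one per image region (four corner quadrants
  + an equal-area centred square), averaged per field.
* **Condition summaries** — mean ± SEM (sd/√n) across the fields of each
  condition.
* **qPCR fold changes** — per sample, ΔCt = Ct(gene) − Ct(18S);
  ΔΔCt = ΔCt − mean control ΔCt; fold = 2^−ΔΔCt, with group mean ± SEM.

A ground-truth simulator (`adipoquant.simulate`) renders confocal-like
fields — Gaussian-profile nuclei, perinuclear clusters of circular
droplets, smooth autofluorescence haze, shot + read noise — so every stage
is testable without external data. See `docs/methods.md` for the model,
parameter defaults, and what the simulator does and does not emulate.

## Worked example

```python
import adipoquant as aq

# simulate one field: 150 cells, 40 % differentiated, seeded
p = aq.SimParams(seed=7, n_cells=150, differentiated_fraction=0.4)
dapi, bodipy, truth = aq.generate_field(p)

nuclei = aq.detect_nuclei(aq.preprocess_dapi(dapi))
seg = aq.segment_droplets(bodipy)
records = aq.classify_adipocytes(nuclei, seg)

print("nuclei:", nuclei.count, "| true:", truth.n_cells)
print("particles:", len(seg.particles), "| true droplets:", len(truth.droplets))
print("efficiency:", round(aq.differentiation_efficiency(records), 3),
      "| true:", round(truth.differentiated_fraction, 3))
size = aq.mean_droplet_area(seg)
print("mean droplet area:", round(size.mean_area_um2, 2), "um^2 /",
      round(size.mean_equiv_diam_um, 2), "um equivalent diameter")
```

prints

```
nuclei: 150 | true: 150
particles: 635 | true droplets: 629
efficiency: 0.4 | true: 0.4
mean droplet area: 7.27 um^2 / 2.92 um equivalent diameter
```

i.e. the detector recovers all 150 nuclei, segmentation finds 635 particles
for 629 rendered droplets (noise specks and merges roughly cancel), the
recovered differentiation efficiency matches the simulated 40 %, and the
field's mean droplet size is reported both as area and as equivalent
diameter (the two conventions in which droplet "size" is printed).

The same stages run from the shell:

```bash
adipoquant simulate --config sim.yaml --out data/        # synthetic dataset
adipoquant nuclei   --dapi field_dapi.tif --out nuclei.csv
adipoquant droplets --bodipy field_bodipy.tif --out-table particles.csv
adipoquant run      --config run.yaml                    # full batch + QC overlays
adipoquant qpcr     --ct ct.csv --reference 18S --control ctrl --out folds.csv
```

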