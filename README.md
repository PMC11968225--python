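# implantquant

Spatial quantification of tissue sections through microporous annealed
particle (MAP) scaffold implants — injectable hydrogel microsphere slurries
annealed into a porous implant, a fraction of whose particles may carry
heparin ("heparin µislands") to sequester endogenous growth factors.

The scientific question these analyses serve is how cells and matrix
organise across an implant over months *as a function of distance from the
implant edge*: immune and stromal cells infiltrate from the surrounding
tissue, so radial gradients — not bulk averages — carry the biology. The
package implements that spatial workflow for multichannel immunofluorescence
sections and caliper morphometry, and pairs it with a synthetic scene
generator with complete ground truth so that every stage is verifiable by
parameter recovery without any raw study images.

## What it computes

- **ROI geometry** (`roi_geometry`): implant segmentation from the DAPI
  channel; concentric 100 µm bands measured inward from the implant edge
  via the Euclidean distance transform (band *k* covers depths
  [(k−1)Δ, kΔ)); and the core/outer split at the depth cutoff *d* such that
  {depth ≥ d} holds 50 % of the implant area (for a disk of radius *R*,
  d = R(1−1/√2)).
- **Intensity quantification** (`intensity_quant`): per-stain thresholding
  (Otsu/triangle/fixed, computed over ROI pixels only), fraction-positive
  per band, and object counts — e.g. CD31⁺ and CD31⁺Podoplanin⁺ (lymphatic
  endothelial) objects per region, normalised to area.
- **Cell phenotyping** (`cell_phenotyping`): Laplacian-of-Gaussian spot
  detection, greedy 8 µm deduplication of nuclear spots, and a proximity
  rule cascade — a cell is a macrophage if a CD68 spot lies < 8 µm away, M1
  if additionally iNOS < 8 µm, M2 if Arg1 < 8 µm; T cells via CD3e and CD4;
  fibroblasts as cells within 2 µm of a thresholded TE-7 surface; Ki67⁺
  cells by near-coincidence.
- **Morphometry** (`morphometry`): implant volumes V = (π/6)·l·w·h from
  caliper dimensions and fold changes relative to implantation.
- **Spatial statistics** (`spatial_stats`): the linear mixed model
  `fraction ~ group × timepoint × distance` with random intercepts per
  mouse and per image replicate (REML), marginal distance slopes per
  group × timepoint cell, and Tukey-adjusted pairwise slope contrasts.
- **Synthetic scenes** (`synthetic_scene`): hard-disk microparticle
  packings (~70 µm diameters, 10 % heparin-flagged), depth-graded cell
  point processes with phenotype labels and conditional marker flags,
  channel rendering, and caliper series with configurable volume decay.

## Worked example

```python
import implantquant as iq

cfg = iq.SceneConfig(seed=5)                 # default study-like scene
roi_true = iq.make_roi_mask(cfg)
truth = iq.generate_cells(cfg, roi_true)     # ground-truth cell table
image = iq.render_scene(truth, cfg)          # DAPI + 9 marker channels

roi = iq.derive_roi(image.channel("DAPI"), image.pixel_size_um)
counts = iq.phenotype_image(image, roi)
print(f"cells detected: {counts.n_cells} (true: {len(truth)})")
for k, v in counts.fractions().items():
    print(f"  {k:<11s} {v:.3f}")
split = iq.inner_outer_split(roi, 0.5)
print(f"core cutoff depth: {split.cutoff_depth_um:.1f} um "
      f"(inner fraction {split.inner_area_fraction:.3f})")
```

prints

```
cells detected: 821 (true: 821)
  macrophage  0.320
  m1          0.156
  m2          0.128
  tcell       0.141
  thelper     0.090
  fibroblast  0.210
  ki67        0.211
core cutoff depth: 174.6 um (inner fraction 0.500)
```

The recovered fractions match the generator's configuration (30 %
macrophages of which 50 %/40 % are iNOS⁺/Arg1⁺, 15 % T cells with 60 %
CD4⁺, 20 % fibroblasts, 20 % Ki67⁺ overall), and the core/outer split lands
on exactly half the implant area — the recovery checks the test suite runs
at scale.

A full multi-image experiment (simulate → ROI → quantify → phenotype →
morphometry → mixed model) runs from one config:

```bash
implantquant run --config run.yaml --seed 7 --out runs/demo
implantquant simulate calipers --seed 2 --out calipers.csv
implantquant morphometry --calipers calipers.csv --out folds.csv
```

Each run directory contains `band_fractions.csv`, `phenotype_counts.csv`,
`object_counts.csv`, `slopes.csv`, `contrasts.csv` and a provenance
`manifest.json` (config hash, seed, version).

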