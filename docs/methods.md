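# Methods

This note records the models, conventions and numerical choices behind
`implantquant`, in the spirit of a statistical-methods appendix: what each
stage assumes, which parameters matter, and what the synthetic-data checks
do and do not demonstrate about real sections.

## Coordinate and unit conventions

Images are 2D grayscale arrays with an isotropic physical pixel size in
micrometres; anisotropic pixels are rejected. Pixel (r, c) occupies the
square [c·px, (c+1)·px) × [r·px, (r+1)·px) µm and has its centre at
((c+0.5)·px, (r+0.5)·px). All physical quantities are carried in µm (µm²
for areas, mm² only for densities and implant areas, mm/mm³ for caliper
data). Randomness always flows from explicit integer seeds through
`numpy.random.Generator`; independent substreams are derived with
`SeedSequence` so that adding a stage never perturbs another stage's draws.

## ROI geometry

**Segmentation.** The implant ROI is derived from the DAPI channel by
Gaussian smoothing (default σ = 20 µm, set to the scale that bridges
inter-nuclear gaps), Otsu thresholding, morphological closing (20 µm),
hole filling and retention of the largest connected component. Otsu always
returns *some* threshold, so an explicit contrast floor (default 0.05
intensity units between foreground and background means of the smoothed
image) turns "no implant present" into an error rather than a noise mask.

**Bands.** Depth from the implant edge is the Euclidean distance transform
of the ROI, in µm. Band k ≥ 1 covers depths [(k−1)Δ, kΔ) with Δ = 100 µm by
default. This is implemented by thresholding the distance transform rather
than by iterated morphological erosion: distance thresholding is isotropic,
calibrated exactly in µm, and equal to iterated erosion in the continuum
limit, whereas a pixel structuring element accumulates metric error on
diagonals. Bands therefore partition the ROI exactly — band areas sum to
the ROI pixel count, and area-weighted band fractions reconstruct the
whole-ROI fraction to machine precision, which the suite asserts.

**Core/outer split.** The 50 %-area split selects the cutoff depth d with
inner = {depth ≥ d}. Inner area is monotone non-increasing in d, so the
optimal cutoff over the observed depth values is found by direct scan of
the sorted unique depths (equivalent to bisection, but exact). The achieved
inner fraction must be within ±0.01 of the target; masks too thin to attain
that (e.g. one-pixel lines, where all depths tie) raise an error reporting
the best achievable fraction. For a disk of radius R the cutoff matches the
closed form R(1−√(1−f)) within one pixel.

## Intensity quantification

Thresholds (Otsu, triangle, or fixed) are computed over ROI pixels only, so
background outside the implant cannot bias them; the method and value used
are stored on the mask for provenance. Object counting uses 8-connected
components with a minimum area of 20 µm² (small enough to keep single
endothelial cross-sections, large enough to drop speckle; configurable) and
assigns objects to the core/outer region by centroid. Double-positive
(CD31⁺Podo⁺) objects are CD31 objects whose pixel overlap with the
podoplanin mask is at least 25 % of their own area — the rule is a
configurable fraction because object-based colocalization has no canonical
cutoff.

## Spot phenotyping

Spot detection is scale-normalised Laplacian-of-Gaussian filtering at the
nuclear scale (σ = 3 µm) with local-maximum extraction, a prominence cut
expressed in blob-amplitude units, and per-axis quadratic subpixel
refinement. Deduplication is greedy in decreasing intensity with ties
broken by (x, y) lexicographic order, keeping a spot only if it lies at
least 8 µm from every kept spot; the output is order-independent and all
pairwise distances among kept spots are ≥ the separation. Proximity rules
use strict `<` for the 8 µm spot–spot cutoffs and inclusive `≤` for the
2 µm surface rule, matching the asymmetry between "closer than" and
"within". The surface distance is the exact Euclidean distance from a point
to the union of positive pixel squares (zero anywhere on a positive pixel),
computed with a KD-tree prefilter; all neighbour queries are asserted equal
to all-pairs brute force. The Ki67 "effectively overlapping" call uses a
4 µm centre distance by default — a configurable convention, not a claim
about any particular instrument's internal rule. M1 and M2 are
non-exclusive flags gated on the macrophage call, so a CD68⁺iNOS⁺Arg1⁺ cell
counts in both; subclass counts can therefore never exceed their parent,
which is asserted on every construction.

## Morphometry

Volumes use the ellipsoid formula V = (π/6)·l·w·h by default (a box option
exists). The primary readouts are fold changes per implant relative to
timepoint 0, for which the formula constant cancels exactly — tested as an
identity. Outlier handling is optional median-absolute-deviation flagging
(3.5 scaled MADs within timepoint, off by default) that marks rather than
removes records, keeping exclusions auditable.

## Distance-trend mixed model

Band fraction records are fit by REML with fixed effects
group × timepoint × distance (all interactions; categorical group and
timepoint, linear distance in µm) and random intercepts for mouse and for
image replicate nested within mouse (variance components). Random slopes
are deliberately omitted: the replication per cell at desk scale cannot
identify them, and the scientific target is the population-level gradient.
Fractions are modeled on the identity scale (the gradients of interest live
well inside (0, 1)); a logit option exists for boundary-heavy responses.

Marginal slopes per group × timepoint cell are linear contrasts of the
fixed effects (design row at distance d+1 minus at d), with standard errors
from the fixed-effects covariance. Degrees of freedom use the residual
approximation df = n − p, recorded in the output as `"residual"`;
Satterthwaite-type df are not available in the fitting backend, and at the
default design (df ≈ 350) the difference is negligible — simulated 95 % CI
coverage over 200 datasets at the default design (two groups × two
timepoints, 3 mice/group, 3 replicates, 10 bands, mouse SD 0.02, replicate
SD 0.01, residual SD 0.02) is 95.0 %. Pairwise slope contrasts use the
studentized-range (Tukey) family over the k cells by default, with Holm and
unadjusted options; adjusted p-values are floored at the raw p-value.
Noise-free data is recovered exactly (≤ 10⁻⁶) because GLS reproduces an
exactly linear response regardless of the weighting.

## Synthetic scenes

The generator emulates the *structure* of implant-section data, not its
optics: cross-sections packed with ~70 µm particles, nuclear and marker
channels with configurable radial gradients and conditional marker
probabilities, and caliper series with configurable decay.

**Particles.** Diameters are truncated-normal (resampling non-positive
draws) with per-formulation defaults of 69.7 ± 2.25 µm (heparin) and
68.8 ± 1.87 µm (plain); the ± values are treated as population SDs. Packing
is random sequential addition of hard disks wholly inside the ROI; the
default count (100 in the default disk ROI, ~34 % area fraction) sits
comfortably below the RSA jamming limit (~0.55 for disks), and a stalled
packing raises an error reporting the achieved density. Exactly
round(N × heparin_fraction) particles are flagged heparin-containing
(default fraction 0.10, the 1-in-10 µisland mixing ratio). The sizing
operation rasterizes particles as disks and reports equivalent-circle
diameters of connected components, erroring if rasterized particles merge.

**Cells.** Cells follow an inhomogeneous point process with intensity
λ(depth) = intercept + slope·depth (default 1000 cells/mm² at the edge,
−1 cells/mm²/µm), truncated at zero nowhere by construction (negative
intensity anywhere is an error). A hard-core thinning enforces a minimum
spacing (default 9 µm, roughly one nuclear diameter in packed tissue):
without an exclusion distance a Poisson process at realistic densities
places several percent of nuclei closer than any detector — or the 8 µm
deduplication rule — can separate, which would make recovery failures a
property of the point process rather than of the pipeline under test. The
thinning slightly reduces realized density (≈ 9 % at defaults) and
flattens gradients where cells are dense; tests of pure Poisson properties
set the spacing to zero. Phenotype labels are drawn from the configured
class fractions (default 30 % macrophage, 15 % T cell, 20 % fibroblast,
5 % endothelial, remainder unlabeled) and marker flags are Bernoulli draws
conditional on the label (CD68|macrophage = 1, iNOS|macrophage = 0.5,
Arg1|macrophage = 0.4, CD3e|tcell = 1, CD4|tcell = 0.6, TE7|fibroblast = 1,
CD31|endothelial = 1, Podo|endothelial = 0.5, Ki67 = 0.2 everywhere).

**Rendering.** Each cell is a 2D Gaussian blob (σ = 3 µm, peak 1.0) splat
bilinearly at its subpixel position; marker blobs are jittered by a 0.5 µm
SD offset emulating imperfect chromatic/segmentation registration. The DAPI
channel additionally receives a uniform 0.15 fill inside the ROI,
representing the dim unresolved signal of tightly packed tissue — this is
also what makes DAPI-based ROI segmentation meaningful. Background is 0.1
with additive Gaussian noise of SD 0.05 (SNR 20 on blob peaks). The
generator does not model point-spread anisotropy, vignetting,
autofluorescence structure, section folds, or 3D effects; passing recovery
tests therefore demonstrates the correctness of the measurement logic under
the stated geometry and noise, not robustness to every artefact of real
slides.

**Calipers.** Implants start near 8 × 8 × 3 mm (≈ 100 µL as an ellipsoid,
5 % between-implant CV). Heights follow the configured height-fold curve;
the two lateral dimensions share the residual fold so the noise-free
volume fold equals the configured fold exactly (default 0.45 at 12 months,
i.e. a 55 % volume decrease; intermediate months 0.90/0.80/0.65 chosen as a
smooth decay consistent with that endpoint). Measurement noise is
multiplicative lognormal per dimension with mean exactly 1 (µ = −s²/2) and
CV 0.05, since caliper error on positive dimensions is roughly
proportional.

## Problem sizes

Default scenes are 768 × 768 px at 2 µm/px (a 1.54 mm field holding a
1.2 mm-diameter implant, ~800 cells) — large enough for six 100 µm bands
and stable phenotype fractions, small enough that the full suite (137
tests, including the 200-dataset coverage simulation and the 200-trial
oracle-equivalence sweep) runs in under a minute on one core. Scaling the
scene up changes only runtime; all conventions are resolution-independent.

## Known limitations

- Threshold choice per stain is a configuration, not an inference; no
  negative-control calibration is implemented.
- Spot phenotyping assumes markers present as point-like signals at the
  cell position; membranous or diffuse stains are better served by the
  surface rule.
- The core/outer split and bands assume a single connected implant
  cross-section; fragmented implants would need per-component analysis.
- The mixed model treats band fractions as homoscedastic Gaussian; for
  fractions near 0 or 1 use the logit option.
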