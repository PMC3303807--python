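# Methods

This note documents the models, parameter choices and numerical
conventions behind `emtscreen`, and what the synthetic-data tests do
and do not demonstrate.

## Coordinate and unit conventions

Pixel grids are indexed `(row, col)`, 0-based; the montage origin is
the top-left of field 0, with fields tiled 0 = top-left, 1 = top-right,
2 = bottom-left, 3 = bottom-right and no overlap. Physical positions
`(x, y)` are in micrometres with `x = col · pixel_size`,
`y = row · pixel_size` (sample-point convention: pixel index *i* sits
at `i · pixel_size`). The default pixel size is 1.6 µm/px, the scale at
which a 30 px disk spans 48 µm; a default field is 1000 × 1000 px, so
the 2 × 2 montage covers 3.2 × 3.2 mm. Concentrations are molar
internally and rendered in nM/µM in reports.

## Synthetic imaging model

The generator emulates the spot-migration assay geometry; its defaults
are the study conditions, fixed once:

* **T1 colony** — 2,500 cells, spreading coefficient 495 µm (a uniform
  disk of radius ≈ 700 µm, the footprint of a 0.5 µl droplet), hard-core
  minimum nucleus separation 10 µm.
* **T2, full dispersion (negative controls)** — CDR 2.2; **T2, full
  inhibition (positive controls)** — CDR 1.05; per-well lognormal
  variability of 3% CV on CDR and 5% CV on growth.
* **Growth** — CCR 2.0: each well roughly doubles overnight + 24 h;
  daughters are placed 1–2 hard-core radii from their parent.
* **Rendering** — nuclei are isotropic Gaussian blobs with
  σ = nucleus_radius/2 (default radius 6.4 µm ⇒ σ = 2 px), peak
  3000 ADU over a 100 ADU baseline; the background adds a smooth
  gradient plus a broad hump of 300 ADU amplitude; sensor noise is
  additive Gaussian with sd 300 ADU (10% of peak). Images are rendered
  as one montage then cut along the seams, so border-straddling nuclei
  appear partially in each field. Written TIFFs are single-channel
  16-bit.
* **Outliers** — 8 cells planted ≥ 80 µm from any colony cell,
  persisting at both timepoints.

Colony point sets are produced by dart throwing from the placement
model (uniform disk of radius sp·√2 or isotropic Gaussian with
σ = sp/√2), then finished by alternating projections onto three
constraints: one connected component at a 45 µm linkage radius (a
deposited epithelial colony is a contiguous sheet — and colony
isolation by 48 µm dilation presumes it), hard-core separation, and an
exact spreading coefficient via rescaling about the centroid. The same
relaxation restores the hard core after T2 division/dispersion, since
nuclei are impenetrable at both timepoints. Infeasible packings raise
an explicit error after bounded restarts. Dispersion at T2 is an
isotropic rescale about the colony centroid plus small jitter; the
assay quantifies dispersion only through sp, so any point process
matching sp serves.

Everything is deterministic given (specs, seed); per-well substreams
are derived by hashing `(seed, plate, well)`.

**What the generator does not emulate:** optics (no PSF beyond the
Gaussian blob, no depth of field), photobleaching, uneven illumination
beyond a smooth low-order background, nucleus size/intensity
heterogeneity, apoptotic debris, or directed (non-isotropic) migration.
Passing tests therefore demonstrate correctness of the measurement
chain under a faithful geometry and realistic SNR, not robustness to
every instrument artefact.

**Scaled test wells.** The test suite and the acceptance script run on
dimensionally scaled wells — 256 × 256 px fields at the same 1.6 µm/px,
200-cell colonies at sp 110 µm — preserving the full-scale assay's cell
density, SNR, CDR/CCR effect sizes and every code path, at roughly 1/60
the pixel count. This is the package's standard small-problem
configuration (`emtscreen.simulate.scaled_render`).

## Segmentation

* **Wavelet detection.** Undecimated à-trous transform with the
  B3-spline kernel `[1,4,6,4,1]/16`, dilated 2^(j−1)-fold at scale j.
  The image is extended by odd (anti-symmetric) reflection before
  filtering, which continues linear intensity trends exactly: smooth
  background gradients then produce no border response (plain mirroring
  creases at the border of a ramp). A pixel is foreground when any
  selected detail plane (defaults: scales 2 and 3, matched to nucleus
  radius at 1.6 µm/px) exceeds k = 3 robust noise sigmas
  (1.4826 × MAD), with an absolute floor of 1e−9 of the image range to
  keep round-off in analytically-zero planes out of the support. The
  per-scale union (rather than intersection) keeps nuclei packed inside
  dense colonies, where the coarser plane dips negative.
* **Core gating.** After labelling, a label must contain at least
  `min_nucleus_area/2` pixels significant at the finest selected scale;
  noise excursions of the coarse scale fail this and are dropped. On
  nucleus-free noise-only wells this leaves zero labels.
* **Watershed.** Seeds are local maxima (minimum separation 2 px) of
  the Gaussian-smoothed (σ = 0.8 px) *fine* band-pass (scales 1 + 2) —
  background-free, so peaks of touching nuclei stay separated — and
  flooding runs on the inverted surface within the mask with
  8-connectivity throughout. Markers and relabelling follow raster
  order, so plateau ties are deterministic.
* **Declumping.** Labels exceeding 1.8 × the median label area (and
  twice the minimum area) are split by a deterministic 2-means on pixel
  coordinates initialised at the extremes of the principal axis;
  repeated until stable. This separates touching nuclei whose mutual
  intensity dip is below the noise. The factor is conservative: in very
  dense wells footprints are Voronoi-clipped and a looser factor starts
  splitting genuine single nuclei.
* **Area gates.** Labels < 20 px² are removed (debris/noise);
  labels > 2000 px² are kept in the grid but flagged oversized and
  excluded from nucleus tables (they are field-border artefacts or
  contamination, not countable nuclei).
* **Stitching.** Field masks are offset to global labels; labels whose
  pixels are 8-adjacent across a seam are merged (union-find), so a
  nucleus straddling a seam is counted once. Seam merges of two truly
  distinct touching nuclei are accepted as the cost of never double
  counting. Centroids are recomputed on the stitched montage,
  intensity-weighted by default (`centroid_mode="geometric"` selects
  unweighted).

Measured on default-noise synthetic wells, nucleus recall is ≈ 97–98%
with ≈ 0% false positives (one-to-one matching within 5 px). Recall
drops to ≈ 94% in post-division positive-control wells, whose packing
approaches the hard-core limit; the dispersion measurements are
insensitive to this (CDR error stays below ~2%) because the misses are
spatially unbiased.

## Colony isolation and the spreading coefficient

The binary nucleus mask is dilated with a Euclidean disk of diameter
30 px — realised exactly as the set of pixels whose centre lies within
radius 15.0 via a distance transform — and connected dilated regions
become candidate colonies. The primary colony is the region with the
most member nuclei (not the largest area: cell number is the quantity
every downstream metric uses), with deterministic tie-breaks by pixel
area then lowest label. All other nuclei are outliers;
primary + outliers always partitions the detected nuclei.

`sp` uses the population (1/n) normalisation — the "standard deviation
of positions about the colony centre" taken literally — not Bessel's
n−1; at colony sizes of 10³ the difference is < 0.1%. sp is reported in
µm (pixels × pixel size); CCR and CDR are unit-free either way. A
single-cell colony has sp = 0; an empty well reports sp as missing with
an `empty_well` flag rather than raising mid-plate.

## Plate metrics and QC

CCR and CDR are plain T2/T1 ratios — the only reading under which a
growth threshold of "CCR ≥ 1.5" and "CDR ≈ 1 means no dispersion" both
make sense. CDR% is anchored so the **positive** control (full
inhibition) maps to 0% and the **negative** control (full dispersion)
to 100%; hits are then "CDR% ≤ 50". Values outside [0, 100] are
legitimate and flagged, never clipped. Controls are aggregated by the
per-plate arithmetic mean (median available as a robust option);
normalisation is within-plate only. The Z-factor uses sample standard
deviations and the absolute mean difference, so it is symmetric in the
groups; coincident control means report −∞ with a degenerate-plate
flag.

## Dose-response fitting

The 4PL is fit on log-dose by trust-region least squares with
deterministic initialisation: top/bottom from the extreme-dose means,
IC50 at the dose whose mean response is nearest the half-effect,
hill = 1. Asymptotes are free by default (optionally pinned to 100/0);
hill is bounded to (0, 20] and log-IC50 to ±4 decades around the tested
range. Preconditions: ≥ 4 distinct positive doses spanning ≥ 1 decade.
A fit is **censored** — IC50 reported as "> max tested" — when the
optimiser fails, the fitted span is < 10 CDR% points (flat or rising
response), or the IC50 lands beyond the highest tested dose.

## Combination index

Fraction affected is `fa = (100 − CDR%)/100`, so the CI at effect `fa`
compares doses at the response level `y = 100·(1 − fa)`. For a
fixed-ratio (r1 : r2) combination fit against *total* dose D,
`D1 = D·r1/(r1+r2)`, `D2 = D·r2/(r1+r2)`, and `Dx_i` inverts each
single-agent 4PL at `y`. Identities that pin the implementation: a drug
combined with itself gives CI = 1 at every ratio and effect level, and
a (1, 0) "combination" reduces to the single agent. Effect levels
outside the overlap of the fitted response ranges raise an error rather
than extrapolating.

## Design notes and limitations

* Hit calling is purely threshold-based (no p-values, hence no
  multiple-testing correction) — the screen's design, kept
  deliberately.
* Hit pooling: `call_hits` judges each (compound, growth factor) pair
  independently; compound-level shortlists count a compound once if it
  passes under any growth factor (`groupby("compound_id").any()`), and
  per-growth-factor tables remain available.
* The pipeline assumes one dominant colony per well. Wells whose
  largest region holds ≤ 1 nucleus are flagged `degenerate_colony`;
  empty wells are flagged and excluded from control aggregates.
* Oversized-label flagging, not removal, means gross contamination
  never silently inflates cell counts but remains visible in QC.
* Byte-identical rerun determinism holds for fixed inputs and
  configuration on a given platform (CSV floats are written with a
  fixed `%.10g` format); cross-platform bit-identity of the underlying
  floating-point pipeline is not guaranteed.
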