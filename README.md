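# emtscreen

High-content screening analysis for the **spot-migration EMT assay**:
quantify how strongly small-molecule compounds block growth-factor
induced epithelial–mesenchymal transition (EMT), read out as the
dispersion of a compact epithelial cell colony.

## The assay and the statistics

A 0.5 µl droplet of dense cell suspension (NBT-II cells with
fluorescently labelled H2B nuclei) is deposited at the centre of each
well of a 96-well plate, forming a compact colony of roughly 2,500
cells. Each well is imaged as four tiled, non-overlapping fluorescence
fields (a 3.2 × 3.2 mm montage at 1.6 µm/px) before compound treatment
(T1) and again 24 h after growth-factor induced EMT (T2). Cells that
undergo EMT scatter out of the colony; an effective inhibitor keeps the
colony compact without blocking growth.

Per well and timepoint the pipeline:

1. detects nuclei in each field with an à-trous B3-spline wavelet
   detector (robust to noise and inhomogeneous background) and splits
   touching nuclei with an intensity watershed,
2. stitches the four field masks into one well mask, merging objects
   split by a field seam,
3. dilates the nucleus mask with a 30 px (48 µm) disk so contiguous
   cells fuse into colony regions, keeps the region with the most
   nuclei (the primary colony) and discards outliers, and
4. measures the colony's cell count `#Col` and **spreading
   coefficient**

   `sp = sqrt( (1/#Col) · Σ_{c∈Col} [(c_x − Col_x)² + (c_y − Col_y)²] )`,

   the RMS distance (µm) of colony nuclei from the colony centroid
   `[Col_x, Col_y]`.

Combining timepoints gives per-well ratios

* **CCR** (cell count ratio) = `#Col(T2) / #Col(T1)` — growth/toxicity,
* **CDR** (cell dispersion ratio) = `sp(T2) / sp(T1)` — EMT scattering,
* **CDR%** = `100 · (CDR − CDR_pos) / (CDR_neg − CDR_pos)` — CDR
  rescaled per plate so positive controls (full inhibition) sit at 0%
  and negative controls (full dispersion) at 100%.

Downstream analytics: Z-factor plate QC
(`Z = 1 − 3(σ_pos + σ_neg)/|µ_pos − µ_neg|`, robust screens have
Z > 0.5), dual-concentration hit calling (a compound is a hit when
CCR ≥ 1.5 **and** CDR% ≤ 50 at both tested concentrations, 1.67 and
6.67 µM), four-parameter-logistic CDR dose-response fits
(`y = bottom + (top − bottom)/(1 + (x/IC50)^hill)`, censored as
"> max tested" beyond the dose range), and the Chou–Talalay combination
index `CI = D1/Dx1 + D2/Dx2` (CI > 1.1 antagonism, 0.9–1.1 additive,
0.2–0.9 synergism, < 0.2 strong synergism).

A first-class simulation module (`emtscreen.simulate`) generates
complete synthetic plates — images plus exact ground truth — so every
stage is testable without instrument data.

## Worked example

Simulate a small plate (two control columns, one potent and one inert
compound at two concentrations) and run the full analysis:

```bash
emtscreen simulate --layout layout.csv --config sim.yaml --seed 11 --out plate/
emtscreen run --manifest plate/manifest.csv --plate-map layout.csv --out results/
```

which prints

```
simulated 8 wells into plate
plate P1: Z-factor 0.679
1 hit(s); results in results
```

and writes `well_metrics.csv`:

```
well             role compound_id   CCR   CDR  CDR_pct
 A01 negative_control        DMSO 2.191 2.197  104.092
 A02             test       CPD_A 1.995 1.311   21.358
 A03             test       CPD_A 2.031 1.113    2.858
 A04             test       CPD_B 2.267 2.273  111.225
 A05             test       CPD_B 2.031 2.275  111.405
 A12 positive_control      AG1478 2.074 1.120    3.469
 B01 negative_control        DMSO 2.042 2.109   95.908
 B12 positive_control      AG1478 1.832 1.046   -3.469
```

Reading the numbers: every well roughly doubled its cell count
(CCR ≈ 2, no toxicity). The negative controls dispersed fully
(CDR ≈ 2.2 ⇒ CDR% ≈ 100) while the positive controls stayed compact
(CDR ≈ 1.1 ⇒ CDR% ≈ 0); their separation gives Z = 0.679, a robust
plate. `CPD_A` (simulated IC50 0.5 µM) suppressed dispersion at both
1.67 and 6.67 µM without inhibiting growth — CCR ≥ 1.5 and CDR% ≤ 50
at both doses — so it is called a hit; `CPD_B` (IC50 1 mM) left
dispersion at control level and is not. `hits.csv` records the
per-dose values behind each call.

Dose-response and synergy follow the same pattern:

```bash
emtscreen fit-dose --metrics dose_metrics.csv --out fits.csv
emtscreen ci --fit-a a.csv --fit-b b.csv --combo combo.csv \
             --ratios 1:4,1:2,1:1,3:1 --out ci.csv
```

## Layout

| Path | Contents |
| --- | --- |
| `src/emtscreen/simulate.py` | synthetic colonies, rendering, plate simulation |
| `src/emtscreen/segmentation.py` | à-trous wavelet detection, watershed, stitching |
| `src/emtscreen/colony.py` | dilation grouping, primary-colony selection, sp |
| `src/emtscreen/metrics.py` | CCR/CDR/CDR%, plate controls, Z-factor |
| `src/emtscreen/screening.py` | hit calling, 4PL IC50 fits, combination index |
| `src/emtscreen/platemap.py`, `pipeline.py`, `cli.py` | plate maps, config, orchestration, CLI |
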