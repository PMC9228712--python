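# specfuse

Chemometric quantification of a low-molecular-weight analyte in a serum-like
matrix by **mid-infrared + near-infrared data fusion**, built as a tested,
reusable pipeline with a synthetic-data generator standing in for laboratory
measurements.

## The problem

Serum is a high-dynamic-range matrix: abundant proteins (albumin ~35–50
mg/mL, immunoglobulins, transferrin) spectrally mask low-molecular-weight
analytes. This package implements the full analysis used to ask whether
combining two vibrational modalities — ATR-FTIR (fundamentals, 4000–800
cm⁻¹) and a handheld NIR spectrometer (overtones/combinations, 2500–1350 nm,
141 points) — lowers the limit of detection for such an analyte, using
glycine spiked into serum (0–50 mg/mL, 13 levels × 3 biological replicates,
20 spectra per sample and instrument) as the model system.

## The pipeline

1. **Simulation** (`specfuse.synthetic`): paired MIR/NIR absorbance spectra
   `A = M̃·(1+δ+m) + c·r·S + b + ε`, where `M̃` is a serum band model with
   per-spectrum band-amplitude heterogeneity, `S` the glycine band model
   (MIR: 906, 1036, 1111, 1330, 1414 cm⁻¹; NIR: 2110, 2204, 2375 nm),
   `c` the spiked concentration, `m` multiplicative scatter, `b` a random
   polynomial baseline and `ε` iid noise.
2. **Preprocessing** (`specfuse.preprocess`): Savitzky–Golay 2nd derivative
   (window 15, polynomial order 2), standard normal variate per block, then
   low-level fusion (column concatenation of the NIR block with the MIR
   fingerprint region 1800–800 cm⁻¹ ≙ 5556–12500 nm) and calibration-mean
   centering.
3. **Splitting** (`specfuse.split`): Kennard–Stone max–min selection on
   per-sample mean spectra — 26 calibration / 13 prediction samples
   (520 / 260 spectra), no replicate leakage.
4. **Calibration** (`specfuse.regress`): PLS1 via NIPALS (from scratch) and
   PCR via SVD; grouped venetian-blind cross-validation; RMSEC / RMSECV /
   RMSEP and prediction R².
5. **Detection limits** (`specfuse.lod`): replicate-based estimators
   `LoB = mean_blank + 1.645·SD_blank`, `LoD = LoB + 1.645·SD_low`
   applied to model-predicted blank and 0.01 mg/mL replicates.
6. **Experiment runner** (`specfuse.experiment`, CLI `specfuse`): the four
   model variants — NIR PLS (8 LVs), MIR PLS (10), fused PLS (10), fused
   PCR (10) — scored per seed into one tidy report.

## Worked example

```bash
python analysis/02_calibration_variants.py
```

prints, for the default simulated dataset (seed 0):

```
  variant  n_components  rmsec  rmsecv  rmsep  r2_pred   lob   lod
  NIR PLS             8  0.471   0.529  0.530    0.998 0.669 1.177
  MIR PLS            10  0.481   0.664  0.394    0.999 0.610 1.151
Fused PLS            10  0.342   0.376  0.309    0.999 0.326 0.618
Fused PCR            10  0.493   0.534  0.286    1.000 0.367 0.815
```

Read: each single instrument calibrates the series well (R² ≥ 0.998) but
detects glycine only above ~1.2 mg/mL; fusing the two blocks nearly halves
the detection limit (LoD 0.62 mg/mL) and gives the lowest prediction error
for PLS (RMSEP 0.31 mg/mL). `analysis/03_fusion_lod.py` repeats this over
25 seeds (median fused-PLS LoD 0.67 vs 1.15 mg/mL for the better single
block), and `analysis/04_blind_robustness.py` shows the fused model changes
its RMSEP by only ~7% when the lowest (0.01 mg/mL) level is excluded.

The same pipeline runs from the shell on simulated or externally measured
wide-CSV spectra:

```bash
specfuse simulate --out-dir data --seed 0
specfuse run --out-dir results/run0 --seed 0
specfuse report --report results/run0/report.csv
```

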