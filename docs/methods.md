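# Methods

## Scope

specfuse implements a complete chemometric quantification study: simulated
paired MIR/NIR spectra of an analyte spiked into a serum-like matrix,
derivative/SNV preprocessing, Kennard–Stone sample splitting, latent-variable
calibration (PLS, PCR), low-level block fusion, and replicate-based LoB/LoD
estimation. The simulator replaces laboratory measurements, so every claim
the package makes is about the modeled data-generating process, not about
any particular instrument.

## Generative model

One spectrum of sample `(donor r, concentration c)` on grid `x`:

```
A(x) = [ Σ_k (1 + η_k) B_k(x) ] · (1 + δ_r + m) + c · ρ · S(x) + b(x) + ε(x)
```

* `B_k` — serum matrix bands (Gaussian by default; Lorentzian available).
  MIR: amide I/II/III (1652/1545/1242 cm⁻¹), CH bend (1452), carbohydrate
  envelope (1080), C–H and amide A stretches (2930, 3290), plus a very broad
  positive envelope. NIR: protein combination bands at 2055 and 2180 nm,
  C–H structure (2290, 1730 nm), N–H/O–H overtone (1500 nm), broad envelope.
  Only the 2055/2180 nm placements are measurement-anchored; the MIR matrix
  uses literature-typical dried-serum positions.
* `η_k ~ N(0, matrix_heterogeneity_sd)` — per-spectrum, per-band relative
  amplitude jitter. Dried-film deposits are compositionally non-uniform
  between repeated scans, so band *ratios* vary, not just overall amplitude.
  This term is what gives the data structured, concentration-irrelevant
  variance: without it, ten principal components always span the informative
  subspace and PCR cannot trail PLS at equal component counts, contrary to
  what fixed-component comparisons on real serum data show. Default 0.05.
* `δ_r ~ N(0, replicate_effect_sd)` — per-donor matrix amplitude offset
  (shared by both instruments). Default 0.01.
* `m ~ N(0, scatter_sd)` — per-spectrum multiplicative scatter. SNV is
  scale-invariant, so scatter on the *matrix-plus-analyte* profile is only
  partially correctable and acts as an effective relative concentration
  error; at 5% it would floor RMSEP near 0.9 mg/mL over a 0–50 mg/mL
  series, far above the regime the study design targets (RMSEP ≈ 0.3,
  R² ≈ 0.999), so the default is 1%.
* `ρ` — analyte response, 0.01 AU per mg/mL at unit band amplitude. Glycine
  band amplitudes are set so the strongest MIR band (1330 cm⁻¹) reaches
  ~0.25 AU at the top 50 mg/mL level against ~1 AU of amide I, i.e. the
  matrix dominates throughout (the masking problem), and so that the two
  blocks are comparably informative — single-block detection limits for this
  pairing are observed to be close, and a fusion comparison is only
  meaningful in that regime.
* `b(x)` — per-spectrum quadratic baseline (Legendre basis, coefficients
  uniform within ±`baseline_amplitude`, default 0.02 AU). A second
  derivative of polynomial order 2 removes it exactly; it exists so the
  derivative step has something to do on raw spectra.
* `ε ~ N(0, noise_sd)` iid per point, default 1 mAU — typical of a
  128-scan FTIR average and a few-second MEMS-NIR integration.

Absorbance is clipped at zero after summation (physical non-negativity; with
the default parameters clipping is a rare tail event). Grids: NIR 141 evenly
spaced points over 1350–2500 nm; MIR 800–4000 cm⁻¹ at 4 cm⁻¹ spacing
(8 cm⁻¹ optical resolution with zero-filling factor 2). Identical
`SimulationConfig` (including seed) reproduces blocks bit-for-bit.

`LOW_NOISE_CONFIG` (noise 0.2 mAU, scatter 0.5%, donor effect 0.5%,
heterogeneity 1%) is used for robustness analyses whose conclusions should
not be noise-driven.

## Preprocessing

Fixed order per block: Savitzky–Golay 2nd derivative (window 15, polynomial
order 2, scaled by the block's native grid spacing) → SNV (row mean 0,
sample SD 1) → fusion → mean-centering on the calibration rows only.

* Derivative edges: the `window//2` columns at each end are replaced by the
  nearest valid interior value, keeping matrix width constant for fusion
  bookkeeping without extrapolated edge polynomials.
* SNV before fusion acts as implicit block scaling; SNV across a
  concatenated heterogeneous matrix would let one instrument's scale
  dominate.
* Fusion is plain column concatenation with a per-column provenance axis
  (modality, native value, nm equivalent); no resampling onto a common
  wavelength grid. Default windows: full NIR block, MIR fingerprint
  1800–800 cm⁻¹.
* The chain is deliberately not idempotent; the pipeline object refuses to
  transform an already-preprocessed block.

SNV has one consequence worth stating: dividing each spectrum by its own SD
makes the noiseless map from concentration to spectrum *nonlinear* (the SD
depends on the analyte level), so no linear calibration is exact under SNV
even without noise. Exactness checks therefore run the linear chain (SNV
off — there is no scatter to correct in that setting); with SNV on, recovery
quality is asserted statistically (prediction R² ≥ 0.99 at default noise).

## Splitting

Kennard–Stone on Euclidean distances between per-sample mean preprocessed
spectra; ties broken toward the lowest index. Selection at sample level
guarantees all replicate spectra of a sample stay on one side. Default
26/13 samples, i.e. 520/260 spectra at 20 spectra per sample. Because the
first picks are exterior points, the blank and the top level always enter
the calibration set on noiseless data.

## Calibration

* PLS1 by NIPALS with X (and y) deflation; unit-norm weights, orthogonal
  scores, regression vector `b = W(PᵀW)⁻¹q`. For a univariate response each
  component is closed-form. If X deflates to zero before the requested
  component count, a rank-deficiency error is raised; if the response
  residual becomes orthogonal to X, iteration stops with zero contribution
  from the remaining components. Degeneracy threshold 1e-10 relative to the
  input scale. The implementation is cross-checked against
  scikit-learn's `PLSRegression` in the test suite (agreement ~1e-14).
* PCR by SVD; response regressed on the leading score vectors.
* Cross-validation: venetian blinds over samples (fold j holds out samples
  j, j+10, …), grouped by sample id; one NIPALS pass per fold scores all
  component counts. Default components follow the study comparison: NIR PLS
  8, MIR PLS 10, fused PLS 10, fused PCR 10; the RMSECV curve on default
  simulations has its interior minimum at 9–10, consistent with that choice.
* Metrics: RMSE = √(Σ(ŷ−y)²/n); R² reported for the prediction set.

## Detection limits

`LoB = mean_blank + 1.645·SD_blank`; `LoD = LoB + 1.645·SD_low`, sample SDs
with n−1 denominator, applied to model predictions of all blank replicates
and all replicates of the lowest non-zero level (0.01 mg/mL by default).
Negative predictions are retained — clipping would bias the SDs downward.
The full CLSI-style multi-day/multi-lot protocol and nonparametric LoB are
out of scope.

## Problem sizes

Default analyses use the full design (780 spectra × 942 grid points per
block). The fusion comparison aggregates 25 seeds (≈6 s total); robustness
checks use 5 seeds of the low-noise configuration. All reported numbers in
the README are outputs of the committed analysis scripts.

## What the simulator does and does not establish

It reproduces the statistical structure the analysis assumes: linear Beer–
Lambert response on a dominant background, replicate grouping, two blocks
with independent noise and partially independent analyte signatures, and
enough structured matrix variability that component-limited models differ.
Passing tests therefore validate the *pipeline* — not any physical claim
about serum: no water-subtraction or drying physics, no Mie/EMSC-type
wavelength-dependent scatter, no instrument line-shape or wavelength-axis
drift, no heteroscedastic detector noise, and band amplitudes beyond the
positions quoted above are plausible choices, not measurements. Absolute
LoD/RMSEP values on real spectra will differ; the orderings the package
tests (fusion ≤ best single block; PLS ≤ PCR at equal components) are the
transportable claims.
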