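# Methods

`specphos` analyzes leaf hyperspectral reflectance as a proxy for plant
phosphorus status in a rice diversity panel, and post-processes genome-wide
association results for the derived spectral traits.  This note documents the
models, the synthetic-data generator that stands in for the measurement
campaign, the numerical choices, and the limits of what the bundled tests
demonstrate.

## Experimental design being modeled

A panel of rice accessions is grown hydroponically under three phosphate
supplies — P100 (320 µM NaH₂PO₄, overly sufficient), P5 (16 µM, mildly
deficient) and P0.25 (0.8 µM, severely deficient) — in randomized complete
blocks.  For each plant, leaf reflectance R_λ is measured on a 380–790 nm
grid at 2-nm steps (two technical replicates per leaf, averaged), and leaf
inorganic phosphate (Pi, nmol/mm²), shoot dry weight (g) and derived
phosphorus utilization efficiency (PUtE = biomass / Pi concentration in
mg/g) are recorded.  The 380–410 nm channels are unstable on the device
class modeled here and are excluded; analyses use 420–790 nm (186 channels).

## Spectral model

The central calibration model links a reflectance characteristic y (a single
band or a band ratio) to Pi through a constrained exponential decay

    y = a + b·exp(−c·Pi),    a ≥ −1,  c ≥ 0,  b free.

Reflectance changes sharply below Pi ≈ 0.1 nmol/mm² and saturates above
≈ 0.2 nmol/mm², which is exactly the shape of this law; c sets the Pi scale
of the sensitive zone, a the well-fed asymptote, and the sign of b encodes
direction (VIS reflectance rises under deficiency, b > 0; NIR falls, b < 0).
Points with Pi < 0.02 nmol/mm² are trimmed before fitting: at that level the
molybdate-blue Pi determination is dominated by assay noise.

Fitting uses bounded trust-region least squares with a three-point
multi-start on the decay rate (c₀/10, c₀, 10·c₀ with c₀ = 1/median(Pi)),
keeping the lowest residual sum of squares; the model is non-convex in c and
a single start can stall on the flat branch.  The parameter covariance comes
from the final Jacobian scaled by the residual variance (n − 3 dof); R² is
1 − SS_res/SS_tot and may be negative for pathological fits (reported as
computed).  A dense grid search over (a, b, c) serves as an independent
oracle in the tests: the bounded fit is never allowed a worse SS_res than
the best grid point.

Fits run at two levels.  *Individual*: every plant is a point.  *Accession*:
Pi and the response are first averaged within accession × treatment cells,
which removes plant-level scatter; accession-level R² is therefore
systematically higher.

## Ratio indices and screening

Band ratios R_NIR/R_VIS condense a spectrum into one number per pair of
bands.  The screening grid pairs 7 NIR bands (730…790 nm, 10-nm spacing)
with 31 VIS bands (420…720 nm): 217 indices.  Each is screened against
traits with Spearman rank correlation (robust to the nonlinear Pi link;
invariant to monotone transforms), computed on plants from the two deficient
treatments pooled — the P100 leaves carry vacuolar Pi stores that are
spectrally invisible, so including them only dilutes the signal.

For association mapping each index is summarized per accession as the
*mean-normalized SR trait*: the accession's mean ratio under P0.25 divided
by its mean ratio under P100.  A value of 1 means deficiency left that index
unchanged.  Means are computed per accession over plants pooled across
blocks (mean-of-ratios, not ratio-of-means), after technical-replicate
averaging.

## Deep models

Both network variants consume per-channel standardized spectra
(z-scored with statistics from the training split only):

* **Encoder** — two convolutional blocks (Conv1d + BatchNorm + ReLU; 16 then
  32 filters, kernel 8, same padding), average pooling (window 4, stride 3),
  flatten.
* **Head** — dropout (0.2), dense → 64, ReLU, dropout, dense → 3 softmax
  class probabilities (P100/P5/P0.25) or a single linear output for log₁₀ Pi
  regression.
* **Decoder (multi-task variant)** — dense layer from the flattened pooled
  features to 32 × ⌈L/4⌉ units, reshaped to (32, ⌈L/4⌉); two blocks of
  Conv + BatchNorm + ReLU + ×2 nearest upsampling (32 then 16 filters,
  kernel 8); final 1-filter convolution (kernel 4), center-cropped to the
  input length.  The decoder dimensions are derived from the encoder's actual
  pooled length at construction time rather than hard-coded, so the
  architecture is consistent for any input length.

Losses: categorical cross-entropy for classification; per-sample mean
squared channel error for reconstruction; the multi-task objective weights
them 1.0 and 0.5.  The implementation is plain numpy with hand-written
backpropagation (verified against central finite differences in float64) and
Adam; parameters are float32, the field's standard precision for networks of
this size.

Training protocol: mini-batches of 64, Adam at 1e-3, early stopping on the
validation loss of the *task head* (the reconstruction term is a
regularizer, not a selection target) with patience 20, up to 200 epochs.
One Gaussian-noise copy of each training spectrum is drawn fresh per epoch
with SD 0.01 in reflectance units — the noise is rescaled per channel by the
standardization SDs so that its physical magnitude is what the protocol
states; augmented samples never enter validation or test sets.  Regression
uses only P5 + P0.25 plants (adding P100 degrades it: the log₁₀ Pi range
becomes dominated by the inert vacuolar pool), with accession-grouped
splits so genetically identical plants cannot straddle train and test.
Stochastic comparisons are reported over 5 weight initializations.

### Grad-CAM

Attribution of a class logit (or the regression output) to wavelengths:
gradients of the target signal with respect to the last convolution block's
output are averaged per filter over positions; the filter maps weighted by
these averages are summed, rectified (only positively contributing regions
kept), interpolated to the input resolution if needed, and normalized to sum
to 1 per sample.  An all-zero map falls back to uniform attribution with a
log message.  Attribution runs in eval mode, so dropout cannot make maps
non-deterministic.

## GWAS post-processing

The mixed-model association scan itself is external; this package consumes
its per-SNP table (``chr, rs, ps, af, p_wald``) and applies the calling
rules: drop MAF < 0.05 (boundary kept); Bonferroni threshold on the −log₁₀
scale, −log₁₀(α/n_tests), which is 6.35 for the reference panel of 113,114
SNPs at α = 0.05 (boundary significant); single-linkage chaining of
significant SNPs within a 300-kb gap into loci (the grouping rule is
configurable; gap-based chaining was chosen over span-based and is flagged
in output metadata); lead SNP = lowest p, ties to the lower position; locus
names ``q<TRAIT><chr>[-k]`` ordered by position.  Candidate windows around a
lead SNP take SNPs within 100 kb *and* LD r² strictly above 0.50; pairs
missing from the LD table count as below threshold and are logged.
``naive_assoc`` (per-SNP OLS slope t-tests) exists so synthetic fixtures can
be run end-to-end; it has no kinship correction and must not be used on
structured populations.

## Synthetic-data generator

The generator is the package's test bed and defines its study conditions.

* **Pi distributions** — lognormal per treatment, parameterized to
  arithmetic mean ± SD of 3.60 ± 1.74 (P100), 0.22 ± 0.07 (P5) and
  0.07 ± 0.03 (P0.25) nmol/mm²; Pi is positive and right-skewed at high
  supply.  A per-accession multiplicative effect (log-SD 0.20) is carved out
  of the marginal spread, so treatment moments stay as configured while the
  data are hierarchical.
* **Spectra** — a fixed smooth leaf baseline (blue/red troughs, green bump,
  red edge, NIR plateau ≈ 0.45) plus the decay-law deviation
  b(λ)·exp(−c·Pi) with b > 0 over 500–725 nm (peaks at the green bump and
  red edge), b < 0 over 730–790 nm, and c = 12 per nmol/mm² — placing the
  sensitive zone below 0.2 nmol/mm², so severe deficiency reshapes the
  spectrum, mild deficiency barely does.
* **Nuisance variation** — accession, block and plant effects are linear
  combinations of three spectral shapes *distinct from the deficiency
  signature*: broadband albedo offset, linear tilt, and a (down-weighted)
  green-bump rescaling.  Technical replicate noise is i.i.d. Gaussian per
  channel (SD 0.004), with extra noise (SD 0.02) below 412 nm to emulate the
  device's unstable short-wavelength end.
* **Calibration** — the plant-level nuisance SD (0.02 reflectance units) was
  fixed at design time so the generated panel reproduces the screening-level
  behavior of the real campaign: Spearman ρ between the selected ratios and
  Pi ≈ 0.7–0.8 in pooled deficient treatments, accession-level decay R² in
  the 0.6–0.85 range, individual-level fits distinctly lower.  The
  individual-level R² here (≈ 0.4) is higher than in the real data (≈ 0.2);
  pushing plant noise high enough to match it destroys the screening
  correlations the generator must preserve, because this noise model has no
  heavy-tailed outliers or leaf-surface artifacts.
* **GWAS fixtures** — 0/1/2 genotypes in LD blocks bounded at 10 SNPs and
  200 kb (within-block redraw probability 0.1), MAFs uniform in [0.05, 0.5],
  additive planted effects plus Gaussian trait noise, and a pairwise r²
  table for same-chromosome SNPs within 300 kb.

What the generator does **not** emulate: senescence and leaf-surface
artifacts, heavy-tailed measurement errors, population structure and
kinship, epistasis, genotype-specific spectral responses to deficiency
beyond the shared decay law.  Passing tests therefore demonstrate that the
pipeline's operations are correct and well-calibrated on data with the
designed structure — not that the models would reach the same accuracy on
field data.

## Problem sizes

Tests and the acceptance script scale the experiments to a single CPU: the
screening/calibration stages run on the full 172 × 3 × 9-plant panel
(≈ 9,300 replicate spectra), network training on panels of 60–90 accessions
with 1–2 blocks (240–540 spectra), the multitask-vs-single comparison on a
élevé-noise panel of 360 spectra with a deliberately small training split
(90 spectra) and large test split (216) to stabilize the accuracy
difference, and GWAS fixtures of 2,000 SNPs × 172 accessions.

## Known limitations

* The multitask model's accuracy advantage over the single-task model is
  small and seed-sensitive on synthetic panels of this size; the generator's
  low-dimensional spectra make reconstruction too easy for the auxiliary
  objective to contribute much.
* ``naive_assoc`` p-values are anti-conservative under population structure;
  only the post-processing rules, not the association engine, are meant for
  real data.
* The decay fit reports the Jacobian-based covariance; for accession-level
  fits with few cells this underestimates uncertainty relative to a
  resampling estimate.
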