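# Methods

## Scope and data model

`micromrs` analyzes 1D ¹H spectra of single embryos / oocytes. A spectrum is
a strictly monotone chemical-shift axis δ (ppm, stored ascending; NMR's
descending-ppm convention is a display matter) with real intensities and
per-sample metadata. FIDs carry complex time-domain samples, the dwell time
(s/point) and the ¹H Larmor frequency (MHz); the ppm axis after FFT follows
from those two numbers plus the carrier position. Regions are closed ppm
intervals; a bin belongs to a region iff its center lies inside. The six
panel regions are PLC [0.83, 2.8], Saturate [1.1, 1.5], S1 [0.83, 1.03],
S3 [2.23, 2.36], SaturateL [1.3, 1.5] and SaturateR [1.1, 1.3]; SaturateL and
SaturateR partition Saturate at the bulk-methylene line (1.30 ppm), and
"right" refers to the upfield half (the right-hand side when plotted with
descending ppm).

## Preprocessing

- **FID → spectrum.** Exponential apodization `exp(-π·lb·t)` (adds `lb` Hz of
  Lorentzian width), zero-filling (×1/2/4), FFT. Default output is the
  phased-real part with the zero-order phase chosen to maximize the integral
  over the lipid (PLC) region — with no first-order term this reduces to the
  analytic angle of the region's complex sum. Magnitude mode is a flag. The
  acquisition literature behind this instrument class does not pin the mode;
  phased-real preserves Lorentzian lineshape math, which the biomarkers rely
  on.
- **Referencing.** The water line is unsuppressed and dominates every
  spectrum, so the axis is rigidly shifted to put the global maximum at
  4.70 ppm (configurable). Ties break toward higher ppm with a warning. The
  shift snaps the argmax bin exactly onto the reference, making the operation
  idempotent.
- **Baseline.** A constant offset — the median over a signal-free window
  (default 9–10 ppm) — is subtracted. No polynomial or first-order phase
  correction is attempted (out of scope).

## The 14-biomarker panel

Each biomarker is a (region, statistic) pair, in fixed order: six intensities
(PLC, Saturate, S1, S3, SaturateL, SaturateR), three skewnesses (PLC,
Saturate, SaturateR), three kurtoses (PLC, Saturate, SaturateR), and the
amplitude and FWHM of a Lorentzian fit in the Saturate window. Conventions
that matter:

- Negative intensities are clipped to zero before integrals and moments;
  weights must be non-negative, and baseline noise dips would otherwise
  corrupt the moments.
- Skewness and kurtosis are **moments of chemical shift weighted by
  intensity** — lineshape descriptors — not moments of the intensity values.
  Higher kurtosis therefore means a sharper spectral profile. Kurtosis is
  Pearson (non-excess): a flat profile gives exactly 9/5, which the tests
  assert analytically.
- "Intensity" is the trapezoidal integral (not mean or max) of the clipped
  lineshape over the region; the alternatives are switchable in code but the
  integral is the default everywhere.
- The Lorentzian fit is single-peak-plus-constant-offset
  (A·γ²/((δ−δ₀)²+γ²) + c), initialized at the region argmax with γ from the
  half-max crossings, bounded least squares (amplitude ≥ 0, γ within 5× the
  region span). Non-convergence or a γ at its bounds yields NaN values and
  `converged=False`; downstream ML imputes with the *training-fold* median so
  the leakage guarantees survive missing values.
- QC per sample: SNR = saturate-region peak maximum ÷ SD of the 9–10 ppm
  window; linewidth = the Saturate-fit FWHM.

Raw integrals are reported without water normalization: the study design
treats water only as a frequency reference, and the large between-sample
intensity spread is itself informative. A `normalize="water"` switch (CLI
`--normalize water`) divides the scale-carrying values (intensities,
Lorentzian amplitude) by the 4.4–5.0 ppm water integral for workflows that
want a concentration-like scale.

## Cohort statistics

For each biomarker, both cohorts pass through a Lilliefors normality gate at
α = 0.05: the KS distance to the normal with estimated mean/SD, with a
seeded Monte-Carlo null (5 000 replicates, parameters re-estimated per
replicate) rather than table lookup. If both cohorts look normal, Welch's
unequal-variance t-test; otherwise a two-sided Mann-Whitney U. The U test is
an exact tie-aware enumeration over all C(n+m, n) rank splits when both
groups have ≤ 10 members (groups of 3 cannot support a normality test and
default to the exact U), and scipy's tie-corrected normal approximation
otherwise.

## Classification pipeline

Leave-one-out CV with a hard leakage contract: each fold fits a standardizer
on its 60 (or 101) training rows, SMOTE-balances the minority class up to the
majority count in standardized space (k = 5 neighbors, auto-reduced to
n_minority − 1), fits a full-rank PCA on the balanced standardized matrix,
and trains an RBF SVM (C = 1, gamma = "scale") on the PC scores. The held-out
row is transformed with the fold's frozen scaler and PCA and scored — never
refit — and synthetic rows never appear among held-out predictions
(structurally impossible and asserted in tests). An alternative order (PCA
before SMOTE) is available behind `pca_before_smote`; the default follows
the standardize → SMOTE → PCA order.

Determinism: training rows are processed in id-sorted order and each fold's
RNG is seeded from SHA-256(master seed, held-out id), so per-sample
predictions are invariant to row order and to cohort re-assembly.

Metrics pool the held-out predictions into one confusion matrix (positive
class = DEV/MAT): accuracy, balanced accuracy, sensitivity, specificity,
precision, NPV, F1, plus ROC AUC computed by the Mann-Whitney rank
formulation on the held-out SVM margins with tie midranks. Undefined ratios
(e.g. precision with no predicted positives) are NaN with a flag, never 0.
The dummy baseline predicts the majority class with one constant score, which
forces AUC = 0.5 exactly under midranks.

The PC1/PC2 scatter and the loading matrix are exploratory views:
whole-dataset standardize → SMOTE → PCA, explicitly non-inferential, with a
deterministic sign convention (each component's largest-|loading| entry is
positive).

## Shapley attribution

Model interpretation uses exact interventional Shapley values on the PC
features of a pipeline refit on the full dataset (fold-wise attribution is
available via `model_and_scores`). The value function v(S) replaces the
features outside S with background rows and averages the SVM margin; all 2ⁿ
coalitions are enumerated (n ≤ 16 enforced), so efficiency, symmetry,
linearity and null-player hold to numerical precision — there is no sampling
approximation to reason about at 14 features. The background defaults to a
seeded 16-row subsample of the dataset to bound the 2ⁿ×|background| batch; a
`None` background size uses every row. PCs are ranked by mean |φ| and the
top-ranked PC is mapped back to biomarkers through its largest |loading|.

## Synthetic-data generator

The generator is the package's study-condition model, not a test fixture. A
sample is a sum of Lorentzian resonances with standard fatty-acid ¹H
assignments — terminal CH₃ 0.90, bulk (CH₂)ₙ 1.30, β-carboxyl 1.59, allylic
2.02, α-carboxyl 2.28, water 4.70 ppm — plus two weak "methylene satellite"
lines at 1.20 and 1.40 ppm (amplitude 0.08 of the main line, fixed 0.08 ppm
width) that model unresolved methylene packing heterogeneity flanking the
main envelope. Exact amplitude ratios of single-embryo lipid spectra are not
published in accessible form; the table is configuration, not code.

Per-sample draws (one RNG stream per sample, spawned from the master seed,
so cohorts are bit-reproducible and order-invariant):

- global intensity scale: log-normal with σ = 0.57, calibrated so the
  expected max/min PLC-intensity ratio across a ~61-sample cohort is ≈ 13
  (E[max z] ≈ 2.25 for n = 61 standard normals ⇒ σ ≈ ln 13 / 4.5). The
  expected ratio grows with cohort size — ≈ 23-fold would be typical at
  n = 200 — so the 13-fold figure is tied to the 61-sample design;
- per-peak amplitude jitter: log-normal compositional variability, larger
  for chain-end/unsaturation resonances (σ = 0.40) than for the methylene
  envelope (σ = 0.15) — lipid composition varies more between samples than
  bulk chain content;
- per-peak FWHM: truncated normal (0.12, 0.04, lower bound 0.02 ppm),
  rejection-sampled (≤ 100 attempts);
- target SNR: truncated normal (22, 8, lower bound 3); the additive white
  noise SD is back-computed as (noiseless saturate-region maximum)/SNR, so
  the *measured* SNR estimator closes the loop on the configured
  distribution (the measured mean runs ~5–10% above target because the
  maximum of signal-plus-noise exceeds the clean maximum);
- a rigid referencing error (SD 0.03 ppm) that the water-referencing step
  must undo.

Cohort effects are multiplicative: `saturate_amp_multiplier` scales all
Saturate-region amplitudes, `s1_amp_multiplier` the S1 region,
`plc_skew_shift` rigidly moves the lipid resonances, and
`saturate_r_width_multiplier` broadens the satellite pair (the off-center
Saturate resonances). The satellites broaden symmetrically about the main
line, so whole-window skewness stays balanced while the panel — which takes
lineshape moments of the upfield half only — registers the effect as a drop
in Kurt-SaturateR; their small amplitude keeps the Saturate Lorentzian fit
anchored to the main line so the linewidth QC stays calibrated. This is the
generator's mechanism for the observed association between developmental
competence and low right-saturate kurtosis.

Preset `embryo61` (54 ARR / 7 DEV) gives the DEV class saturate amplitude
× 2.5, satellite width × 6 and S1 × 1.5 — strong effects sized so that a
61-sample LOOCV run separates the classes clearly (AUC > 0.9), consistent
with the strong clustering the study reports at this sample size. Preset
`oocyte102` (63 IMM / 39 MAT) gives MAT saturate amplitude × 2.0 (sized so
the Saturate-Int comparison reaches p < 10⁻⁴ at n = 102, the significance
level reported for that contrast), satellite width × 0.8, S1 × 1.3 and a
−0.01 ppm shift. `null_effect_config` strips all effects for sentinel runs.

### What the generator does and does not emulate

It reproduces the documented *statistics* of single-sample spectra —
linewidth and SNR distributions, intensity fold-spread, class imbalance,
cohort effect directions — on an idealized Lorentzian basis with white
noise. It does not model coil sensitivity profiles, temperature drift, shim
inhomogeneity beyond the linewidth spread, baseline roll, J-coupling
multiplets, or chemical-shift crowding from non-lipid metabolites. Passing
tests therefore demonstrate that the *analysis machinery* is correct and
leakage-free under realistic statistical structure; they do not certify
classifier performance on real embryo data.

## Numerical and design choices

- Tolerances: noiseless Lorentzian recovery asserted at 1e−6 relative;
  Shapley efficiency at 1e−8; PCA orthonormality at 1e−10; analytic
  region-statistics checks at grid-discretization level (the 4096-bin axis
  puts ~0.0024 ppm per bin).
- The LOOCV sentinel: with 7 positives the null-AUC sampling SD is ≈ 0.12,
  so single-seed values legitimately stray outside [0.3, 0.7]; the sentinel
  asserts the 20-seed mean stays in that band and no seed shows the ≈ 0.9+
  optimism a leaking pipeline produces.
- Degenerate inputs: single-member minority classes abort LOOCV (a fold
  would train on one class); SMOTE with one minority row duplicates with a
  warning; all-zero regions raise rather than return silent zeros.
- Problem sizes: calibration checks use 200-spectrum cohorts; sentinel and
  recovery checks use the 61-sample embryo shape; attribution tests use a
  12–16-row background. These sizes give stable statistics while keeping a
  full test run inside a few minutes on one core.

## Known limitations

- The exact SI-table biomarker definitions and per-peak amplitude ratios of
  the original instrument's spectra are approximated by configurable
  defaults; the registry and peak table accept overrides.
- Single-Lorentzian-plus-offset is the only fit model; overlapping-peak
  deconvolution is out of scope.
- With 7 positive samples, fold-level point metrics (sensitivity, precision)
  have large sampling variance; the panel plus AUC should be read together.
- The balanced-accuracy field follows its standard definition
  ((sensitivity + specificity)/2); published panels sometimes compute it
  differently, and no attempt is made to reconcile alternatives.
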