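# Methods

## Feature-matrix construction

Each sample is a set of centroided positive-mode MS1 scans. Scans with
retention time in the closed interval [0.8, 1.0] min — the flow-injection
plug — contribute; peak intensities are summed into half-open m/z bins
`[lower, lower + 0.01)` Da over [250, 1300), i.e. 105,000 bins. The bin
index is `floor((m/z − 250 + 1e-9) / 0.01)`; the 10⁻⁹ Da guard absorbs
float representation error at bin boundaries, and a peak exactly on a
boundary belongs to the bin whose lower edge it is (a peak at exactly
1300.00 falls outside the last bin and is excluded, with a logged count).
The half-open convention makes bin assignment exactly invertible. Columns
are ordered by injection order; the raw matrix is stored sparse, but every
contract is value-wise and independent of storage. Binning conserves
intensity: the column total equals the in-window, in-range peak total to
1e-6 relative.

Raw matrices can also be ingested directly from TSV/CSV/XLSX tables
(first column = bin m/z), bypassing binning, for externally produced
feature matrices.

## Normalization chain

Applied strictly in order, enforced by a stage tag on the matrix:

1. **Sparsity filter** — a bin is kept iff `nonzero_count / n_samples ≥
   0.01`. The comparison is inclusive ("at least 1%"): with 180 samples the
   threshold is 1.8, so a bin needs ≥ 2 nonzero samples.
2. **TIC normalization** — each column is divided by its sum; columns then
   sum to 1 ± 1e-9. This removes per-sample total-lipid-load differences
   and, with it, any *global* per-sample or per-batch scale factor.
3. **log₂ transform** — `v → log₂(v + ε)`, ε = 10⁻¹⁰, so zeros map to
   ≈ −33.22 rather than −∞. ε is recorded on the matrix so later stages can
   map back to the linear scale as `2^v − ε`.
4. **Batch correction** — per feature, an intercept-plus-batch linear model
   with sum-to-zero contrasts is fitted by least squares and the fitted
   batch terms are subtracted (the `removeBatchEffect` algebra; a test
   cross-checks against the R limma implementation on an unbalanced
   design). The one-way model is saturated, so corrected values equal
   `y − (batch mean − unweighted mean of batch means)` per feature for any
   design; the sum-to-zero intercept is preserved to 1e-8 and balanced
   designs end with equal per-feature batch means. A single batch is the
   identity (with a warning); correction uses batch vectors only, no
   additional covariates.
5. **Top-median selection** — exactly `n_keep` bins with the largest
   per-bin medians are retained, ties at the boundary broken toward the
   lower m/z edge, row order preserved, values untouched.

Batch vectors come either from explicit metadata (the repeat-injection
series of the reproducibility design: 5 batches of 18) or from consecutive
injection blocks (30 consecutive samples per batch: 6 batches of 30 for
the 180-sample cohort).

`n_keep` is an explicit parameter because "top ~10% of medians" of the
surviving bin set is design-dependent: on a real instrument some 3–4×10⁴
bins survive the 1% filter (n_keep 3000–4000); the synthetic default of
500 lipid peaks leaves ~500 bins, for which the package's demo and
acceptance configurations keep 400 (~80%), enough to retain most of the
injected-effect bins.

## %RSD reproducibility

`%RSD = 100 · sd(values, ddof=1) / mean(values)`, a linear-scale intensity
CV. Intrabatch: %RSD across the six technical replicates within each batch
independently (5 batches); interbatch: %RSD across the five repeat
injections of each replicate independently (6 replicates); per region, all
per-(bin, group) values are pooled and summarized by their median.
Zero-mean bins yield non-finite %RSD and are excluded from the median with
a logged count.

**Scale decision.** %RSD is computed by default on the linear
TIC-normalized values (fractional ion counts) restricted to the
top-selected bins — i.e. *before* batch correction. The reason is
structural: the replicate design is balanced (every replicate in every
batch), so the least-squares correction removes per-feature batch means
exactly; after that, the interbatch residual variance is mathematically at
most the intrabatch variance (removing the batch mean leaves (5/6)σ²
across batches versus σ² within a batch). An interbatch median *above* the
intrabatch median — the signature of real batch-to-batch drift — is
therefore only observable on a scale where batch effects survive. The
post-correction scale remains available (`scale="final"`), and empirically
shows the predicted collapse (interbatch ≤ intrabatch).

For the same reason, a *global* per-batch multiplier is invisible after
TIC normalization (every peak in a column scales together), so the
generator's batch model includes per-peak batch drift (below). The pooled
intrabatch median sits slightly below the injected CV (≈ 2.8% for a 3%
CV): the median of a 6-replicate sample-SD estimate is biased a few
percent below the population SD.

## Donor-exclusion LOOCV

One split per sample; the training set excludes *all* samples from the
test sample's donor, so donor identity cannot inflate accuracy. Folds
sharing a test donor have identical training sets, so one booster is
fitted per donor and predicts all of that donor's samples — predictions
are identical to the per-sample loop. Hyperparameters are fixed and not
optimized (gbtree, binary:logistic, η 0.3, γ 0, max_depth 6,
min_child_weight 1, subsample 1, colsample_bytree 1, 50 rounds); fitting
is single-threaded with an explicit seed and the `hist` tree method, so
repeated runs are bit-identical. Accuracy is the percentage of samples
whose out-of-fold probability, thresholded at 0.5 (ties counted as
positive), matches the truth. The ROC pools all out-of-fold probabilities,
thresholds in descending order with ties grouped, and the AUC is the
trapezoidal area — equal to the pair-counting statistic
P(score⁺ > score⁻) + ½ P(equal), which a test verifies to 1e-12.

On null data this design has a small *pessimistic* bias (removing a donor
leaves the training set slightly imbalanced against the test label), so
null AUCs center slightly below 0.5 with a wide spread at 30 donors
(roughly ±0.1 across cohorts); the mean over ≥50 label permutations stays
within [0.45, 0.55].

## PCA and concentration ellipses

Samples × features data are mean-centered but not variance-scaled (inputs
are already log-scale and batch-corrected; scaling is available as a
switch). Scores are projections onto the top right-singular directions,
with each component oriented so its largest-magnitude loading is positive.
Per group, a normal-probability ellipse is computed from the 2×2 score
covariance: semi-axes `sqrt(λᵢ · χ²₂(level))` along the eigenvectors,
level 0.95 by default (an isotropic unit-variance group gives a circle of
radius ≈ 2.4477). Degenerate covariances warn and floor the axes at zero.

## Synthetic cohorts

The generator emulates two study designs: a variability cohort (30 donors,
half male/half female, three grooming regions, two fingerprints per donor
per region = 180 samples, six consecutive-block MS batches) and a
reproducibility design (one donor, six technical replicates per region,
each injected once into each of five MS batches = 90 spectra).

Per-peak intensity of a sample:

```
baseline × 2^(donor + region + sex) × batch_global × batch_peak × tic × (1 + noise)
```

truncated at zero, with:

- 500 lipid peaks, m/z uniform in [250, 1300), baselines log-normal
  (log₂ mean 17, SD 2) — a heavy-tailed abundance distribution;
- region effect: neck shifts 20% of peaks by +1.0 log₂ unit; cheek and
  forehead share the baseline profile (defaults chosen to mirror the
  observed pattern that neck profiles differ while cheek/forehead do not);
- sex effect: 0 by default (the null reference scenario); a nonzero log₂
  shift on 20% of peaks can be enabled for power exploration;
- donor offsets: per-donor per-peak N(0, 0.3²) log₂ — between-donor
  lipidome variation (no published variance estimate exists; 0.3 log₂
  units ≈ 23% CV is a plausible biological scale);
- batch effects: optional global per-batch multipliers (default 1) plus
  per-peak per-batch log-normal drift with CV 0.04 — the m/z-dependent
  response drift that TIC normalization cannot remove;
- per-sample total-load factor: log-normal, σ = 0.25 (the vial's lipid
  concentration; constant across a replicate's repeat injections);
- technical noise: multiplicative Gaussian, CV 0.03, drawn per peak per
  injected spectrum. Noise is applied at the sample level and the sample's
  intensity is then split over the in-window scans with fixed fractions
  (0.3/0.4/0.3); per-scan independent noise would shrink the binned-sum CV
  by √3 and decouple the noise parameter from the %RSD it is meant to
  calibrate.

Each sample emits five scans: three inside the 0.8–1.0 min window and two
outside (at 0.50 and 1.30 min, carrying 5% of the intensity each), so the
retention-time filter is always exercised. Emitted values are rounded to
the MS1 text precision, making the MS1 and mzML renderings numerically
identical and whole runs byte-reproducible from (config, seed).

What the generator does **not** model: isotope envelopes, adducts, charge
states, chromatographic structure, instrument resolution or centroiding
error, missingness beyond the intensity floor, and donor-level covariance
between peaks (offsets are independent across peaks). Passing tests
therefore demonstrate the pipeline's algebra and its behavior under the
modeled effect/noise structure — not performance on real spectra, where
peak density, correlated drift, and m/z calibration error are harsher.

## Problem sizes and numerical choices

Tests and the acceptance script run the full designs (90 and 180 samples,
105,000 bins, 400 retained) — the synthetic profiles are sparse enough
that this is fast. Tolerances: binning conservation 1e-6 relative; TIC
column sums 1e-9; batch-correction algebra 1e-8; AUC identity 1e-12.
Determinism is exact: same config and seed give byte-identical generated
files and bit-identical pipeline outputs.

## Known limitations

- The %RSD scale decision (pre-correction default) is an interpretation;
  both scales are exposed, and the choice matters exactly when batch
  effects are present.
- Donor-exclusion LOOCV accuracy/AUC on small cohorts is noisy and
  slightly pessimistic under the null; single-cohort AUCs should be read
  with ±0.1 uncertainty at 30 donors.
- Gradient-boosting outputs are deterministic for a fixed library version
  but may drift by a percent or two across XGBoost releases.
- No lipid annotation: bins are m/z intervals, never assigned identities.
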