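# Methods

## Scope and data model

The package operates on NN-interval (cleaned RR-interval) series in
milliseconds, one series per subject per training stage, and on grouped
feature tables (one row per subject: stage label + numeric features). Beat
onset times are derived as cumulative interval sums in seconds. Recordings
of roughly 5–15 minutes are the intended regime; the generator default is
300 s.

Artifact filtering (not part of the scientific contribution, but required in
practice) removes intervals outside [300, 2000] ms or differing from the
previous retained interval by more than 20 % — conventional HRV
preprocessing defaults, overridable per call and via config. The filter is a
single forward scan and is idempotent.

## Time-domain indices

SDNN and SDSD are sample standard deviations (N−1 denominator) of the
intervals and of the successive differences respectively; RMSSD is the root
mean square of successive differences; pNN50 uses a strict |Δ| > 50 ms
threshold. RMSSD is sometimes verbally described as a "mean square
deviation"; the standard root-mean-square definition is implemented. Note
that with the N−1 convention SDSD can slightly exceed RMSSD when the mean
successive difference is near zero; the exact relation
sdsd² = (n/(n−1))(rmssd² − mean(Δ)²) is asserted in tests.

## Frequency-domain indices

The tachogram is mean-removed and its PSD estimated on a regular frequency
grid (default step 1 mHz) covering (0, max(0.40 Hz, pseudo-Nyquist)], where
the pseudo-Nyquist is half the mean beat rate. Two estimators sit behind
`SpectralConfig.method`:

- **`lomb_scargle`** (default): the Lomb–Scargle periodogram on the uneven
  beat times — RR series are inherently unevenly sampled, so no resampling
  distortion. The raw periodogram is rescaled so that its trapezoidal
  integral over the grid equals the variance of the detrended tachogram;
  this fixes the units to ms²/Hz and makes band powers sum to the total
  power. Band ratios (normalized units, LF/HF) are independent of this
  normalization choice.
- **`resample_welch`**: cubic-spline resampling at 4 Hz followed by Welch's
  averaged periodogram (density scaling, ms²/Hz directly).

Band edges default to the universal short-term convention VLF 0.0033–0.04,
LF 0.04–0.15, HF 0.15–0.40 Hz and are configurable. Band powers are
trapezoidal integrals over the grid points inside each band;
LF n.u. = 100·LF/(LF+HF) and HF n.u. = 100·HF/(LF+HF) sum to 100 by
construction. When LF+HF (or HF) power is zero the normalized units (or the
ratio) are reported as NaN rather than a number. A constant series yields an
all-zero density; recordings shorter than twice the period of the lowest
requested band edge carry a warning on the PSD result.

Shifting all intervals by a constant changes the beat times slightly, so
spectral invariance to level shifts is approximate (mean removal makes it
hold to ~1 % on band fractions), whereas the time-domain ms indices are
exactly scale-equivariant.

## Distance-evaluation weighting

Given classes y = 1..Y with N_y ≥ 2 samples and M features, the chain is:
per-class mean u_{y,m} and sample SD δ_{y,m}; ordered-pair absolute
distances within each class with mean d_{y,m} and SD τ_{y,m}
(N_y(N_y−1) − 1 denominator); within-class term clt_m^inner = mean_y δ_{y,m}
with compensation factor f_m^inner = max_y δ / min_y δ; a between-class term
clt_m^outer with factor f_m^outer; and the weight

η_m = [1/(f_m^inner/max_m f^inner + f_m^outer/max_m f^outer)] · clt_m^outer / clt_m^inner.

Design points that were genuinely open and how they were resolved:

- The within-class pairwise difference is taken in absolute value: the mean
  of *signed* differences over all ordered pairs is identically zero, which
  would degenerate the distance d.
- Two between-class variants are provided. The default, `center_distance`,
  uses the mean and max/min of |u_{y,m} − u_{c,m}| over ordered class pairs,
  which matches the method's intent (a cleanly separated feature scores
  high). The literal variant `as_printed` uses the RMS and max/min of
  |τ_{y,m} − τ_{c,m}|, i.e. dispersion of within-class scatter across
  classes; it is kept because it is the formula as published, but it assigns
  zero separation to a perfectly separated feature with equal class spreads.
  Neither variant is claimed to be "what was originally run"; both are
  oracle-tested.
- All min-denominators are guarded by eps = 1e−12 so zero-variance features
  produce finite weights; if every η_m is zero the normalized weights are
  all zero and a warning is raised.
- Weights are max-normalized (η_norm = η / max η) because the classifier
  needs a (0, 1] multiplier scale; the raw η is also reported.
- Unequal class sizes are permitted throughout (the formulas never require a
  common N).

Useful invariants, all tested: permutation invariance (within classes and of
class order), per-feature scale invariance of η (the clt ratio cancels the
scale), and monotonicity of η_norm in the class-mean gap.

## Weight-modulated boosting

Standard second-order gradient boosting (binary logistic for 2 classes,
one-vs-all softmax for ≥ 3; exact greedy split search over midpoints of
adjacent observed values; leaf value −G/(H+λ); shrinkage applied per tree)
with one modification: a candidate split on feature m has its gain

gain = ½ [G_L²/(H_L+λ) + G_R²/(H_R+λ) − G²/(H+λ)]

multiplied by η_norm_m before it is compared against other candidates and
against the minimum-gain threshold γ (strict inequality). Consequences that
define the semantics, and are asserted in tests: uniform weights reproduce
unweighted boosting bit-for-bit; a zero-weight feature never appears in any
split; decreasing a feature's weight never increases its split count.
Ties between equal weighted gains are broken by lowest feature index, then
lowest threshold, so fitting is deterministic given data order. An
alternative integration (feature-sampling probability proportional to η)
was considered and not implemented — the gain multiplier is deterministic
and reduces exactly to the unweighted model.

Defaults: 100 trees, depth 3, learning rate 0.1, λ = 1, γ = 0, min 2
samples per leaf. No subsampling, histograms, early stopping or GPU paths —
the target tables are tens to low hundreds of rows. Models serialize to a
documented JSON tree schema. Stratified k-fold cross-validation assigns each
class round-robin over shuffled folds and recomputes feature weights inside
each training fold only, so no held-out information leaks into the
weighting.

## Stage statistics

Classic fixed-effects one-way ANOVA: F = MSB/MSW with (k−1, Σn_i−k) degrees
of freedom and p from the F distribution. The summary-statistics route uses
SSW = Σ(n_i−1)·sd_i² and SSB = Σ n_i(mean_i − grand mean)² and is
algebraically identical to the raw-data route — tested as an exact
round-trip identity. Degenerate conventions: zero within-group variance with
unequal means reports F = +inf (p = 0); all values identical reports F = 0
(p = 1). No repeated-measures modeling, no post-hoc tests, no multiplicity
correction. Published stage tables of this kind report F values that cannot
be reconciled with their own printed means ± SD under any plausible group
size, so printed F values are treated as non-reproducible and are never used
as calibration targets.

Resting-potential banding: the published integer bands (< −30 very low,
−29..−1 low, 0..46 best, > 47 high) leave gaps on the reals; they are closed
by right-extension into the partition (−∞,−30) / [−30,0) / [0,47) / [47,∞),
which preserves every published integer assignment and makes the map total
and monotone.

## Synthetic cohort generator

Each subject's tachogram is generated beat-by-beat:
RR_k = mean_rr + lf_amp·sin(2π·0.1·t_k + φ_LF) + hf_amp·sin(2π·0.25·t_k + φ_HF) + noise_sd·ε_k,
with t_k the cumulative onset time, phases drawn once per subject, ε_k
standard normal, and intervals clipped to [300, 2000] ms (generation fails
if > 1 % of beats would be non-positive before clipping). Oscillator
frequencies are the canonical LF/HF band centers. Stage differences are
encoded only through the profile parameters:

- overall variability: (lf_amp, hf_amp, noise_sd) are scaled by a common
  factor found by deterministic bisection until the mean SDNN of 50 seeded
  subjects hits the stage set-point (52.31 / 55.93 / 69.67 ms for
  early/middle/late) within 1 %;
- sympathovagal balance: the LF/HF amplitude ratio is set from the stage
  LF n.u. set-point (30.33 / 26.62 / 32.51 %) via
  lf_amp/hf_amp = √(lf_nu/hf_nu), since band powers scale with amplitude
  squared.

Between-subject heterogeneity is median-preserving multiplicative lognormal
jitter (default sd 10 %) on mean_rr, the amplitudes and the noise — an
invention, chosen to keep parameters positive and produce stage spreads of
the published magnitude; the source tables give no within-stage
distributional information. Everything is reproducible from the cohort seed.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: respiratory frequency drift and non-stationarity,
ectopic beats and measurement artifacts, circadian/postural effects,
correlations between HRV indices and central-nervous-system measures, and
any true physiological RR dynamics (no IPFM/ODE sinus-node model). It
reproduces the *statistical surface* the analysis consumes (stage-dependent
SDNN level and LF/HF balance), which is exactly what is needed to test the
pipeline without confidential recordings.

## Problem sizes and numerical choices

Tests and the acceptance script use 300 s recordings (~375 beats),
100 subjects per stage for calibration checks, 100 replicates for
recovery-rate estimates, 50 seeds for the stage-ordering check, and compact
boosting settings (15–50 trees, depth 2–3) on tables of 36–200 rows — sizes
at which every quantity is stable to well within the asserted tolerances.
Oracle-equivalence assertions use 1e−9 relative tolerance; eps = 1e−12
guards denominators; probability normalization is exact to 1e−12.

## Known limitations

- The Lomb–Scargle variance normalization distributes total power over the
  grid up to the pseudo-Nyquist; with heavy broadband noise the absolute
  band powers depend mildly on the grid's upper limit (ratios do not).
- The boosting implementation is exact-greedy and pure Python/numpy; it is
  meant for small cohort tables, not large-scale learning.
- ANOVA assumes independent groups; paired/repeated-measures designs across
  stages of the same athletes are out of scope.
- The `as_printed` weighting mode is intentionally faithful to its published
  form including its degeneracy for separated classes with equal spreads.
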