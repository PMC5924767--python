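# Methods

`fintrack` implements a complete fine-scale movement analysis for
GPS/time-depth-tagged coastal marine mammals — track cleaning and
regularization, dive segmentation and metrics, environmental annotation,
and multimodel-averaged GLS inference — together with a synthetic-data
generator that plants known environmental effects so every stage can be
validated against ledgered truth.

## Track processing

Raw fixes (projected metres, UTC) are cleaned in three steps:

1. **Positional outlier screen.** A fix is removed when the speed from
   its predecessor exceeds 15 km/h *and* the track returns toward where
   it came from, quantified as `dist(i-1, i+1) < 0.5 * dist(i-1, i)`.
   The 0.5 return ratio is a package choice (robust to ~25 m GPS noise
   for kilometre-scale spikes) and is configurable. The rule is applied
   iteratively — earliest offender first, recompute, repeat to fixpoint —
   so spikes revealed by earlier removals are caught; the screen is
   idempotent. The first and last fixes can never be removed (they lack
   a predecessor or a return fix).
2. **Post-tagging discard.** Everything within 24 h of tagging is
   dropped (capture effects), applied identically to fixes and depth
   samples.
3. **Regularization.** The irregular series is thinned to a
   near-constant interval (15 min ± 2 min by default; 30 ± 4 and
   60 ± 8 min for sensitivity analyses) by greedy forward selection:
   from the last retained fix, keep the fix whose gap is closest to the
   target interval inside the tolerance band; if the band is empty, a
   new segment starts at the first fix beyond it. The greedy rule is
   deterministic and order-independent given sorted input. Speeds
   (Euclidean distance over elapsed time) and absolute turning angles
   (0–180°, from atan2 headings) are computed only within segments;
   a zero-length displacement leaves the adjacent angles undefined.

## Dive processing

Depth records are 1 Hz, metres positive down. A robust (Theil–Sen) line
through per-hour surface minima estimates transducer drift; an offset is
subtracted only when the drift magnitude exceeds 0.1 m/day (clean tags
pass through untouched). A **dive** is a maximal run of consecutive
samples deeper than 2 m spanning at least 10 s (last minus first sample
time). Four metrics are extracted per dive: duration, maximum depth,
**wiggliness** — the summed absolute depth change over consecutive
sample pairs that both lie in the bottom phase — and post-dive surface
duration. The bottom phase is depth ≥ 80% of the dive's maximum; the
threshold is configurable, and wiggliness is non-increasing in it by
construction. Dives are condensed onto the regularized fixes when their
start lies within ±30 s of a fix timestamp; each dive joins at most one
fix (its nearest), and the nearest dive wins when several compete for
one fix. Anchoring the window on the dive start (rather than midpoint or
overlap) is a package choice; at 15-min fix spacing with a 60-s window
the alternatives rarely differ.

## Environmental annotation

Static layers (bathymetry, seabed slope, distance to coast) live on a
~300 m cell-centre-registered grid, row 0 northernmost; dynamic
sea-surface layers (temperature, salinity, height, current velocity) on
a ~7 km grid with an hourly time axis. Slope is the Horn 3×3 gradient in
degrees (edge cells by replication, i.e. one-sided differences);
distance to coast is the exact Euclidean distance transform between cell
centres. Sampling is nearest-cell and nearest-hour (ties to the earlier
hour) — matching snapshot-style source data and keeping the annotation
oracle-trivial; no interpolation. Hour of day is the fractional UTC
hour. Annotation is pure: re-annotating an annotated table is a no-op.

Pairwise Pearson correlations among the eight candidate covariates drive
a collinearity split: when bathymetry correlates with distance to coast,
slope or SST at |r| ≥ 0.5 (configurable; the motivating correlations in
coastal shelf data are 0.5–0.75), two disjoint model sets are formed —
set A with bathymetry, set B with the distance/slope/SST trio — each
retaining salinity, SSH, velocity and hour of day.

## GLS with AR(1) errors and per-individual variance weights

Each movement parameter is regressed on environmental covariates with
error covariance

    cov(e_a, e_b) = sigma^2 * delta_g(a) * delta_g(b) * rho^(|a-b|)

within individual g (records ordered in time; delta_1 ≡ 1). Responses
are log10-transformed except turning angle; SSH and hour of day always
enter as centred linear+quadratic pairs (hour as a plain quadratic, not
cyclic — this mirrors the standard shelf-sea analysis and is
discontinuous at midnight, a known limitation). Predictors are
standardized internally and coefficients reported back on input scale.

Estimation is maximum likelihood with beta and sigma profiled out
analytically: for given (rho, delta) the AR(1) blocks are whitened in
O(n), beta is the weighted least-squares solution and sigma² = RSS/n.
The optimizer works on atanh(rho) and log(delta), Nelder–Mead from a
moment-based warm start (lag-1 autocorrelation and per-group sds of the
OLS residuals), with a neutral restart on non-convergence and an
optional {0, ±0.5} multistart. ML (not REML) keeps AICc comparable
across fixed-effects structures. The parameter count k includes the
fixed effects, sigma, rho and the m−1 variance multipliers. The
generalized R² is the squared Pearson correlation between fitted and
observed response. With rho fixed at 0 and unit deltas the fit is
exactly ordinary least squares (tested against the closed form at 1e-6
relative). AR(1) runs on within-individual record rank, treating
segment breaks as consecutive records — a documented simplification for
the regularized series.

## Multimodel inference

Every subset of a variable set is fitted (polynomial pairs as units,
intercept-only included; 2^5 = 32 models for set A, 2^7 = 128 for set
B), in deterministic bitmask-ascending order. AICc =
−2ℓ + 2k + 2k(k+1)/(n−k−1); Akaike weights are the normalized
exp(−Δ/2). Averaging is **conditional (natural)**: each coefficient is
averaged over the models containing it with renormalized weights, and
its unconditional SE folds in between-model spread,
`SE = Σ w̃_i sqrt(se_i² + (β_i − β̄)²)`; the 95% CI is β̄ ± 1.96·SE and
a variable whose CI excludes zero is flagged as an effect. Variable
importance w₊(j) sums the weights of models containing j; a polynomial
pair shares one w₊(j) but reports both coefficients. rho and delta are
re-estimated per candidate model. Model sets are compared by their
minimum AICc on identical rows (exact ties go to the bathymetry set by
convention). Reported R² is the unweighted mean (with min and max) over
the candidate set. Marginal prediction curves come from the full
(all-terms) model with other covariates at their means, banded by
±1.96·SE from the coefficient covariance and back-transformed through
10^(·) for log10 responses.

Choices the source analysis leaves open, decided here: conditional
rather than full-shrinkage averaging with z = 1.96 CIs; unweighted mean
R²; per-model re-estimation of the error structure.

## Synthetic data generator

The generator emulates a six-animal coastal deployment:

* **World.** A 42 km square. Bathymetry deepens from a northern land
  strip to ~45 m with smooth mesoscale bumps; slope and distance to
  coast are derived by the environment module. Salinity carries a fixed
  30→35 PSU west→east gradient plus a small tidal wobble; SST a
  north–south gradient plus a diel cycle; SSH is a pure M2 (12.42 h)
  sinusoid with a west–east phase lag; velocity is the rectified tidal
  stream. Fields are smooth and noise-light by design — they emulate
  model-reanalysis products, not in-situ variability.
* **Movement.** A two-state (travelling/foraging) correlated random
  walk at 1-min resolution with reflecting boundaries, state dwell
  ≥ 15 min, and covariate-dependent switching (logistic link).
  Travelling: ~1.25 m/s, 15° turn sd; foraging: ~0.45 m/s, 60° turn sd;
  speeds capped at 2.6 m/s (under the observed 2.8 m/s ceiling).
  Planted effects multiply movement parameters by
  10^(β · z(covariate)) with z standardized over the field; residual
  noise is AR(1) with per-individual sd multipliers (first ≡ 1),
  parameterized by its value at the 15-min analysis step.
* **GPS.** Acquisition attempts every 3 min thinned independently to
  ~5 fixes/h, isotropic 25 m noise (snapshot-GPS error scale;
  configurable), and single-fix spikes at rate 2%: 1–5 km excursions
  inflated when needed so the implied speed always exceeds 15 km/h and
  the next fix returns. A ledger records every spike.
* **Depth.** 1 Hz traces alternating surface intervals (mean ~30 s)
  with trapezoidal dives (constant-rate descent/ascent, sinusoidal
  bottom wiggle), depth capped by local bathymetry; durations span
  10–250 s and depths 2 m to the local seabed. Wiggle amplitude and
  bottom duration are modulated by the planted effects and the
  foraging state. The dive ledger records, per emitted dive, the true
  2 m-crossing boundaries, maximum depth and bottom distance — computed
  from the emitted (noisy) samples by the same contiguous-run rule the
  segmentation uses, so ledger and segmentation are comparable
  sample-exactly.

What the generator does **not** emulate: geodesy (a projected plane
only), prey fields and energetics, heteroscedastic or autocorrelated
GPS failure (retention is independent per attempt), dive-shape classes
beyond wiggly trapezoids, and real mesoscale oceanography. Passing
recovery tests therefore demonstrates correctness of the pipeline's
algorithms and calibration of its inference under the assumed error
structure — not robustness to every pathology of field data.

## Validation battery and problem sizes

`fintrack.validation` runs each study at sizes chosen to complete in
minutes on one core while keeping the Monte-Carlo error well inside the
acceptance bands: 1000 random traces for segmentation oracle
equivalence; 50 tracks (50 h each) for spike recovery; 20 random
designs (n = 200) for the OLS degenerate case; 100 replicates
(n = 2000, 4 groups) for rho/delta recovery; 200 replicates for CI
coverage and 50 for the null-flag rate, using covariates from one
generator-default deployment (6 × 100 h, 60 rows per individual spread
over each track) with fresh AR(1) errors per replicate; 20 full
pipeline runs (6 × 100 h) for sign recovery; 20 seeds for model-set
selection on a bathymetry-driven response. Every study is deterministic
given its seed.

## Numerical notes and degenerate inputs

* rho is bounded at |rho| ≤ 0.99 via the atanh reparameterization;
  deltas are positive via log.
* Rank-deficient designs raise with the aliased column names (pivoted
  QR screen); constant covariates are dropped by the collinearity
  screen with a warning.
* Non-positive responses under log10 raise with the offending rows;
  the pipeline drops and counts such rows (e.g. zero-wiggliness
  V-dives) before fitting.
* Empty series, sub-3-fix tracks and zero-duration configs return
  empty/unchanged outputs with warnings rather than raising, except
  where a result would be meaningless (all-sea mask, no surface
  intervals for the drift estimate).
* AICc is reported as +inf when n − k − 1 ≤ 0 and weight computation
  refuses such sets.

## Known limitations

* Conditional model averaging is mildly anti-conservative for
  covariates that vary slowly along a track (bathymetry especially):
  with few hundred rows, the finite-sample downward bias of the
  estimated AR(1) coefficient understates the effective correlation
  between a smooth covariate and smooth residuals, so the null
  false-flag rate for such covariates sits near (not comfortably
  below) the nominal level. Longer deployments or rows spread across
  the track mitigate this; the validation battery measures it
  directly.
* AR(1) runs on record rank, so a segment break contributes one
  spuriously correlated pair per break.
* Hour of day as a plain quadratic is discontinuous at midnight.
* The collinearity split is a hard threshold on pairwise |r|; no
  VIF-style multivariate screen.
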