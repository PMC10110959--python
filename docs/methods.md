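# Methods

`modewalk` analyzes long-term (hours to a day) 2D single-cell migration
tracks sampled at a nominal 1-minute interval, such as confined dendritic
cells followed by bright-field time-lapse imaging.  Its premise is that a
cell's motility is not one stationary process but a sequence of discrete,
hour-scale *migration modes*, and that these modes are recoverable from
the geometry and kinetics of one-hour track windows.

## Track model and preprocessing

A trajectory is a strictly time-ordered sequence r(t) = (x(t), y(t)) in
micrometers (Cartesian, y up), with times in minutes.  Tracking dropouts
appear as absent rows, never as placeholder coordinates.

Cleaning applies three rules, in this order:

1. **Split** at any untracked period ≥ 10 min.  Long dropouts usually
   reflect cell-cell contact or edge-of-field loss; the two sides are
   treated as independent tracks (suffixed `#1`, `#2`, ...).
2. **Interpolate** remaining gaps (< 10 min) at the missing 1-min grid
   points with a per-coordinate cubic spline through all observed points.
   The spline uses not-a-knot boundaries, so cubic motion is reproduced
   exactly; observed samples are never altered.  Splitting first
   guarantees interpolation never bridges a split boundary.
3. **Filter**: a track is kept only if its mean step speed is
   ≥ 1.5 μm/min, its duration ≥ 60 min, and its maximal displacement from
   the starting position ≥ 20 μm.  Removed tracks carry every violated
   criterion, so filter reports are auditable.

Surviving tracks are cut into consecutive, non-overlapping one-hour
windows anchored at the first timestamp.  Windows with fewer than 50
points are dropped; admissible segments therefore hold 50–60 points.

## Segment features

Each segment is summarized by five numbers.  With centered positions
δr(t_l) = r(t_l) − ⟨r⟩ the gyration tensor is the second moment
ℝ_ij = (1/N) Σ_l δr_i(t_l) δr_j(t_l) with eigenvalues λ1 ≥ λ2 ≥ 0.
(The equivalent pairwise form (1/2N²) Σ_lm (r_l − r_m)(r_l − r_m)ᵀ is the
regression oracle in the tests.)  The features are:

* **R_g = √(λ1 + λ2)** — radius of gyration (μm), overall spreading;
* **A = ((λ1 − λ2)/(λ1 + λ2))²** — asphericity in [0, 1]; 0 for an
  isotropic (circular) cloud, 1 for collinear motion;
* **E = (1/(N−1)) Σ_n V(t_n)²** — mean squared step speed ((μm/min)²), a
  kinetic-energy proxy without the ½m factor;
* **R_ete** — end-to-end distance, first to last point (μm);
* **Var[θ] = (1/(N−2)) Σ (θ_i − ⟨θ⟩)²** — population variance of the
  signed lag-1 turning angles (rad²).

Turning angles are signed by the 2D cross product (counterclockwise
positive), live in [−π, π) with exact reversals at −π, and are computed
between consecutive *non-overlapping* displacement vectors on the lag
grid.  Zero-length displacements carry no direction; they are skipped and
the angle count adjusted.  Whether the variance should use signed or
absolute angles is genuinely open; signed angles are used, consistent
with the signed definition everywhere else (for symmetric turn
distributions the two agree in expectation up to the mean term).

All five features are invariant under rigid motions, and Var[θ] also
under reflection; the tests enforce these invariances directly.

## The hybrid kernel

K-means is scale-sensitive and the five features span orders of
magnitude, so features are z-scored per column before clustering (the
scaling is stored in the model and reused at prediction time; whether the
original analysis standardized is unstated, so this is a declared choice
of this implementation).

The cluster count k is selected by maximizing the mean silhouette score
over k = 2..8 (K-means, k-means++ with 10 restarts, fixed seed).  The
silhouette uses the self-inclusive within-cluster distance,
D_W(i) = (1/|C_I|) Σ_{j∈C_I} d(i, j) with i ∈ C_I included (d(i,i) = 0),
D_D(i) the minimum over other clusters of the mean distance to their
members, and s(i) = (D_D − D_W)/max(D_W, D_D).  This differs from the
|C|−1 normalization common in libraries (e.g. scikit-learn), which is why
the package carries its own implementation, checked against an
independent double-loop oracle.

The winning K-means assignment becomes the *pseudo-label* of every
segment.  An XGBoost classifier is then trained on a random 36.6% of
segments (configurable as a fraction or absolute count) with a
cross-validated grid search over max_depth ∈ {3, 6}, learning_rate ∈
{0.1, 0.3}, n_estimators ∈ {100, 300} (5-fold).  Held-out agreement with
the pseudo-labels and normalized gain importances are recorded in the
model.  The split is unstratified unless a pseudo-class would be missing
from the training set, in which case a stratified draw replaces it.
`tree_method="exact"` is used: it places split thresholds midway between
neighboring feature values, which generalizes cleanly across wide
inter-cluster gaps, whereas histogram binning can misassign held-out
points lying marginally outside the training range.

With k = 3 the clusters are named from their summary statistics: the
cluster with the highest mean energy is **FP** (fast-persistent); of the
remaining two, the one with higher mean asphericity is **SP**
(slow-persistent) and the other **SD** (slow-diffusive).  Naming is
invariant to cluster index permutation and fails loudly on ties.

Annotation segments an arbitrary gap-free trajectory with the same
windowing rules, scales with the stored scaling, predicts with the stored
booster and maps to mode names.  Models persist as a single versioned
JSON envelope (scaling, centers, naming, serialized booster); loading a
mismatched version fails loudly.

## Trajectory statistics

* **MSD**: time-averaged over all overlapping start times,
  MSD(k) = (1/(N−k)) Σ_i |r_{i+k} − r_i|², with the anomalous exponent α
  the log-log least-squares slope.  The default long-time fit window is
  lags 10–30 min (configurable); α = 1 is normal diffusion, < 1
  sub-diffusive, 1–2 super-diffusive, 2 ballistic.
* **P(α)**: the per-segment exponent distribution with quartile
  summaries, quantifying cell-to-cell dynamic heterogeneity.
* **Displacement PDF** P(x|Δt): histogram of 1D x-displacements over all
  overlapping pairs, unit-normalized (Freedman–Diaconis bins by default).
* **Turning-angle heatmap**: per-lag signed-angle histograms over
  non-overlapping vectors, pooled per angle across trajectories (not
  per-trajectory weighted — a declared choice), each lag column
  normalized to 1; 61 bins over [−π, π) by default.
* **Phase space**: V_n = (|D(t_{n+1})| − |D(t_n)|)/Δt against
  Δθ_n = θ_{n+1} − θ_n, where Δθ is deliberately *not* re-wrapped: two
  successive opposite full turns genuinely produce |Δθ| ≈ 2π, and
  wrapping would erase that zigzag signature.
* **Zigzag fraction**: over successive angle pairs (θ_n, θ_{n+1}), the
  ratio of opposite-sign to same-sign pairs, pairs containing an exact
  zero excluded, +∞ when no same-sign pair exists.  Above 1 means
  alternating (zigzag) turning; below 1 consistent-sign (curly) turning.

## Transition analytics

Per-window mode sequences feed four estimators: the 3×3 transition matrix
(all consecutive window pairs pooled over tracks, self-transitions
included; rows with no outgoing counts are NaN-flagged, never silently
zeroed), per-mode window fractions, single- vs multi-mode track
fractions, and mode lifetimes (maximal constant-mode runs; runs touching
a track boundary are censoring-flagged but kept in the CDFs — dropping
them would bias against long-lived modes).  Cross-transition pathways are
counted on the collapsed run sequence: for each ordered pair (i, j) the
one-step count is adjacent i→j and the two-step count i→k→j through the
third mode, normalized within the pair (routes of three or more steps are
not categorized).

## The synthetic generator

No generative model for the modes is given by the data the pipeline
targets, so the simulator is designed to reproduce the *summary
statistics* each mode is defined by, with defaults:

| mode | walker | mean speed (μm/min) | turning behavior |
|------|--------|--------------------:|------------------|
| SD | anchored (discrete Ornstein–Uhlenbeck) walk, stiffness κ = 0.3/min | 2.58 (±1.90 reported spread) | anti-persistent: reversal peaks at θ ≈ ±π beyond ~3-min lags, sub-diffusive long-lag MSD |
| SP | persistent walker, zigzag turns | 2.21 ± 1.61 | turn magnitude \|N(0.9, 0.3)\| rad, sign alternating with probability 0.9 |
| FP | persistent walker | 6.27 ± 2.66 | Gaussian heading increments, scale 0.35 rad |

Per-step speeds are i.i.d. truncated-normal on (0, ∞) with the location
solved (cached Brent root find on the truncated-normal mean) so the
realized mean equals the configured speed — naive truncation would
inflate the SP mean by ~12%.  The SD walk's noise scale is calibrated
analytically from κ and the target mean step speed; its speed spread is
therefore a property of the OU model rather than the `speed_sd` field.
The OU anchor makes SD strongly confined, so its long-lag MSD exponent is
near 0 rather than the ~0.6 of real diffusive cells; the pipeline only
requires sub-diffusivity (α < 1), and the plateau is the price of a
two-parameter SD model.  Turn scales were fixed once so that the three
modes are genuinely distinct in feature space — mode separability is a
premise of the classification approach, not a finding of this package.

Mode switching is a first-order Markov chain at 60-min (window)
granularity: the mode is constant within a window and the next window's
mode is drawn from a row-stochastic 3×3 matrix.  Sub-window switching is
out of scope by design, mirroring the classifier's resolution.  All
generators derive per-trajectory streams from a single seed by
counter-based splitting, so any trajectory is reproducible in isolation.
Analytic fixtures (ballistic, Brownian, circular, zigzag, stationary)
with closed-form MSD/shape signatures serve as oracles.

What the generator does *not* emulate: heavy-tailed (Lévy-like) step
distributions, sub-minute dynamics, gradual intra-window mode drift,
localization noise, or cell-cell interactions.  Tests passing on this
synthetic data demonstrate the *pipeline's* correctness and its ability
to recover planted structure; they do not certify that real cells have
exactly three modes or that the mode boundaries found on other data sets
are biologically equivalent.

## Numerical choices and scales

* Segment pools for kernel tests use 3000 segments (1000 per mode) of 60
  points each; the silhouette scan covers k = 2..8; parameter-recovery
  checks use 200 tracks × 24 h.  These sizes make the checks sharp
  (binomial 3σ bands, agreement thresholds at the 99.6% level) while a
  full test run stays interactive.
* Brownian-exponent checks use the ensemble mean of 200 time-averaged
  MSDs over 300-step tracks, fit over lags 2–30 min, tolerance ±0.1
  (time-averaged single-track MSDs at long lags are noisy; the ensemble
  mean slope concentrates at 1).
* Determinism: every stochastic routine takes an explicit seed;
  `fit_modes` pins K-means restarts, the train/test permutation and the
  XGBoost seed, so a fixed seed reproduces labels, importances and
  agreement bit-for-bit.
* Degenerate inputs fail loudly and specifically: stationary segments
  have undefined asphericity, single-cluster silhouettes are undefined,
  zero-MSD fit ranges are rejected, zero-count transition rows are
  NaN-flagged.

## Known limitations

* The admissible-segment rule (≥ 50 points per 60-min window) assumes
  ~1-min sampling; much finer sampling would need resampling first (the
  windowing caps segments at 60 points).
* The silhouette implementation is O(n²) in memory and time; it is meant
  for feature matrices of thousands of rows, not millions.
* Lifetime CDFs include censored runs without survival-analysis
  correction; they are descriptive, not estimators of the true dwell
  distribution.
* The transition matrix is a pooled estimator; per-track heterogeneity in
  switching rates is not modeled.
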