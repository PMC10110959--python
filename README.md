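# modewalk

Discovery and dynamics of discrete migration modes in long-term 2D
single-cell trajectories.

Migrating cells — immune cells such as dendritic cells in particular —
rarely move as one stationary random walk.  Over a day of observation a
single cell drifts between qualitatively different motility states:
crawling diffusively in place, advancing in a zigzag, or streaking
persistently across the field.  `modewalk` is a Python library (plus a
thin CLI) for researchers who track cells at ~1-min resolution and want
to turn raw (t, x, y) tables into:

1. **modes** — a data-driven decomposition of one-hour track segments
   into discrete migration modes, via a hybrid unsupervised/supervised
   kernel;
2. **statistics** — anomalous-diffusion exponents, turning-angle
   structure, displacement densities and zigzag quantification per mode;
3. **dynamics** — transition matrices, mode lifetimes and one- vs
   two-step switching pathways along each trajectory.

## The method in brief

Each admissible one-hour window (50–60 points at 1-min sampling) is
summarized by five descriptors built on the gyration tensor
ℝ_ij = (1/N) Σ_l (r_i(t_l) − ⟨r_i⟩)(r_j(t_l) − ⟨r_j⟩) with eigenvalues
λ1 ≥ λ2:

| feature | definition | measures |
|---|---|---|
| R_g | √(λ1 + λ2) | spatial spreading |
| A | ((λ1 − λ2)/(λ1 + λ2))² | shape anisotropy (0 circle … 1 line) |
| E | (1/(N−1)) Σ V(t_n)² | kinetic energy proxy |
| R_ete | \|r(t_N) − r(t_0)\| | net progress |
| Var[θ] | (1/(N−2)) Σ (θ_i − ⟨θ⟩)² | turning-angle fluctuation |

K-means clusters the z-scored features; the mean silhouette score
s(i) = (D_D − D_W)/max(D_W, D_D) selects the cluster count; the K-means
assignment pseudo-labels the segments; and a grid-searched XGBoost
classifier learns the labels, reports feature importances, and annotates
arbitrary trajectories window by window.  With three clusters the modes
are named **SD** (slow-diffusive), **SP** (slow-persistent, zigzag-like)
and **FP** (fast-persistent) from their mean energy and asphericity.
Mode sequences then feed transition, lifetime and pathway estimators, and
a trajectory-statistics suite (time-averaged MSD ∝ Δt^α, turning-angle
heatmaps, (V_n, Δθ_n) phase space, zigzag fraction) characterizes each
mode's dynamics.

A synthetic generator ships with the package: three mode-specific walkers
(anchored/Ornstein–Uhlenbeck, zigzag-persistent, persistent) with
Markov mode switching at one-hour granularity, plus analytic fixtures
(ballistic, Brownian, circular, zigzag) used as test oracles.  See
`docs/methods.md` for the full model description and design rationale.

## Worked example

```sh
python examples/simulate_and_classify.py
```

```
mean silhouette by k: {2: 0.596, 3: 0.665, 4: 0.638, 5: 0.61, 6: 0.575, 7: 0.546, 8: 0.528}
selected k = 3  (highest mean silhouette)
held-out agreement with pseudo-labels: 0.9979
feature importances: {'rg': 0.661, 'asphericity': 0.004, 'energy': 0.32, 'rete': 0.008, 'var_theta': 0.007}
cluster naming: {0: 'SD', 2: 'SP', 1: 'FP'}
agreement with simulator ground truth: 0.9980
```

The silhouette peaks at k = 3: the 1500 synthetic segments fall into
three distinct motility patterns.  The boosted classifier reproduces the
cluster assignment on 99.8% of held-out segments, and the recovered
clusters match the walkers that actually generated each segment 99.8% of
the time.  Other examples cover window-by-window annotation of a
switching track (`annotate_switching_track.py`), per-mode MSD exponents
and zigzag fractions (`msd_and_turning_angles.py`), transition-matrix
recovery (`transition_dynamics.py`) and gap handling
(`clean_raw_tracks.py`).

## Library at a glance

```python
from modewalk import (read_tracks, preprocess_trajectory, filter_tracks,
                      segment_trajectory, feature_matrix, scan_cluster_count,
                      fit_modes, annotate_trajectory, transition_matrix)

table = read_tracks("tracks.csv")                      # t, x, y tables
clean = [p for tr in table.trajectories()
         for p in preprocess_trajectory(tr)]           # split + interpolate
kept, removed = filter_tracks(clean)                   # quality criteria
segments = [s for tr in kept for s in segment_trajectory(tr)]
X = feature_matrix(segments)                           # n x 5
scores, k = scan_cluster_count(X)                      # silhouette scan
model = fit_modes(X, k)                                # K-means + XGBoost
sequences = [annotate_trajectory(model, tr) for tr in kept]
tm = transition_matrix(sequences)                      # P_ij with self-loops
```

The same stages are available as `modewalk simulate | preprocess |
features | discover | annotate | stats | transitions | run` with a YAML
config (see `modewalk --help`).

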