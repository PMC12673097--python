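# Methods

## Pipeline model

`sitpheno` assumes the upstream pose-estimation step is done: its inputs
are per-frame keypoint tables (x, y, likelihood per body part) in the
DeepLabCut dialect, one table per animal per session, plus a pixel-space
description of the arena. Everything downstream is deterministic
arithmetic on those tables; given identical inputs and configuration the
outputs are byte-identical.

Two body-part roles drive the metrics and are resolved by a configurable
mapping (defaulting to case-insensitive substring match, so `Nose`,
`nose_tip`, `spine_center` all resolve):

* **centre** — defines SIZ occupancy (the conventional "body centre in
  the zone" criterion) and the path length;
* **nose** — defines the continuous POI-distance metric, since the nose
  is what actually investigates the target.

### Session metrics

For each session, after dropout repair:

* `time_in_siz` = (frames with centre inside the SIZ polygon) / fps.
  Zone membership is a convex-polygon test with the boundary counted as
  inside.
* `mean_dist_poi` = per-frame mean Euclidean nose→POI distance, converted
  from pixels to metres via the arena scale. Frames inside over-long
  tracking gaps are excluded from this mean and counted separately.
* `total_distance` = summed frame-to-frame centre displacement, metres.

The per-animal aggregation treats the summation in the ratio definitions
as a within-session, per-animal mean over frames: for zone time the
averaging factor cancels, leaving total occupancy seconds; for distance
it is the per-frame mean. Ratios are therefore per-individual quantities,
as they are reported per mouse downstream.

Sessions are trimmed to a configured duration (default 2.5 min) from
their first frame so that unequal recording overruns cannot bias the
type-B ratios; pass `session_minutes=None` to disable.

### Ratios, index, classification

Type-A ratios divide S2 by S1 (boundary 1); type-B ratios divide S2 by
the two-session sum (boundary 0.5, bounded in [0, 1]). The two are
algebraically linked by `b = a/(1+a)`, so the classification rules agree
whenever both are finite — the type-B rule is the default basis, type A
is kept for cross-checking. The boundary is inclusive to resilient
(`≥ 0.5` → resilient). Degenerate inputs never raise during ratio
construction: `x/0` with `x > 0` yields `inf` plus a zero-denominator
flag (and classifies as resilient under type A, since it is maximal
approach), `0/0` yields `nan` plus an undefined flag and the label
`unclassifiable`. SEI = time-B / distance-B, with the cluster boundary
fixed at 1 (equal numerator and denominator).

### Ambiguity flags

Two heuristics operationalise the qualitatively ambiguous cases a
bidimensional view exposes; both are configurable and neither affects the
binary label:

* `near_poi_low_time`: S2 mean POI distance **and** S2 zone time both at
  or below the cohort's lower quartile — proximity without engagement.
  Requires a cohort of ≥ 4 animals; smaller cohorts disable the
  criterion with a warning. The quartile (default 0.25) is a stated
  choice, not a universal constant.
* `sei_cluster_mismatch`: susceptible with SEI > 1, or resilient with
  SEI < 1.

## Dropout repair

Pose estimators emit a per-frame likelihood; frames below a threshold
(default 0.6, the conventional DLC cutoff) are treated as dropouts and
replaced per body part by linear interpolation between the nearest
confident neighbours (nearest confident value at track edges). Runs
longer than `max_gap` (default 1 s) are filled anyway but reported, and
the metrics layer excludes them from the mean-distance computation — a
long gap interpolates as a straight line through space the animal never
occupied, which is tolerable for occupancy counting but would bias a
mean distance. Repair is idempotent and never touches confident frames.
A body part with zero confident frames aborts with an explicit error
rather than fabricating a trajectory.

## Statistics

**Wilks' Λ MANOVA.** One-way, on a per-animal feature matrix (default:
the two type-B ratios; raw session metrics can be passed instead —
which features enter is a configuration choice, not hard-wired).
Λ = det(W)/det(W + B) from the within- and between-group cross-product
matrices, with the p-value from Rao's F transformation — exact for the
two-feature case used here. Λ is invariant under any affine rescaling of
a feature column. A within-matrix determinant ≤ 0 raises an error naming
the near-collinear feature column. Preconditions: ≥ 2 groups, each with
≥ 2 animals, and more animals than features + groups.

**Spearman ρ.** SEI vs the ordinal 1–5 nest score. Scores are treated as
ordinal ranks with midrank ties (the standard resolution when a rank
correlation is applied to a small ordinal scale); ρ is the Pearson
correlation of the rank vectors and p comes from the t-approximation
with n − 2 df. Zero rank variance in either variable is an error, not a
silent 0. Routine univariate machinery (normality tests, ANOVA,
post-hocs) is deliberately left to general statistics packages.

## Trajectory simulator

The generator emulates the study conditions — 2.5-minute sessions at
30 fps in a 42 × 42 cm arena with the cage centred on one wall (cage
face 10 cm wide, 10 cm into the arena; SIZ = cage footprint + 8 cm
corridor) — with the body centre following a reflected
Ornstein–Uhlenbeck walk integrated by Euler–Maruyama at dt = 1/fps:

    dX = [θ(c − X) + v·u(X)] dt + σ dW,    reflected at the walls,

where θ (default 0.2 s⁻¹) is a homing pull toward the arena centre that
keeps the walk stationary, σ (default 6 cm/√s) the diffusion scale, and
v the signed session drift along the unit vector toward the POI —
positive for approach, negative for avoidance. Inside the SIZ the animal
freezes for a frame with probability `dwell_bias` (cage-sniffing
dwell). The nose rides 2 cm ahead of the centre along the heading with
0.15 cm Gaussian jitter; a `dropout_rate` fraction of frames receives a
likelihood drawn below 0.5 to exercise the repair path. Steps larger
than the arena (|v|·dt + 4σ√dt > side) are rejected as numerically
unstable.

Preset drifts (cm/s, S1/S2): control 0/+1.5, resilient-like 0/+3.5,
susceptible-like +0.5/−3.5, with dwell biases 0.25/0.45/0. These were
chosen once so that a 2.5-minute session lets the programmed
approach/avoidance dominate diffusion, mirroring the clear separation
real resilient and susceptible cohorts show. Synthetic nest scores come
from a latent Gaussian (mean 3 + 0.55·drift_S2, sd 0.9) rounded and
clipped to 1–5, giving the rank-correlation stage genuine signal.

Seeding: one master seed; animal *i*, session *j* uses the stream seeded
by `SeedSequence((master, i, j))` (nest scores use `(master, i, 99)`), so
cohorts are bit-reproducible and independent of generation order.

With zero drift and negligible homing the reflected walk's stationary
distribution is uniform, so long-run SIZ occupancy converges to the
area ratio — the calibration property the test suite checks by
Monte-Carlo.

### What the simulator does not emulate

No gait or body deformation (the nose is a rigid offset), no thigmotaxis
or corner preference, no interaction dynamics with the caged animal, no
cage-body collision (trajectories may cross the cage footprint), and
dropouts are i.i.d. rather than burst-like occlusions. Passing tests
therefore demonstrate that the arithmetic pipeline — zone counting,
calibration, ratios, classification, statistics — is correct and that
programmed phenotypes are recovered end to end; they do not validate the
movement model against real mouse behavior.

## Numerical choices

* Zone membership uses a sign test with a relative tolerance of 1e-9 of
  the polygon's coordinate magnitude, so boundary points are inside on
  both orientations.
* CSV round-trips write 17 significant digits and parse with pandas'
  round-trip float precision, making write→read bit-exact.
* Pixel scale = mean of the four arena edge lengths / physical side;
  square pixels are assumed.
* Test and example problem sizes (cohorts of 12–46 sessions, sessions of
  0.05–2.5 min) were chosen as the smallest sizes at which the stochastic
  properties under test are stable.

## Known limitations

* The SIZ default (8 cm corridor off the cage face) is a field
  convention, not a universal constant; studies using a different zone
  must supply their polygon.
* MANOVA assumes multivariate normality within groups and homogeneous
  covariances; with the bounded ratios this is an approximation, adequate
  at the moderate group sizes the test targets.
* The ambiguity quartile rule is one explicit operationalisation of a
  qualitative pattern; alternatives (fixed physical distance cutoffs,
  model-based clustering) may suit other designs better.
* Non-square arenas and non-square pixels are out of scope.
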