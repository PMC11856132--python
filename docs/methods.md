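# Methods

## The tracking model

`weeviltrack` is an online tracking-by-detection system. Each frame, a
detector (external to this package) supplies boxes with confidences and,
optionally, unit-norm appearance vectors. The tracker maintains a set of
tracks, each with:

- a Gaussian belief over the 8-dim state (cx, cy, a, h, vcx, vcy, va, vh) —
  box center, aspect ratio w/h, height, and per-frame velocities — advanced
  by a constant-velocity Kalman filter with time step fixed at one frame
  (the target videos are constant 30 fps, so variable-dt support would buy
  nothing);
- a FIFO gallery of appearance vectors (budget 100);
- a lifecycle status: *tentative* until matched in `n_init` frames,
  *confirmed* thereafter, *deleted* when unmatched for more than `max_age`
  frames (tentative tracks are deleted on their first miss).

Association runs in two stages per frame. The **matching cascade** considers
confirmed tracks in order of increasing time-since-last-update, so fresh
tracks claim detections first; its cost is the minimum cosine distance
between each detection's feature and the track's gallery (falling back to
1 − IoU when the stream carries no features), with pairs whose squared
Mahalanobis distance in the 4-dim observation space exceeds the gate
removed. The **IoU stage** then matches tentative tracks and confirmed
tracks missed exactly once against the remaining detections at cost
1 − IoU. Both stages solve a minimum-cost assignment (Hungarian method,
`scipy.optimize.linear_sum_assignment`); matches costlier than the stage
threshold are demoted to unmatched.

### The identity-history store

The store ("Target_dict" in the joint detection–tracking design this
implements) is a global map from every identity ever issued to its recorded
(frame index, center, box) trajectory. It persists across track deletion
and drives three behaviours:

1. **Validation.** Every matched observation of a known identity is checked
   against that identity's last record: the frame gap must be ≤
   `validation_max_gap` and the implied speed (displacement / gap) ≤
   `validation_max_speed`, both inclusive. A failing observation means the
   track has almost certainly latched onto a different insect; the track is
   reassigned a fresh identity and the old entry is left untouched —
   splitting is preferred over corrupting a trajectory.
2. **max-ID+1 issuing.** Fresh identities are one above the maximum over the
   store and all live tracks, so no identity is ever reused, even after its
   track has died.
3. **Recovery.** Before minting a new identity, a spawning track searches
   the store for a *dormant* identity (no live track carries it, at least
   `n_init` records so detector flickers are not resurrected) whose last
   record the new detection plausibly continues under the same gap/speed
   rule; the nearest such identity is resumed. This is what removes the
   identity switch that otherwise always occurs when a target reappears
   from an occlusion longer than `max_age`.

With `history_enabled=False` the store still records trajectories (it is
the bookkeeping behind output and counting) but validation and recovery are
off — that variant is the plain-DeepSort baseline used by the `ablate`
command.

Tracker output is reconstructed from the store: every identity with at
least `n_init` records is emitted over all its recorded frames. This makes
output retroactive — the pre-confirmation frames of a track that goes on to
be confirmed are included — and filters one- or two-frame false-positive
tracks. The unique-target **count** is the number of such identities.

## Parameters

| parameter | default | meaning / why |
|---|---|---|
| `n_init` | 3 | frames of consecutive support before a track is confirmed; 0.1 s at 30 fps |
| `max_age` | 30 | frames a confirmed track survives unmatched; 1 s at 30 fps |
| `max_iou_cost` | 0.7 | IoU-stage threshold (accept overlap ≥ 0.3) |
| `max_appearance_cost` | 0.25 | cascade cosine-distance threshold |
| `gating_threshold` | 9.4877 | chi-square 0.95 quantile, 4 dof |
| `appearance_budget` | 100 | gallery size (FIFO) |
| `validation_max_speed` | image diagonal / 10 per frame | scale-free; via `TrackerConfig.for_arena` |
| `validation_max_gap` | 2 × `max_age` | see below |
| filter noise | position std h/20, velocity std h/160 | height-scaled, the established convention for this filter family |

`validation_max_gap` deliberately exceeds `max_age`: a record in the store
is at least `max_age` frames old by the time its track has been deleted, so
a gap bound equal to `max_age` would make recovery unreachable and the
store dead weight. Doubling it lets the store bridge occlusions up to twice
as long as the motion filter itself tolerates; beyond that, position
prediction is worthless anyway and resuming an identity would be a guess.

The filter's default noise weights favour jitter rejection over
responsiveness: on a noise-free constant-velocity track the one-step
prediction error decays geometrically (≈ ×0.88/frame) toward zero but
retains a visible lag for tens of frames. A high-velocity-gain
configuration (`std_weight_velocity ≥ 1`) locks on within ~5 frames to
below 1e-6 px; the tests exercise both regimes.

## Evaluation conventions

- **Detection matching** (for P/R/F1 and AP): greedy, detections in
  descending confidence (input order on ties), each claiming the unmatched
  ground-truth box of highest IoU ≥ threshold. AP integrates the
  monotone precision envelope over recall increments (all-points
  interpolation), the direct discretisation of ∫P(R)dR; 11-point
  interpolation was rejected as a coarser historical approximation.
  Zero-denominator P/R are 0.0 with a warning so sweeps stay total.
- **CLEAR-MOT correspondence**: previous-frame pairings are kept while they
  still overlap ≥ the threshold (continuity), the rest are matched by
  minimum (1 − IoU) assignment with sub-threshold pairs masked infeasible
  up front (so a feasible match is never sacrificed for total-cost
  reasons). A ground-truth object whose matched hypothesis identity differs
  from its *last ever* matched identity counts one switch, also across
  gaps.
- **MOTP** is reported as mean IoU of correct matches × 100 (higher-better),
  the reading consistent with precision figures near 90% quoted alongside
  accuracies near 94%; the literal distance reading of the definition is
  available as `mode="distance"` (mean center distance, pixels).
- **Counting accuracy** = (1 − |count − truth|/truth) × 100, one decimal.
  The absolute value makes over- and under-counts symmetric penalties; the
  published comparison only constrains the undercount case (16 of 17 →
  94.1%), and symmetry is the conservative completion.

## The simulator

`synth_scenarios.generate` emulates detector-output statistics for the
conditions that cause ID hopping in the field: several near-identical
targets (per-target unit appearance vectors mixed with a shared component
at weight `inter_id_similarity`, plus N(0, 0.05) observation noise),
piecewise constant-velocity motion whose speed and heading are resampled
with probability `turn_probability` per frame (sudden take-off/landing),
reflection at the arena walls, occlusion as detection dropout over listed
frame windows, per-detection miss probability `fn_rate`, Poisson false
alarms (`fp_rate` per frame, random position and appearance), and Gaussian
box jitter. A `lanes` layout places targets in separate horizontal lanes
with purely horizontal motion — and, when the run is short enough to fit
the arena, start positions chosen so no wall is ever hit — giving a
guaranteed non-crossing, truly constant-velocity scenario for
exact-recovery checks.

It does **not** render images: there is no lighting, background clutter,
detector confidence structure beyond uniform draws, or box merging during
occlusion (dropout stands in for it). Passing tests therefore demonstrate
the tracker's association, lifecycle and identity logic under controlled
degradation, not end-to-end performance on real RPW video, which depends
on a trained detector outside this package's scope.

The packaged 17-target fixture (`paper_like_fixture`) is a 300-frame,
1920×1080 scenario with four occlusion windows (21–46 frames, three of
them longer than `max_age`), 5% misses, 0.3 false alarms/frame, 1 px jitter, and high
(0.6) inter-identity similarity; its zero-noise variant uses the lane
layout with exact, complete detections. Scenario sizes throughout the test
suite (≤ 17 targets, ≤ 300 frames, ≤ 20 seeds per property) were chosen as
the smallest at which the occlusion/crossing phenomenology is well
expressed.

## Numerical choices and degenerate inputs

- Kalman updates use the Joseph-form covariance and re-symmetrise, keeping
  the covariance PSD through long runs; gating factorises the innovation
  covariance by Cholesky and raises on singularity.
- Assignment ties are broken deterministically (lowest row, then column);
  infeasible entries use a sentinel cost of 1e5, far above any real cost.
- Boxes must have strictly positive width and height; degenerate boxes are
  rejected at construction. IoU of edge-touching boxes is 0.
- Empty frames, empty files and empty cost matrices are all legal and give
  the obvious degenerate results (no detections → all misses, etc.).
  Trailing all-empty frames cannot be represented in a MOT text file; the
  frame count is inferred from the maximum frame index on read.
- The tracker has no internal randomness: identical inputs give identical
  outputs; all stochasticity lives in the simulator, behind one seed.

## Known limitations

- Appearance features are supplied or synthetic; no embedding network is
  included, so real-video use requires an external re-identification model.
- Recovery can, in principle, resume a dormant identity with a false-alarm
  chain that happens to pass the gap/speed check; galleries are not
  consulted because the store records positions only. Under heavy erratic
  motion the unique-identity count overshoots the target number — fragments
  longer than `n_init` frames each count once.
- The CLEAR-MOT continuity rule and the greedy detection-matching rule are
  stated conventions; other tools' choices may differ in ways that matter
  at the third decimal.
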