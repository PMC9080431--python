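# Methods

## Setting and assumptions

One fish per arena, one detector proposal per frame, analysed at 1 frame/s
in 1,280 × 768 px image coordinates (origin top-left, y downward, boxes
stored with inclusive corners as annotation tools write them). The shelter
hides the fish from the camera, so visibility and "outside the shelter" are
treated as the same event; the detector's per-frame class probability is
therefore a presence score and its bounding-box centroid a position estimate.
Frame counts are data-driven throughout — nothing assumes a video is exactly
an hour or exactly 3,600 frames.

## Validation statistics

**Thresholding.** Presence ⇔ probability ≥ τ. The boundary is inclusive so
that a score sitting exactly on τ = 0.5 counts as a detection; the rule is a
config option. Matching percentages are computed overall and separately over
the manually-present and manually-absent frames; a part with no frames is
reported as missing, never as 0 or 100, and the identity
overall = (n₁·present% + n₀·absent%)/n is asserted per video.

**Aggregation.** Videos are equally weighted regardless of length. The
interval is the normal approximation mean ± z·SD/√n with z = 1.96. This
convention was chosen because it reproduces the published worked examples to
the printed precision (92.79 ± 6.78, n = 14 → [89.24, 96.34];
78.20 ± 24.73, n = 14 → [65.25, 91.15]; 10.25 ± 61.59, n = 1085 →
[6.59, 13.91]); a Student-t interval does not. With ~14 videos the normal
interval is anti-conservative (t₁₃ would be ≈9% wider); it is kept for
comparability and z is configurable.

**RMSE.** Two definitions are implemented because the quantity is ambiguous
for a binary agreement series: `frame_pooled` (default),
100·√(pooled mismatch fraction), which is the RMSE of the 0/1 residuals on
the percentage scale; and `per_video`, √(meanᵢ (100 − overallᵢ%)²). Published
per-table RMSE values for this kind of validation are not derivable from the
printed means and SDs under either definition, so neither is claimed to
match them; both are reported for synthetic data where they are exact.

**Positioning.** Error = Euclidean distance between predicted and manual box
centroids. The success threshold is the pooled mean of all manual box widths
and heights (each box contributes two side lengths; opposite equal sides are
not double-counted); a per-box-mean variant exists and differs only under
unbalanced aspect ratios. Success is inclusive (error ≤ threshold). SD is
the sample SD (n−1); the identity RMSE² = mean² + population variance is
checked on every summary (it also holds, to rounding, for the published
triple 10.25/61.59/62.42). Labelling frames are apportioned across videos by
largest remainder on present-frame counts (ties to the earlier video), then
drawn uniformly without replacement — proportional sampling is the only
autocorrelation mitigation, mirroring field practice.

## Behavioural metrics

Computed from the thresholded trajectory (the deployment condition), not
from manual annotation; a manual series can be substituted upstream.
Swimming needs a speed threshold no standard defines; the default 5 px/s
(≈0.2 body lengths/s for a ~25-cm fish imaged at this scale) is exposed in
config and echoed in output metadata. Area covered is grid occupancy with
32-px cells — robust and monotone in observation time, unlike hulls or
kernel densities; boundary points belong to the higher-index cell. The
turning angle is the mean *absolute* angle (atan2 of cross and dot products,
range [0°, 180°]) over triplets of consecutive present frames with two
nonzero displacements; signed means are ≈0 on symmetric paths and carry no
activity signal. Gaps break triplets; positions are not interpolated or
smoothed by default (an optional 3-frame median filter exists but is off,
since per-second positions are reported raw).

## Synthetic arena

The generator emulates the data-generating process the validation assumes,
with every parameter known so the pipeline can be tested by recovery.

* **Occupancy**: two-state Markov chain; stationary visible fraction
  p_exit/(p_exit + p_enter), mean run lengths 1/p_enter and 1/p_exit.
  Defaults p_exit = 0.02, p_enter = 0.01 give ⅔ of time outside with
  ~100 s excursions — a shelter-using but active animal.
* **Movement**: correlated random walk; turning angles ~ wrapped Cauchy with
  concentration = persistence (uniform at 0, the standard CRW
  parameterization), step length |N(0, step_sigma)| (default 20 px/s),
  reflection at borders, re-emergence at a fixed shelter anchor — the
  simplest behaviour consistent with a fixed shelter. These are scenario
  settings, not estimates of any species' movement.
* **Detector noise**: scores ~ Beta(8, 2) when visible and Beta(2, 8) when
  hidden (bounded scores with ≈2% mass on the wrong side of 0.5; point-mass
  laws give exact noiseless runs), per-axis Gaussian centroid jitter
  (default 5 px), and with probability `outlier_prob` (default 0.01) the box
  relocates uniformly in the arena or onto the novel object — reproducing
  the small-mean / large-SD error structure of real detectors that
  occasionally lock onto the wrong object. Hidden frames still emit a box at
  the outlier source, as a single-proposal detector does. Error rates at any
  τ are analytic via the Beta CDF, which is what the recovery tests check
  against.

What the generator does *not* emulate: appearance, occlusion or lighting
structure in errors (noise is i.i.d. given the state), multi-fish scenes,
within-second movement, or temporally correlated detector failures. Passing
recovery tests therefore shows the *statistical machinery* is correct, not
that any particular detector meets a given accuracy on real video.

## Numerical choices

* One seed per simulated video; each generative layer draws from a
  sub-stream derived via `SeedSequence(seed, spawn_key)`, so adding a stage
  never shifts another's draws; identical params + seed are bit-identical.
* Ground-truth positions are snapped to a 1/65536-px dyadic grid. This is
  far below physical resolution and makes box corners (centroid ± half-size)
  and their midpoint exactly representable in binary floating point, so the
  noiseless limit recovers positions *bit-for-bit* rather than to ~1e-13.
* Emitted boxes are kept inside the arena by shrinking symmetrically about
  the centroid rather than truncating corners, so border clipping never
  biases the centroid.
* CSVs are written with shortest round-trip float representation and read
  with `float_precision="round_trip"`; read∘write is the identity.
* Largest-remainder ties in frame sampling go to the earlier video in input
  order; boundary grid points go to the higher-index cell; a detector frame
  missing from a table is probability 0 with no box (absence of a proposal
  is evidence of absence) and is logged.

## Problem sizes

Recovery tests use 6–14 synthetic videos of 600–3,600 frames and 10⁴-frame
jitter samples — large enough that 3-standard-error bands are a fraction of
a percentage point, small enough that the full suite runs in seconds. The
acceptance script's classification recovery uses 14 one-hour videos
(50,400 frames), matching the scale of a realistic validation campaign.

## Known limitations

* The normal-approximation CI is anti-conservative at n = 14 (kept for
  comparability; z configurable).
* Percentage matching inherits the annotation's 1-s granularity; sub-second
  shelter transitions are invisible at 1 frame/s.
* Exploration metrics assume a stationary object with a known centroid.
* No identity maintenance or IoU matching: the single-fish, single-proposal
  setting makes centroid distance the whole localization story.
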