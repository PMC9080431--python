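# arenatrack

Validation and behavioural metrics for single-fish detector output in
experimental arenas.

A convolutional object detector watching a behavioural arena emits, once per
second, a class probability and a bounding box for its single best fish
proposal. Because the fish is invisible to the camera while inside its
shelter, thresholding that probability yields a presence/absence series
("outside the shelter"), and the box centroid yields a per-frame position.
`arenatrack` is for behavioural ecologists who need to (a) validate such a
detector against manual annotation before trusting it, and (b) turn its
output into standard open-field (activity) and novel-object (exploration)
metrics.

## What it computes

**Classification validation.** For thresholds τ ∈ {0.5, …, 0.9} the score
series p₁…pₙ is binarized (presence ⇔ pᵢ ≥ τ) and compared frame-by-frame
with the manual series, giving a per-video matching percentage — overall and
split into the manually-present part (1 − miss rate) and the manually-absent
part (1 − false-positive rate). Across videos the summary is the mean %, the
sample SD, the normal-approximation interval mean ± 1.96·SD/√n, and an RMSE
(frame-pooled 100·√(mismatch fraction) by default, or per-video
√(mean (100 − %ᵢ)²)).

**Positioning validation.** Per sampled frame the error is the Euclidean
distance ‖c_pred − c_manual‖ between box centroids (px). Success means error
≤ the mean side length of all manually drawn boxes (widths and heights
pooled). Labelling frames are drawn proportionally to each video's
manually-present portion (largest-remainder quotas).

**Behavioural metrics.** From the thresholded trajectory: time outside the
shelter; time swimming (steps ≥ 5 px/s by default); mean absolute turning
angle between successive displacement vectors; arena area covered as the
fraction of 32-px grid cells visited; minimum distance of approach to a
novel object; time within 100 px of the object. Metrics never bridge
absence gaps, and undefined quantities are reported as missing, never as 0.

**Synthetic arena.** A generative stand-in for real videos with known
parameters: two-state Markov shelter occupancy, a correlated random walk
(wrapped-Cauchy turning, half-normal step lengths, border reflection),
Beta-law detector scores conditioned on true presence, Gaussian centroid
jitter and a rare relocation outlier. Every pipeline stage is verified by
recovering these parameters.

## Worked example

A scenario file describes the arena and the detector noise:

```yaml
# scenario.yaml
seed: 42
scenario: {n_activity: 2, n_exploration: 1}
simulation: {duration: 1800, p_exit: 0.02, p_enter: 0.01,
             step_sigma: 20.0, persistence: 0.6}
noise: {jitter_sigma: 5.0, outlier_prob: 0.01}
```

```sh
arenatrack simulate --config scenario.yaml --out data
arenatrack validate-classification --config scenario.yaml --data-dir data --out cls
arenatrack validate-positioning    --config scenario.yaml --data-dir data --out pos --n-frames 300 --seed 42
arenatrack metrics                 --config scenario.yaml --data-dir data --out met --threshold 0.5
```

The classification sweep prints (pooled "Total" rows):

```
test_type  threshold  n_videos  mean_pct   sd_pct    ci_low   ci_high      rmse  present_mean_pct  absent_mean_pct
    Total        0.5         3 97.907407 0.394144 97.461391 98.353424 14.465796         98.085679        97.709179
    Total        0.9         3 49.185185 9.909519 37.971509 60.398861 71.284511         22.199281       100.000000
```

At τ = 0.5 the detector agrees with the manual annotation on 97.9% of frames
(Beta(8,2)/Beta(2,8) scores put ≈2% of mass on the wrong side of 0.5);
raising τ to 0.9 trades presence sensitivity (22.2%) for perfect absence
calls — the threshold sweep makes that trade-off explicit. The positioning
report,

```
n=300 mean=10.44 sd=41.27 [5.77-15.11] rmse=42.50 success=99.0% (threshold 80.2 px)
```

shows the signature of a 1% relocation-outlier mixture: a small mean error
(5-px jitter ⇒ Rayleigh mean ≈ 6.3 px) with a far larger SD, yet 99.0% of
localizations within the 80.2-px mean-box-side criterion. The metrics table
is tidy CSV, one row per video and metric (e.g. `exp00` spent 1185 s outside,
approached the object to 25.6 px and spent 18 s within 100 px of it).

Each command writes a `manifest.json` (config, seed, version), so
deterministic stages reproduce bit-for-bit. Every command is also available
as a library function (`arenatrack.sweep`, `summarize_positioning`,
`activity_metrics`, …).

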