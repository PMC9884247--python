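# Methods

This note documents the models and procedures implemented in `pursuitmvpa`,
the parameter choices that matter, and what the synthetic validation
studies do and do not establish.

## Conventions

All time axes are uniform 1-ms grids in milliseconds relative to pursuit-
target (stimulus) onset; the default axis is −100…500 ms. Directions are
signed degrees, 0° = rightward, negative = clockwise (downward), so the
task's three directions are 0°, −30°, −60°. Velocities are in deg/s,
positions and IRVE in deg. "Rotating a trace by ρ" means expressing its
velocity vector in a coordinate frame rotated by ρ, so a vector pointing
along ρ becomes purely horizontal.

## Synthetic-data generator

The generator produces the statistical structure the analysis assumes, not
biophysically realistic recordings.

**Behavior.** The executed pursuit direction is the reliability-weighted
circular mean (unit-vector average) of target and cue directions, with
weights r_target(contrast) and r_cue. Defaults r_cue = 1,
r_target = 8 at 100% contrast and 2 at 12% — chosen so cue attraction for a
60° cue–target conflict is ≈7° at high and ≈20° at low contrast, a
noticeable but sub-total pull. Latency is Gaussian per trial with mean
124 ms at 12% contrast (the measured low-contrast value) and 105 ms at
100% (a plausible default; the high-contrast mean is not empirically
anchored), jitter SD 10 ms. After latency, eye speed follows
`g_ss · v_target · (1 − exp(−λ(t − latency)))` with rate λ = 0.025/ms
(≈40 ms time constant) and steady-state gain g_ss = 0.9: open-loop pursuit
undershoots target velocity before visual feedback corrects it, which
leaves a persistent retinal velocity error — the reason the IRVE keeps
growing after the velocity traces have saturated. Position is the
trapezoidal integral of velocity. With probability `saccade_rate` a trial
receives a brief (≤30 ms) transient of 35–50 deg/s peak speed inside
−100…250 ms, for screening tests.

**Epochs.** Channel c of trial k is
`w_s · P_s[c, dir] · |IRVE|(t + t_s) + w_m · P_m[c, dir] · speed(t + t_m) + ε`,
with direction-specific spatial patterns P_s, P_m drawn once from
`spatial_pattern_seed`, true mixture (w_s, w_m) = (1.0, 0.5) and shifts
(t_s, t_m) = (−35, +27) ms (negative = sensory leads the channels). Noise
is Gaussian with a rank-`noise_spatial_rank` shared spatial component plus
a 25%-variance white floor (so covariances stay full rank), channel SD
`noise_sd` = 0.5. Everything is deterministic given the config: identical
seed + config → bit-identical arrays.

**What the generator does not emulate:** oscillatory band structure,
volume conduction, eyeblink artifacts, nonstationary noise, inter-day
amplitude drift beyond the day label itself, catch-up saccade dynamics.
Tests passing on this generator therefore establish correctness of the
*analysis machinery* and of directional/qualitative predictions, not
quantitative agreement with any real recording.

## Behavioral statistics

Screening rejects a trial if eye speed exceeds 5 deg/s anywhere in
−100…100 ms (fixation) or 20 deg/s in 100…250 ms (pursuit); fixation
violations take precedence in the reported reason. Screening is idempotent.

Latency estimation: baseline speed over −100…0 ms; threshold = baseline
mean + 3 SD (absolute 2 deg/s fallback for a zero-variance baseline);
first crossing in 50…300 ms sustained ≥20 ms, then walked back to where
speed last sat at baseline + 1 SD, so the estimate is the movement onset
rather than the threshold-crossing time. The exact estimator is a
documented in-house choice of standard oculomotor form; its parameters are
exposed.

Rotated-trace distance: Δy(t) = |mean rotated-vertical(upper) − mean
rotated-vertical(lower)| (absolute separation; a full 2-D Euclidean metric
is available). With both validity blocks present, ΔΔy = Δy(valid) −
Δy(invalid), evaluated on a −100…100 ms axis centred on each block's mean
estimated latency, and summarised at +100 ms (the end of the open-loop
period). Δy is invariant to a common velocity offset and rotation
preserves speed sample-wise.

## Cross-validated Mahalanobis dissimilarity

Preprocessing: per-channel rectangular smoothing over ±10 ms (21-sample
window, edge-replicating), per-day division by the day's global maximum
absolute value, then per-channel z-scoring over times × trials
(zero-variance channels are zeroed, logged).

At each time point the per-condition channel covariances are pooled with
trial-count weights and pseudo-inverted. Because tens of trials poorly
condition a 47-channel covariance, a shrinkage policy is applied before
inversion: `none`, fixed-λ toward the scaled identity (default λ = 0.1), or
Ledoit–Wolf with the coefficient estimated from the within-condition-
centred patterns. The "pooling + shrinkage + pseudo-inverse" combination is
our reading of covariance variance-stabilization; the policy is pluggable
precisely because the canonical choice is not settled.

D₁₂ − D₁₁ uses leave-one-trial-out means: the held-out trial is excluded
from its own condition's mean (n−1 trials) but the other condition's mean
uses all n trials. Both condition-role assignments are computed and
averaged (symmetrization — the asymmetric single-role variant is
available). Unequal trial counts are handled by averaging over 10 seeded
random subsamples of the larger set; with equal counts the computation is
a single pass and seed-independent. A non-cross-validated variant exists
only as a falsification target in the tests: it is positively biased under
exchangeability, while the cross-validated estimator is centred on zero.
(Literal leave-one-out introduces a small O(1/n) asymmetry — own mean from
n−1 trials, other mean from n — negligible at the tested sizes relative to
Monte-Carlo error.)

Eye-movement features use identical machinery with the two "channels"
being the horizontal and vertical components. Channel-subset analysis
operates on a synthetic 64-name montage (standard 10-10 labels); the
default analysis set drops 17 muscle/noise-prone channels (47 remain), and
built-in regional groups cover frontal-central (13) and central-parietal
(14) electrodes.

## Time-shifted linear model

E(t) = w_s S_IRVE(t + t_s) + w_m M_vel(t + t_m), fitted simultaneously to
the four condition cells (validity × contrast) over 30…330 ms with one
shared parameter set and equal weight per condition. Regressors are
max-min normalized jointly across conditions and time points (zero-range
regressors are zeroed, logged); the neural trace is left on its native
scale. The full variant adds S_RVE (sharing t_s) and M_pos (sharing t_m):
six free parameters.

Because the weights enter linearly, they are profiled out by OLS at each
candidate integer-ms (t_s, t_m) pair and the global optimum inside the
shift bounds (default ±100 ms, covering the physiologically expected
−35/+27 ms with margin) is found by exhaustive grid scan — deterministic
and exactly reproducible, replacing derivative-free restart searches.
Collinear candidates are solved by the least-norm (pseudo-inverse)
solution and flagged. RSS ties are broken toward the smallest
|t_s| + |t_m|. A seeded multistart hill-climb (8-neighbour moves, step
schedule 16→1) is provided and matches the grid optimum in practice. No
intercept by default (the model has none); with the intercept option the
residual mean is exactly zero. Variance explained is 1 − RSS/TSS about the
grand mean of the concatenated neural trace.

Residual analysis returns observed − predicted per condition and the
valid − invalid residual difference per contrast — the carrier of any
cue-validity effect the sensory/motor model cannot absorb — ready for the
cluster test.

## Cluster-based permutation inference

One-sample t across participants at each time point; contiguous runs of
same-sign samples with two-sided p below the cluster-defining threshold
(0.05 or 0.01 in practice) form clusters with mass Σt. The null
distribution is the maximum |mass| over participant-level sign flips
(both signs jointly → two-sided family-wise control), with the
(count + 1)/(n_perm + 1) p-value convention. Sign flipping is the exact
exchangeability scheme for a test against zero; paired comparisons are
run on the participant-wise difference. 50,000 permutations is the
production default; calibration studies use 1,000 for tractability, which
only coarsens the p-value grid.

## Validation studies (problem sizes)

The studies in `pursuitmvpa.validation` (run by `scripts/acceptance.py`
and the test suite) use sizes chosen to give stable Monte-Carlo estimates
at desk scale: oracle agreement on 20 random instances (≤4 channels, ≤10
trials); null calibration over 200 exchangeable datasets of 100
trials/condition; shift/weight recovery over 100 noise replicates at 25%
noise, with regressor shapes taken from the generator's own noise-free
IRVE and velocity separation curves; cluster FWER over 500 null replicates
and power over 200 injected-effect replicates (14 participants, 1-SD,
50-ms boxcar); cue-attraction ordering at 200 trials/cell.

## Known limitations

* The behavioral ramp is a one-parameter exponential; real pursuit shows
  richer acceleration profiles and catch-up saccades.
* Per-time-point covariance estimation (matching "at each time point")
  ignores temporal smoothness beyond the 20-ms smoothing window; a
  time-pooled covariance option would trade bias for stability.
* The linear model assumes a single latency per signal class across the
  whole window and across conditions.
* Scalar t-tests assume approximate normality across participants; no
  nonparametric scalar alternative is provided.
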