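# Methods

## Coordinate and sign conventions

The package fixes a right-handed frame, y up, listener at the origin facing
−z at trial start.  Azimuth is measured in the horizontal (x–z) plane, 0°
straight ahead, positive to the listener's right, range (−180°, 180°].
Signed error is defined as response minus target, so a positive mean is a
rightward response shift; under this convention an eccentricity
*undershoot* (responses compressed toward the midline) appears as a
**negative** slope of the signed-error means against target azimuth.  The
same coupling described with the opposite subtraction order flips the sign
only; magnitudes are unaffected.

Yaw is extracted by rotating the forward unit vector (0, 0, −1) with the
orientation quaternion (stored scalar-first) and projecting onto the
horizontal plane.  This avoids Euler-order ambiguity; orientations whose
projection has norm < 1e−9 (gaze straight up/down) raise a degenerate-
orientation error, and the vectorized path carries the last valid yaw
forward.  Yaw at response time is the nearest sample (ties to the earlier
one), not an interpolation — at 10 Hz any interpolation model would be an
unverifiable assumption.

## Per-trial measures and the outlier filter

Head distance is the raw cumulative Euclidean path length of the head
position over samples within [t_onset, t_hit]; no smoothing is applied, and
a minimum-displacement threshold (default 0 m) is available for noisy
trackers.  Whether samples outside the stimulus window should count is a
genuine ambiguity; the package clips to the window.

The outlier rule flags trials whose unsigned error is strictly greater than
mean + k·SD (default k = 2, sample SD with ddof = 1) within a stratum.
Strata are per target location; the pooling level is configurable
(`per_condition` default, `fully_pooled`, `per_participant`).  Pooling
within condition keeps the tight real-environment error scale from being
inflated by the wider virtual-environment one.  The filter is single-pass
and non-destructive: flags are set, exclusion is the caller's decision.
Note that trimming the upper error tail slightly attenuates estimated
response biases; parameter-recovery checks therefore run on unfiltered
metrics.  The flagged percentage is reported both raw and rounded to two
decimals (round-half-even), since display rounding conventions vary.

## Inferential battery

Levene's test uses mean centering (the classical statistic; median
centering, i.e. Brown–Forsythe, is an option).  Mean comparisons use
Welch's ANOVA/t with Welch–Satterthwaite degrees of freedom when Levene
rejects homogeneity at α, otherwise the classical one-way F.  All tests are
two-tailed.  Bonferroni correction requires an explicitly declared family
size m (adjusted p = min(1, m·p)); the pipeline's default family is the set
of mean comparisons per measure, and the m actually used is recorded in the
output table.  Post-hoc power is computed from the noncentral t (two-sample
designs, noncentrality d·√(n₁n₂/(n₁+n₂))) or noncentral F (one-way,
noncentrality f²·N) at the observed standardized effect — the usual caveat
applies that post-hoc power is a monotone transform of the p-value.
Standard tests are delegated to scipy and pingouin; the unit tests verify
them against independent textbook-formula and Monte-Carlo oracles.

Eccentricity regressions are ordinary least squares **on the per-azimuth
means** (≤13 points), not on raw trials, so the fit is not dominated by
whichever azimuth has more retained trials.  When the response means have
zero variance, r² is defined as 0.

## Envelope and quadrant statistics

Unsigned errors are binned at 1° (half-open bins centered on integers,
matching the 1° pointer resolution).  Each bin's upper bound is
mean(h) + k·SD(h); k = 1.96 labels the two-sided normal 95% level and
k = 3.0 the 99.7% level.  Bins with fewer than two trials have no sample SD
and are excluded (and reported).  Both envelope fits are unweighted OLS
across bins; the logarithmic model uses the natural log (a base change only
rescales A).  The `max` constant in the log model is the largest unsigned
error of the analyzed subset.

The quadrant curve sweeps candidate corners over the sorted unique ε
values; at each corner the height is the k-th largest h among points with
ε ≥ ε₀, where k = round(fraction·N), minimum 1.  With distinct h values the
closed quadrant then contains exactly k points; with ties it contains the
smallest achievable count ≥ k.  Monotonicity (h₀ non-increasing in ε₀)
follows because the k-th largest of a subset cannot exceed the k-th largest
of its superset; the tests nevertheless verify every returned corner by
brute-force O(N) counting.  The quartile split uses the linearly
interpolated 75th percentile of head distance.

## Synthetic sessions

The generator emulates the structure of a two-condition (R/V), two-order-
group study: 37 participants (17 R-first, 20 V-first), 13 azimuths × 5
repetitions per condition in seeded randomly balanced order, 10 Hz
trajectories.  Defaults: rightward bias per group × condition of
1.9/2.5/1.7/0.6°, undershoot 3% of target azimuth, static response noise SD
2.8° (R) / 4.9° (V), lognormal latencies with means ≈3.2 s (R) / ≈4.0 s
(V), and a strategy mixture with p_dynamic = 0.3.

The movement–accuracy coupling is implemented through that mixture rather
than a causal law: *dynamic* trials draw small response noise (SD 1.5°),
end with the head tightly on target (divergence SD 8°), and translate by
sweeping a 9 cm neck-pivot arc plus a decaying scanning oscillation (≤30°
amplitude); *static* trials keep the tracker near its origin apart from
smoothed postural sway (2 mm SD, moving-averaged over 0.5 s so the sway is
low-frequency rather than white), while still orienting loosely toward the
target (divergence SD 21°).  Static heads rotate about their own axis
without the pivot-arm translation — treating the pivot sweep as part of the
active-search strategy — because a frontal-hemifield divergence spread of
~20° requires even low-movement listeners to orient partially toward the
source.  The yaw path is a damped exponential approach (time constant drawn
from 0.3–1.0 s) scaled to hit the drawn final yaw exactly at response time.
Response rounding to 1° is applied after noise, matching pointer
resolution.

All draws pass through a single `numpy.random.Generator` seeded from
`SimConfig.seed`; identical configurations are bitwise reproducible.

What the generator does *not* emulate: acoustic cues (ITD/ILD/HRTF),
front–back confusions, learning or fatigue dynamics within a session,
velocity profiles of real head movements, and tracker dropout.  Passing
tests therefore demonstrate that the pipeline recovers known parameters
from data *with this structure*, not that real listeners behave like the
model.

## Problem sizes and tolerances

The test suite exercises the full 4810-trial default once (a few seconds)
and uses 6-participant sessions elsewhere.  Parameter recovery runs 50
seeds of 4-participant studies and checks the injected bias (2°) and
undershoot slope (0.03) against 95% Monte-Carlo confidence intervals of the
seed means, plus the sign of the envelope slope on every seed.  Null
calibration of Levene and Welch's t uses 2000 replicates at n = 30 per
group against the 95% binomial band around α = 0.05 — a check that a
correctly calibrated test still fails with ~5% probability per seed, which
is inherent to the criterion, not a defect.  Exact identities (Welch F = t²
for two groups, Spearman = Pearson-on-ranks, quaternion yaw vs the
rotation-matrix expansion, quadrant corners vs brute-force counting) are
asserted at 1e−9–1e−12.

## Known limitations

* The envelope bound mean + k·SD is a normal-theory label; for skewed
  within-bin h distributions the nominal 95/99.7% coverage is approximate.
* The quadrant curve is undefined once fewer than k points remain to the
  right; the curve simply terminates there.
* Post-hoc power at the observed effect should not be read as a design
  property of future experiments.
* `pingouin` computes the Welch ANOVA; its two-group F is verified against
  Welch's t² in the tests rather than re-derived.
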