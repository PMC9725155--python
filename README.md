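# audioloc

Analysis pipeline for horizontal auditory-localization experiments with
head-tracked listeners.  It is written for auditory psychophysicists who
record, per trial, a pointed azimuth and a ~10 Hz stream of head position
and orientation, and who want to ask: *does spontaneous head movement go
together with accurate localization?*

## What it computes

For each trial with target azimuth θ and response azimuth θ̂ (degrees,
rightward positive, frontal hemifield −90°…+90°):

* **signed error** = θ̂ − θ (positive = rightward shift), **unsigned
  error** ε = |θ̂ − θ|, **latency** = t_hit − t_onset;
* **head divergence** = θ − yaw(t_hit), the circular difference between the
  target and the head's horizontal orientation at response time, with yaw
  extracted by rotating the forward vector by the tracking quaternion and
  projecting onto the horizontal plane;
* **head distance** h = Σᵢ‖pᵢ₊₁ − pᵢ‖ over samples in [t_onset, t_hit],
  the head's translational path length in meters.

Trials with ε > mean + 2·SD per target location (per condition) are flagged
as outliers.  The inferential battery is Levene's test followed by Welch's
heteroscedasticity-robust ANOVA/t (or the classical F when variances are
homogeneous), Spearman correlations, explicit-family Bonferroni correction,
and post-hoc power from the noncentral t/F.

The package's distinctive statistics quantify the *triangular* shape of the
(ε, h) scatter — large head movement co-occurring only with small error:

* **envelope regressions**: per 1° error bin, the upper bound
  h_{p,ε} = mean(h) + k·SD(h) (k = 1.96 → 95%, k = 3 → 99.7%), fitted as
  h_{p,ε} ≈ m·ε + q and as h_{p,ε} ≈ A_p·log(max + 1 − ε) + B_p, where
  *max* is the largest unsigned error;
* **quadrant-partition curve**: the frontier of corners (ε₀, h₀) whose
  closed upper-right quadrants {ε ≥ ε₀, h ≥ h₀} each contain exactly
  k = round(0.05·N) trials;
* **quartile split**: head-divergence mean/SD above vs below the third
  quartile of head distance.

A seeded synthetic-session generator (`SimConfig`, `generate_dataset`)
produces complete studies — trial logs plus 10 Hz trajectories — with known
ground truth, so every stage of the pipeline is testable without access to
private raw data.

## Worked example

```sh
python examples/04_envelope_and_quadrant.py
```

prints (seed 42, 37 synthetic participants):

```
95% envelope: linear m=-0.0160, q=0.285, r^2=0.89 | log A=+0.0691, B=+0.0818, r^2=0.73
99.7% envelope: linear m=-0.0216, q=0.367, r^2=0.88 | log A=+0.0934, B=+0.0926, r^2=0.72

quadrant frontier: k=62 of 1247 points per corner
  corner (eps >= 0 deg, h >= 0.247 m) holds exactly 62 trials
  ...
above Q3 of head distance (0.143 m): divergence mean -0.11 vs +1.22 deg below
(closer to zero by 90.8%), SD 9.3 vs 20.0 deg (53.2% smaller)
```

The negative envelope slopes say the ceiling on head movement shrinks as
error grows; the quartile split says high-movement trials end with the head
aimed at the source.  Together: head movement is *sufficient*, but not
*necessary*, for accurate horizontal localization.  The other examples
(`examples/01…05`) walk through simulation, per-trial metrics, the
statistical battery, and the end-to-end pipeline; the same functionality is
available from the shell via `audioloc simulate` and `audioloc run`.

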