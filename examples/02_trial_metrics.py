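"""Per-trial measures and the 2-SD outlier filter.

Signed error is response minus target (positive = rightward shift), head
divergence is how far the head points from the source at response time,
and head distance is the head's translational path length during the trial.
"""

import audioloc as al

records, trajectories, _ = al.generate_dataset(al.SimConfig(seed=42))
metrics = al.flag_outliers(al.compute_metrics(records, trajectories))

summary = al.outlier_summary(metrics)
print(
    f"outliers: {summary.n_flagged} of {summary.n_total} trials "
    f"({summary.pct_raw:.3f}%, displayed {summary.pct_2dp}%)"
)
print("\nsigned error by group and condition (outliers excluded):")
for s in al.summarize(metrics, "signed_error"):
    print(f"  {s.group} in {s.condition}: mean {s.mean:+.2f} deg, SD {s.sd:.2f} deg (n={s.n})")
print("\nlatency by group and condition:")
for s in al.summarize(metrics, "latency"):
    print(f"  {s.group} in {s.condition}: mean {s.mean:.2f} s")
# Positive means in every cell = the rightward response bias; R-condition
# errors are tighter than V because the loudspeakers are visible.
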