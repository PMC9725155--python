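"""Pipeline orchestration: read -> kinematics -> metrics -> outlier filter
-> inferential battery -> envelope analysis, with every result surface
written as a machine-readable table under one output directory plus a
checksummed manifest.

The test-selection logic mirrors the standard heteroscedasticity-aware
battery: Levene's test first; if variances differ at the configured alpha
the mean comparison uses Welch's ANOVA/t, otherwise the classical ANOVA F.
Bonferroni correction is applied per comparison family with the family
size recorded in the output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .envelope import (
    EnvelopeFit,
    QuadrantCurve,
    QuartileSplit,
    fit_envelope,
    quadrant_curve,
    quadrant_emptiness,
    quartile_split_divergence,
)
from .exceptions import ValidationError
from .io import (
    StudyConfig,
    read_trajectories,
    read_trial_log,
    write_metrics_table,
)
from .metrics import (
    TrialMetrics,
    compute_metrics,
    flag_outliers,
    metrics_to_frame,
    summarize,
)
from .stats import (
    StatResult,
    anova_f,
    bonferroni,
    eccentricity_regression,
    per_participant_spearman,
    welch_anova,
    levene_test,
    with_power,
)

MEASURES = ("signed_error", "unsigned_error", "latency", "head_divergence", "head_distance")


@dataclass(frozen=True)
class OutlierSummary:
    n_flagged: int
    n_total: int
    pct_raw: float  # 100 * n_flagged / n_total at full precision
    pct_2dp: float  # the same, rounded (half-even) to 2 decimals


def outlier_summary(metrics: Sequence[TrialMetrics]) -> OutlierSummary:
    """Count flagged trials; the percentage is reported both raw and at two
    decimals, since rounding conventions differ across reporting styles."""
    n_total = len(metrics)
    if n_total == 0:
        raise ValidationError("no trials")
    n_flagged = sum(m.is_outlier for m in metrics)
    raw = 100.0 * n_flagged / n_total
    return OutlierSummary(n_flagged, n_total, raw, round(raw, 2))


@dataclass
class AnalysisReport:
    """Everything the pipeline computed, plus where it was written."""

    outdir: Path
    config: StudyConfig
    metrics: list[TrialMetrics]
    outliers: OutlierSummary
    group_summaries: pd.DataFrame
    stats_table: pd.DataFrame
    eccentricity_fits: pd.DataFrame
    participant_correlations: pd.DataFrame
    envelopes: list[EnvelopeFit]
    envelope_table: pd.DataFrame
    quadrant: QuadrantCurve
    quartile_split: QuartileSplit
    manifest: dict


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    return float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0


def _compare_two(
    label: str, a: np.ndarray, b: np.ndarray, alpha: float
) -> list[dict]:
    """Levene, then Welch ANOVA (heteroscedastic) or classical ANOVA."""
    lev = levene_test([a, b])
    mean_test = welch_anova([a, b]) if lev.p_value < alpha else anova_f([a, b])
    d = abs(_cohens_d(a, b))
    mean_test = with_power(mean_test, [len(a), len(b)], d, alpha=alpha)
    rows = []
    for res in (lev, mean_test):
        rows.append(
            {
                "analysis": label,
                "test": res.test,
                "statistic": res.statistic,
                "dof1": res.dof[0],
                "dof2": res.dof[1] if len(res.dof) > 1 else np.nan,
                "p": res.p_value,
                "power": res.power if res.power is not None else np.nan,
            }
        )
    return rows


def build_stats_table(metrics: Sequence[TrialMetrics], config: StudyConfig) -> pd.DataFrame:
    """Comparison families: per measure, groups within each condition and
    conditions within each group; Bonferroni per family."""
    df = metrics_to_frame(list(metrics))
    df = df[~df["is_outlier"]]
    frames = []
    for measure in MEASURES:
        rows: list[dict] = []
        for cond in ("R", "V"):
            sub = df[df["condition"] == cond]
            a = sub.loc[sub["group"] == "G_R", measure].to_numpy()
            b = sub.loc[sub["group"] == "G_V", measure].to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                rows += _compare_two(f"{measure}: G_R vs G_V in {cond}", a, b, config.alpha)
        for grp in ("G_R", "G_V"):
            sub = df[df["group"] == grp]
            a = sub.loc[sub["condition"] == "R", measure].to_numpy()
            b = sub.loc[sub["condition"] == "V", measure].to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                rows += _compare_two(f"{measure}: R vs V in {grp}", a, b, config.alpha)
        fam = pd.DataFrame(rows)
        if len(fam):
            # the family is the mean comparisons for this measure
            is_mean = fam["test"] != "levene"
            m = config.bonferroni_m if config.bonferroni_m is not None else int(is_mean.sum())
            fam["p_adj"] = np.nan
            fam.loc[is_mean, "p_adj"] = bonferroni(fam.loc[is_mean, "p"].tolist(), m)
            fam["bonferroni_m"] = m
            frames.append(fam)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(
    trials_path: str | Path,
    trajectories_path: str | Path,
    config: StudyConfig | str | Path | None = None,
    outdir: str | Path = "audioloc_out",
    figures: bool = False,
) -> AnalysisReport:
    """Execute the full analysis and write all tables under ``outdir``.

    Deterministic: identical inputs and config give byte-identical outputs.
    Every trial must have a trajectory; a missing one raises
    :class:`ValidationError` naming the trial.
    """
    if config is None:
        config = StudyConfig()
    elif not isinstance(config, StudyConfig):
        config = StudyConfig.from_yaml(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = read_trial_log(trials_path, azimuth_set=config.azimuth_set)
    trajectories = read_trajectories(trajectories_path)
    metrics = compute_metrics(records, trajectories)
    metrics = flag_outliers(metrics, k=config.outlier_k, strata=config.outlier_strata)
    outliers = outlier_summary(metrics)

    summaries = []
    for measure in MEASURES:
        for s in summarize(metrics, measure):
            summaries.append({"measure": measure, **dataclasses.asdict(s)})
    group_summaries = pd.DataFrame(summaries)

    stats_table = build_stats_table(metrics, config)

    gv = [m for m in metrics if m.group == "G_V"]
    ecc_rows = []
    for cond in ("R", "V"):
        for measure in ("signed_error", "unsigned_error", "head_divergence", "head_distance"):
            try:
                fit = eccentricity_regression(gv, measure, cond)
            except ValidationError:
                continue
            ecc_rows.append(
                {
                    "group": "G_V",
                    "condition": cond,
                    "measure": measure,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                    "n_locations": fit.n_points,
                }
            )
    eccentricity_fits = pd.DataFrame(ecc_rows)

    gv_v = [m for m in gv if m.condition == "V" and not m.is_outlier]
    corr = per_participant_spearman(gv_v, alpha=config.alpha)
    participant_correlations = pd.DataFrame([dataclasses.asdict(c) for c in corr])

    eps = np.array([m.unsigned_error for m in gv_v])
    h = np.array([m.head_distance for m in gv_v])
    max_error = float(eps.max()) if len(eps) else 0.0
    envelopes = [
        fit_envelope(eps, h, label, k_sd, bin_width=config.bin_width, max_error=max_error)
        for label, k_sd in config.envelope_levels
    ]
    envelope_table = pd.DataFrame(
        [
            {
                "regression_type": "linear",
                "level": e.level_label,
                "slope_or_A": e.linear.slope,
                "intercept_or_B": e.linear.intercept,
                "r_squared": e.linear.r_squared,
                "n_bins": e.linear.n_points,
            }
            for e in envelopes
        ]
        + [
            {
                "regression_type": "logarithmic",
                "level": e.level_label,
                "slope_or_A": e.log.A,
                "intercept_or_B": e.log.B,
                "r_squared": e.log.r_squared,
                "n_bins": e.log.n_points,
            }
            for e in envelopes
        ]
    )
    quadrant = quadrant_curve(eps, h, fraction=config.quadrant_fraction)
    qsplit = quartile_split_divergence(h, np.array([m.head_divergence for m in gv_v]))

    # ---- write everything ----
    paths: dict[str, Path] = {}
    paths["metrics"] = write_metrics_table(metrics, outdir / "metrics.csv")
    for name, frame in [
        ("group_summaries", group_summaries),
        ("stats", stats_table),
        ("eccentricity_fits", eccentricity_fits),
        ("participant_correlations", participant_correlations),
        ("envelope_table", envelope_table),
    ]:
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False, float_format="%.12g")
        paths[name] = p
    qc = pd.DataFrame({"eps0": quadrant.eps0, "h0": quadrant.h0})
    paths["quadrant_curve"] = outdir / "quadrant_curve.csv"
    qc.to_csv(paths["quadrant_curve"], index=False, float_format="%.12g")

    results = {
        "outliers": dataclasses.asdict(outliers),
        "quartile_split": dataclasses.asdict(qsplit),
        "quadrant": {"fraction": quadrant.fraction, "k": quadrant.k, "n_total": quadrant.n_total},
        "envelope_emptiness_997_linear": quadrant_emptiness(eps, h, envelopes[-1].linear),
    }
    paths["results"] = outdir / "results.json"
    with open(paths["results"], "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=1, sort_keys=True)

    if figures:
        _write_figures(metrics, envelopes, quadrant, qsplit, eps, h, outdir, paths)

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "inputs": {
            "trials": str(trials_path),
            "trajectories": str(trajectories_path),
        },
        "files": {name: {"path": p.name, "sha256": _sha256(p)} for name, p in paths.items()},
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return AnalysisReport(
        outdir=outdir,
        config=config,
        metrics=metrics,
        outliers=outliers,
        group_summaries=group_summaries,
        stats_table=stats_table,
        eccentricity_fits=eccentricity_fits,
        participant_correlations=participant_correlations,
        envelopes=envelopes,
        envelope_table=envelope_table,
        quadrant=quadrant,
        quartile_split=qsplit,
        manifest=manifest,
    )


def _write_figures(metrics, envelopes, quadrant, qsplit, eps, h, outdir: Path, paths: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(eps, h, s=4, alpha=0.3, color="gray", label="trials")
    xs = np.linspace(0, eps.max() if len(eps) else 1, 100)
    for env, color in zip(envelopes, ("tab:blue", "tab:red")):
        ax.plot(
            xs,
            env.linear.slope * xs + env.linear.intercept,
            color=color,
            label=f"{env.level_label}% linear",
        )
        ax.plot(
            xs,
            env.log.A * np.log(env.log.max_error + 1 - xs) + env.log.B,
            color=color,
            linestyle="--",
            label=f"{env.level_label}% log",
        )
    ax.step(quadrant.eps0, quadrant.h0, where="post", color="magenta", label="5% data up right")
    ax.set_xlabel("unsigned error (deg)")
    ax.set_ylabel("head distance (m)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    p = outdir / "envelope.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["figure_envelope"] = p
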