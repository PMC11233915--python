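"""End-to-end pipeline: simulate -> qc -> metrics -> analyse -> report.

A run is driven by a single serializable :class:`RunConfig`; the effective
configuration is archived in the run directory together with every stage's
outputs and row counts, so each reported number is traceable to a stage
output file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import kinematics, mixed_stats, synthetic_data, trace_io

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "render_report"]

log = logging.getLogger("whiskkin")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    When ``simulate`` is true the cohort is generated from
    ``synthetic`` with ``seed``; otherwise ``traces`` and ``metadata``
    must point at existing tables.  ``allow_unvetted`` lets QC-failed
    clips through to the metrics stage (off by default).
    """

    out_dir: str = "whiskkin_run"
    simulate: bool = True
    seed: int = 0
    traces: str | None = None
    metadata: str | None = None
    synthetic: synthetic_data.SyntheticConfig = field(
        default_factory=synthetic_data.SyntheticConfig
    )
    qc: trace_io.QcConfig = field(default_factory=trace_io.QcConfig)
    kinematics: kinematics.KinematicsConfig = field(
        default_factory=kinematics.KinematicsConfig
    )
    alpha: float = 0.05
    allow_unvetted: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["animals_per_cell"] = {
            f"{k[0]}:{k[1]}": v for k, v in self.synthetic.animals_per_cell.items()
        }
        d["synthetic"]["effects"] = {
            synthetic_data.cell_label(*k): dict(v)
            for k, v in self.synthetic.effects.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        syn = dict(d.pop("synthetic", {}))
        if "animals_per_cell" in syn:
            syn["animals_per_cell"] = {
                tuple(k.split(":")): v for k, v in syn["animals_per_cell"].items()
            }
        if "effects" in syn:
            syn["effects"] = {
                tuple(k.split(":")): dict(v) for k, v in syn["effects"].items()
            }
        if "dc" in syn:
            syn["dc"] = synthetic_data.DcModulation(**syn["dc"])
        for key in ("clips_per_animal", "pc_frames", "dc_frames", "whiskers_per_side"):
            if key in syn:
                syn[key] = tuple(syn[key])
        kwargs = dict(d)
        kwargs["synthetic"] = synthetic_data.SyntheticConfig(**syn)
        if "qc" in d:
            kwargs["qc"] = trace_io.QcConfig(**d["qc"])
        if "kinematics" in d:
            kwargs["kinematics"] = kinematics.KinematicsConfig(**d["kinematics"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Stage order: simulate (optional) -> qc -> metrics -> analyse.  Each
    stage logs its row counts; a failure raises :class:`PipelineError`
    naming the stage, with earlier outputs left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

    # --- stage: input acquisition
    try:
        if config.simulate:
            cohort = synthetic_data.generate_cohort(config.synthetic, config.seed)
            traces, metadata = cohort.traces, cohort.metadata
            trace_io.write_traces(traces, out / "traces.csv", overwrite=True)
            trace_io.write_metadata(
                metadata.values(), out / "metadata.csv", overwrite=True
            )
            cohort.ground_truth.to_csv(out / "ground_truth.csv", index=False)
        else:
            if not (config.traces and config.metadata):
                raise ValueError("traces and metadata paths required when simulate=False")
            traces = trace_io.read_traces(config.traces)
            metadata = trace_io.read_metadata(config.metadata)
    except Exception as err:
        raise PipelineError(f"input stage failed: {err}") from err
    log.info("input: %d trace rows, %d clips", len(traces), len(metadata))

    # --- stage: qc
    try:
        reports = trace_io.qc_cohort(traces, metadata, config.qc)
        trace_io.write_qc_report(reports, out / "qc_report.csv")
    except Exception as err:
        raise PipelineError(f"qc stage failed: {err}") from err
    passed = [r.clip_id for r in reports if r.passed]
    log.info("qc: %d/%d clips passed", len(passed), len(reports))

    # --- stage: metrics
    keep = sorted(metadata) if config.allow_unvetted else passed
    if not keep:
        raise PipelineError(
            "metrics stage failed: no clip passed QC "
            "(set allow_unvetted to override)"
        )
    try:
        metrics = kinematics.metrics_table(traces, metadata, keep, config.kinematics)
        trace_io.write_metrics_table(metrics, out / "metrics.csv", overwrite=True)
    except Exception as err:
        raise PipelineError(f"metrics stage failed: {err}") from err
    log.info("metrics: %d clips", len(metrics))

    # --- stage: analyse
    try:
        report = mixed_stats.analysis_suite(metrics, alpha=config.alpha)
        report.models.to_csv(out / "model_ftable.csv", index=False)
        report.posthoc.to_csv(out / "posthoc.csv", index=False)
        report.errors.to_csv(out / "model_errors.csv", index=False)
        summary = {
            "n_clips_in": len(metadata),
            "n_clips_passed_qc": len(passed),
            "n_clips_analysed": len(metrics),
            "alpha": config.alpha,
            "n_models": int(report.models[["stage", "stratum", "response"]]
                            .drop_duplicates().shape[0]) if len(report.models) else 0,
            "n_significant_terms": int((report.models["p"] < config.alpha).sum())
            if len(report.models)
            else 0,
            "n_posthoc_contrasts": len(report.posthoc),
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    except Exception as err:
        raise PipelineError(f"analyse stage failed: {err}") from err
    log.info("analyse: %d model terms, %d post-hoc contrasts",
             len(report.models), len(report.posthoc))
    return out


def render_report(run_dir: str | Path, example_clips: int = 1) -> Path:
    """Render figures and a plain-text summary from a completed run.

    Produces per-metric bar charts of treatment x sex x texture cell means
    (clip means with SEM error bars and per-animal points) and example
    left/right smoothed whisker-angle traces with contact at time zero.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    needed = ["metrics.csv", "model_ftable.csv"]
    absent = [f for f in needed if not (run_dir / f).exists()]
    if absent:
        raise PipelineError(f"render: missing stage outputs: {absent}")
    fig_dir = run_dir / "figures"
    fig_dir.mkdir(exist_ok=True)

    metrics = trace_io.read_metrics_table(run_dir / "metrics.csv")
    models = pd.read_csv(run_dir / "model_ftable.csv")

    for response in mixed_stats.PC_RESPONSES + mixed_stats.DELTA_RESPONSES:
        if response not in metrics.columns:
            continue
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.6), sharey=True)
        for ax, sex in zip(axes, ("female", "male")):
            sub = metrics[metrics["sex"] == sex]
            cells = [
                (tr, tex)
                for tr in ("control", "MIA")
                for tex in ("smooth", "textured")
            ]
            means, sems, labels = [], [], []
            for tr, tex in cells:
                vals = sub.loc[
                    (sub["treatment"] == tr) & (sub["object_texture"] == tex), response
                ].dropna()
                means.append(vals.mean() if len(vals) else np.nan)
                sems.append(vals.sem() if len(vals) > 1 else 0.0)
                labels.append(f"{tr}\n{tex}")
            xs = np.arange(len(cells))
            ax.bar(xs, means, yerr=sems, capsize=3, color="lightgray",
                   edgecolor="black")
            animal_means = (
                sub.groupby(["treatment", "object_texture", "animal_id"],
                            observed=True)[response].mean().reset_index()
            )
            for k, (tr, tex) in enumerate(cells):
                pts = animal_means.loc[
                    (animal_means["treatment"] == tr)
                    & (animal_means["object_texture"] == tex),
                    response,
                ]
                ax.plot(np.full(len(pts), xs[k]), pts, "o", mfc="none",
                        color="black", ms=4)
            ax.set_xticks(xs, labels, fontsize=8)
            ax.set_title(sex)
        axes[0].set_ylabel(f"{response} (deg or deg/s)")
        fig.suptitle(response)
        fig.tight_layout()
        fig.savefig(fig_dir / f"{response}.png", dpi=110)
        plt.close(fig)

    # example trace plot, contact at t = 0
    traces_path = run_dir / "traces.csv"
    meta_path = run_dir / "metadata.csv"
    if traces_path.exists() and meta_path.exists():
        traces = trace_io.read_traces(traces_path)
        metadata = trace_io.read_metadata(meta_path)
        for clip_id in sorted(metadata)[:example_clips]:
            meta = metadata[clip_id]
            series = kinematics.per_side_series(
                traces[traces["clip_id"] == clip_id], meta
            )
            fig, ax = plt.subplots(figsize=(7, 3))
            t = (np.arange(meta.n_frames) - meta.contact_frame) / meta.frame_rate * 1e3
            for side, colour in (("left", "tab:red"), ("right", "tab:blue")):
                raw = series[side].mean_angle
                ax.plot(t, raw, color=colour, lw=0.4, alpha=0.5)
                ax.plot(t, kinematics.smooth_series(raw), color=colour, lw=1.6,
                        label=side)
            ax.axvline(0.0, color="black", ls="--", lw=0.8)
            ax.set_xlabel("time from contact (ms)")
            ax.set_ylabel("mean whisker angle (deg)")
            ax.set_title(f"clip {clip_id} ({meta.treatment} {meta.sex}, "
                         f"{meta.object_texture})")
            ax.legend(frameon=False)
            fig.tight_layout()
            fig.savefig(fig_dir / f"trace_{clip_id}.png", dpi=110)
            plt.close(fig)

    # plain-text summary
    lines = ["whiskkin run summary", "=" * 40]
    sig = models[models["p"] < 0.05] if len(models) else models
    if len(sig):
        lines.append("significant terms (p < 0.05):")
        for _, row in sig.iterrows():
            lines.append(
                f"  [{row['stage']}/{row['stratum']}] {row['response']} ~ "
                f"{row['term']}: F_{row['df1']},{row['df2']:.3f} = "
                f"{row['F']:.3f}, p = {row['p']:.4f}"
            )
    else:
        lines.append("no significant terms at p < 0.05; no post-hoc sections")
    posthoc_path = run_dir / "posthoc.csv"
    if posthoc_path.exists():
        ph = pd.read_csv(posthoc_path)
        if len(ph):
            lines.append("Tukey post-hoc contrasts:")
            for _, row in ph.iterrows():
                lines.append(
                    f"  [{row['stratum']}] {row['response']}: {row['contrast']} = "
                    f"{row['estimate']:.3f} (p_tukey = {row['p_tukey']:.4f})"
                )
    (run_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return run_dir
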