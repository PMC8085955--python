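"""End-to-end orchestration: simulate → clean → fit → project → report.

A :class:`PipelineConfig` (constructible from a YAML file) names the
input session table — or asks the synthetic generator to produce one —
and carries the per-stage parameters.  :func:`run_pipeline` chains the
stages, writes every intermediate artifact as CSV/JSON into the output
directory, and returns a manifest of file paths and audit counts.  With
all defaults and the canonical rate curves, the projection stage
regenerates the reference labor-projection table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import cleaning as _cleaning
from . import experience as _experience
from . import productivity as _productivity
from . import projection as _projection
from . import simulate as _simulate
from .ratemodels import CANONICAL_MODELS, RateModel

__all__ = ["PipelineConfig", "run_pipeline", "models_to_json", "models_from_json"]

log = logging.getLogger("digilabor")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for a full pipeline run."""

    output_dir: str | Path = "digilabor_out"
    input_sessions: str | Path | None = None
    input_labels: str | Path | None = None
    generate: bool = True
    generator: _simulate.GeneratorConfig = field(
        default_factory=_simulate.GeneratorConfig
    )
    cleaning: _cleaning.CleaningConfig = field(default_factory=_cleaning.CleaningConfig)
    bin_width: float = 2.0
    experience_limit: float = 64.0
    durations: Sequence[int] = _projection.DEFAULT_DURATIONS
    counts: Sequence[int] = _projection.DEFAULT_COUNTS
    model_source: str = "canonical"  # or "fitted"
    top_words: int = 17
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model_source not in ("canonical", "fitted"):
            raise ValueError("model_source must be 'canonical' or 'fitted'")
        if not self.generate and self.input_sessions is None:
            raise ValueError(
                "generation is disabled and no input_sessions path was given"
            )
        if self.seed is not None:
            object.__setattr__(
                self, "generator", dataclasses.replace(self.generator, seed=self.seed)
            )

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        if "generator" in raw and not isinstance(raw["generator"], _simulate.GeneratorConfig):
            raw["generator"] = _simulate.GeneratorConfig(**raw["generator"])
        if "cleaning" in raw and not isinstance(raw["cleaning"], _cleaning.CleaningConfig):
            c = dict(raw["cleaning"])
            for key in ("acceptable_phrases", "excluded_reporters", "excluded_workflow_entries"):
                if key in c:
                    c[key] = frozenset(c[key])
            raw["cleaning"] = _cleaning.CleaningConfig(**c)
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def models_to_json(models: Mapping[str, RateModel]) -> str:
    payload = {
        task: {
            "form": m.form,
            "coefficients": list(m.coefficients),
            "rate_limit": m.rate_limit,
            "limit_direction": m.limit_direction,
            "experience_limit": m.experience_limit,
        }
        for task, m in models.items()
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def models_from_json(text: str) -> dict[str, RateModel]:
    payload = json.loads(text)
    return {
        task: RateModel(
            task=task,
            form=spec["form"],
            coefficients=tuple(spec["coefficients"]),
            rate_limit=spec["rate_limit"],
            limit_direction=spec["limit_direction"],
            experience_limit=spec.get("experience_limit", 64.0),
        )
        for task, spec in payload.items()
    }


def _load_or_generate(config: PipelineConfig, outdir: Path):
    if config.input_sessions is not None:
        path = Path(config.input_sessions)
        if not path.exists():
            raise FileNotFoundError(f"input sessions file not found: {path}")
        sessions = _simulate.read_sessions(path)
        labels = (
            _simulate.read_labels(config.input_labels)
            if config.input_labels is not None
            else None
        )
        return sessions, labels
    sessions, labels = _simulate.generate_sessions(config.generator)
    _simulate.write_sessions(sessions, outdir / "sessions.csv")
    _simulate.write_labels(labels, outdir / "labels.csv")
    return sessions, labels


def _cleaning_config_with_labels(
    config: PipelineConfig, labels: pd.DataFrame | None, sessions: pd.DataFrame
) -> _cleaning.CleaningConfig:
    """Fold ground-truth reporter/workflow flags into the cleaning config.

    Unreliable reporters and atypical-workflow entries are identified by
    human investigation, not an algorithm; when the generator provides
    ground truth, its flags stand in for that investigation.
    """
    if labels is None:
        return config.cleaning
    fraud = labels.loc[labels["label"] == "fraudulent_reporter", "entry_id"]
    reporters = set(
        sessions.loc[sessions["entry_id"].isin(set(fraud)), "reporter_id"]
    )
    workflow = set(
        labels.loc[labels["label"] == "nonrepresentative_workflow", "entry_id"]
    )
    return dataclasses.replace(
        config.cleaning,
        excluded_reporters=frozenset(config.cleaning.excluded_reporters | reporters),
        excluded_workflow_entries=frozenset(
            config.cleaning.excluded_workflow_entries | workflow
        ),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return a manifest of artifacts and audit counts."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"output_dir": str(outdir), "files": {}, "audit": {}}

    def _stage(name):
        log.info("stage %s starting", name)
        return time.perf_counter()

    def _done(name, t0):
        log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)

    t0 = _stage("sessions")
    sessions, labels = _load_or_generate(config, outdir)
    if config.input_sessions is None:
        manifest["files"]["sessions"] = str(outdir / "sessions.csv")
        manifest["files"]["labels"] = str(outdir / "labels.csv")
    _done("sessions", t0)

    t0 = _stage("clean")
    clean_config = _cleaning_config_with_labels(config, labels, sessions)
    outcome = _cleaning.clean_sessions(sessions, clean_config)
    outcome.kept.to_csv(outdir / "cleaned_sessions.csv", index=False)
    _cleaning.exclusions_frame(outcome).to_csv(outdir / "exclusions.csv", index=False)
    outcome.audit.to_csv(outdir / "audit.csv", index=False)
    manifest["files"]["cleaned_sessions"] = str(outdir / "cleaned_sessions.csv")
    manifest["files"]["exclusions"] = str(outdir / "exclusions.csv")
    manifest["files"]["audit"] = str(outdir / "audit.csv")
    manifest["audit"] = {
        row["category"]: {"n_entries": int(row["n_entries"]), "hours": round(row["hours"], 3)}
        for row in outcome.audit.to_dict("records")
    }
    log.info(
        "cleaning kept %d of %d entries", len(outcome.kept), len(sessions)
    )
    _done("clean", t0)

    t0 = _stage("fit")
    records = _experience.cumulative_task_hours(outcome.kept)
    bins = _experience.bin_by_experience(
        records, bin_width=config.bin_width, limit=config.experience_limit
    )
    bins.to_csv(outdir / "experience_bins.csv", index=False)
    fitted = _experience.fit_all_tasks(bins)
    (outdir / "rate_models.json").write_text(models_to_json(fitted))
    manifest["files"]["experience_bins"] = str(outdir / "experience_bins.csv")
    manifest["files"]["rate_models"] = str(outdir / "rate_models.json")
    _done("fit", t0)

    t0 = _stage("project")
    models = dict(CANONICAL_MODELS) if config.model_source == "canonical" else fitted
    table = _projection.projection_table(models, config.durations, config.counts)
    table.to_csv(outdir / "projection_wide.csv")
    _projection.projection_table_tidy(table).to_csv(
        outdir / "projection_tidy.csv", index=False
    )
    manifest["files"]["projection_wide"] = str(outdir / "projection_wide.csv")
    manifest["files"]["projection_tidy"] = str(outdir / "projection_tidy.csv")
    _done("project", t0)

    t0 = _stage("report")
    report_path = outdir / "report.txt"
    report_path.write_text(_render_report(sessions, outcome, table, config))
    manifest["files"]["report"] = str(report_path)
    _done("report", t0)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["files"]["manifest"] = str(outdir / "manifest.json")
    return manifest


def _render_report(sessions, outcome, table, config: PipelineConfig) -> str:
    """Plain-text productivity report: rates, setbacks, word frequencies."""
    pre = _productivity.totals_from_sessions(sessions, "pre_cleaning")
    post = _productivity.totals_from_sessions(outcome.kept, "post_cleaning")
    lines = ["Digitization productivity report", "=" * 34, ""]
    lines.append("Project-wide rates (specimens/minute):")
    lines.append(
        f"  method A (pre-clean specimens / pre-clean hours):   "
        f"{_productivity.project_wide_rate(pre, 'A'):.3f}"
    )
    lines.append(
        f"  method B (post-clean specimens / post-clean hours): "
        f"{_productivity.project_wide_rate(post, 'B'):.3f}"
    )
    lines.append(
        f"  method C (post-clean specimens / primary hours):    "
        f"{_productivity.project_wide_rate(post, 'C'):.3f}"
    )
    lines.append("")
    lines.append("Per-task rates, post-cleaning (specimens/minute):")
    for task in sorted(post.specimens_by_task):
        hours = (
            outcome.kept.loc[outcome.kept["task"] == task, "minutes"].sum() / 60.0
        )
        if hours > 0:
            rate = _productivity.task_rate(post.specimens_by_task[task], hours)
            lines.append(f"  {task:20s} {rate:.2f} over {hours:.0f} hours")
    lines.append("")
    summary = _productivity.setback_summary(sessions, outcome)
    lines.append("Setback summary:")
    for row in summary.to_dict("records"):
        lines.append(
            f"  {row['scope']:20s} n={row['n_setback']:<5d} "
            f"hours={row['setback_hours']:8.1f} "
            f"mean-min(setback)={row['mean_minutes_setback']:6.1f} "
            f"mean-min(clean)={row['mean_minutes_no_setback']:6.1f}"
        )
    lines.append("")
    words = _productivity.word_frequencies(
        outcome.excluded["setback"]["setback_text"]
    )[: config.top_words]
    lines.append(f"Top {len(words)} setback words: ")
    lines.extend(f"  {w}: {c}" for w, c in words)
    lines.append("")
    lines.append("Labor projection (hours), combined tasks:")
    lines.append(table.to_string())
    return "\n".join(lines) + "\n"
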