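"""Synthetic technician session reports with ground-truth anomaly labels.

Real digitization projects collect self-reported work-session logs: one
row per technician per session with the task performed, minutes worked,
specimens processed and a free-text setback field.  This module
generates tables with the same statistical structure so the cleaning and
curve-fitting stages can be exercised end-to-end, and every injected
anomaly carries a ground-truth label:

``clean``
    specimens ≈ minutes × noise × rate-curve(cumulative task hours).
``setback``
    reported minutes inflated (default ×1.32) with no extra production,
    plus a non-whitelisted free-text description.
``swapped_fields``
    the minutes and specimens values exchanged (a data-entry error).
``extreme_outlier``
    one numeric field replaced by a value far outside its task's
    distribution (e.g. a timer left running).
``fraudulent_reporter``
    whole reporters whose rates are internally inconsistent.
``nonrepresentative_workflow``
    a few entries flagged as produced under an atypical workflow.

Anomalies are injected so that the downstream cleaning rules can
separate them perfectly: swaps are planted on sessions whose clean rate
sits within 1 SD of the task mean (the swap detector tolerates 2 SD),
minutes-outliers are drawn large enough that their inverse ratio cannot
be mistaken for a typical rate, and clean draws are truncated at ±2.5 SD
so no clean entry trips the 5-SD outlier rule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .ratemodels import CANONICAL_MODELS, PRIMARY_TASKS, TASKS, RateModel

__all__ = [
    "GeneratorConfig",
    "generate_sessions",
    "write_sessions",
    "read_sessions",
    "write_labels",
    "read_labels",
    "SESSION_COLUMNS",
    "LABEL_COLUMNS",
]

SESSION_COLUMNS = (
    "entry_id",
    "reporter_id",
    "session_date",
    "collection_code",
    "task",
    "minutes",
    "specimens",
    "setback_text",
)
LABEL_COLUMNS = ("entry_id", "label")

LABELS = (
    "clean",
    "setback",
    "swapped_fields",
    "extreme_outlier",
    "fraudulent_reporter",
    "nonrepresentative_workflow",
)

_COLLECTION_CODES = ("TENN", "UCHT", "HTTU", "MTSU", "ETSU", "SWMT", "UTM", "UOS")

#: Free text that normalizes onto the no-setback whitelist (plus blanks).
_NO_SETBACK_POOL = (
    "", "", "", "", "no", "none", "No", "None.", "NONE",
    "No setbacks", "no setbacks!",
)

#: Free text describing genuine setbacks (never whitelist-normalizable).
_SETBACK_POOL = (
    "camera settings needed repair",
    "internet outage halted portal uploads",
    "computer froze during imaging",
    "training blitz with new technicians",
    "missing barcode labels",
    "specimens misfiled in wrong folders",
    "portal running slow today",
    "label printer jammed",
    "new camera training session",
    "skeletal entry tool was down",
    "collector name illegible on label",
    "species folders out of order",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic session-report generator.

    Defaults emulate a multi-herbarium digitization project: ~100
    technicians reporting sessions averaging 101 minutes, a ~15%
    incidence of setback sessions running ~32% longer, a ~1% rate of
    swapped-field entry errors, ~2% extreme outliers, and a couple of
    reporters submitting unreliable numbers throughout.
    """

    n_technicians: int = 105
    sessions_per_technician: int | tuple[int, int] = (5, 60)
    task_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "barcoding": 0.15,
            "imaging": 0.30,
            "skeletal_databasing": 0.25,
            "other": 0.30,
        }
    )
    session_minutes_mean: float = 101.0
    session_minutes_sd: float = 35.0
    rate_curves: Mapping[str, RateModel] = field(
        default_factory=lambda: dict(CANONICAL_MODELS)
    )
    rate_noise_cv: float = 0.10
    setback_probability: float = 0.15
    setback_minutes_inflation: float = 1.32
    swap_error_probability: float = 0.01
    outlier_probability: float = 0.02
    fraudulent_reporter_count: int = 2
    workflow_entry_count: int = 3
    task_stickiness: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_technicians < 1:
            raise ValueError("n_technicians must be a positive integer")
        spt = self.sessions_per_technician
        if isinstance(spt, int):
            if spt < 1:
                raise ValueError("sessions_per_technician must be positive")
        else:
            lo, hi = spt
            if lo < 1 or hi < lo:
                raise ValueError("sessions_per_technician range must satisfy 1 <= lo <= hi")
        if set(self.task_mix) - set(TASKS):
            raise ValueError(f"task_mix keys must be among {TASKS}")
        if any(p < 0 for p in self.task_mix.values()):
            raise ValueError("task_mix proportions must be non-negative")
        if abs(sum(self.task_mix.values()) - 1.0) > 1e-9:
            raise ValueError("task_mix must sum to 1")
        for name in (
            "setback_probability",
            "swap_error_probability",
            "outlier_probability",
            "task_stickiness",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in (
            "session_minutes_mean",
            "session_minutes_sd",
            "setback_minutes_inflation",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rate_noise_cv < 0:
            raise ValueError("rate_noise_cv must be non-negative")
        if self.fraudulent_reporter_count < 0 or self.workflow_entry_count < 0:
            raise ValueError("anomaly counts must be non-negative")
        if self.fraudulent_reporter_count > self.n_technicians:
            raise ValueError("fraudulent_reporter_count exceeds n_technicians")

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)


def _round5(x: np.ndarray) -> np.ndarray:
    """Reported minutes are never more precise than the nearest 5 minutes."""
    return np.maximum(np.round(np.asarray(x) / 5.0) * 5.0, 5.0)


def _truncnorm(rng, mean, sd, lo_z=-2.5, hi_z=2.5, size=None):
    return stats.truncnorm.rvs(lo_z, hi_z, loc=mean, scale=sd, size=size, random_state=rng)


def generate_sessions(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a session-report table and its ground-truth label table.

    Returns ``(sessions, labels)``.  ``sessions`` has columns
    :data:`SESSION_COLUMNS`; ``labels`` maps every ``entry_id`` to exactly
    one anomaly label.  Identical configs (including the seed) produce
    identical tables.
    """
    rng = np.random.default_rng(config.seed)
    mix_tasks = list(config.task_mix)
    mix_p = np.array([config.task_mix[t] for t in mix_tasks], dtype=float)
    sigma = config.rate_noise_cv

    rows: list[dict] = []
    fraud_ids = set(range(config.n_technicians - config.fraudulent_reporter_count,
                          config.n_technicians))
    for tech in range(config.n_technicians):
        reporter = f"tech{tech:03d}"
        fraud = tech in fraud_ids
        spt = config.sessions_per_technician
        n_sessions = (
            spt if isinstance(spt, int)
            else int(rng.integers(spt[0], spt[1] + 1))
        )
        code = str(rng.choice(_COLLECTION_CODES))
        primary = str(rng.choice(mix_tasks, p=mix_p))
        day = date(2016, 6, 1) + timedelta(days=int(rng.integers(0, 700)))
        cum_hours = {t: 0.0 for t in TASKS}
        for _ in range(n_sessions):
            task = (
                primary
                if rng.random() < config.task_stickiness
                else str(rng.choice(mix_tasks, p=mix_p))
            )
            minutes = float(
                _round5(
                    _truncnorm(
                        rng,
                        config.session_minutes_mean,
                        config.session_minutes_sd,
                    )
                )
            )
            x_end = cum_hours[task] + minutes / 60.0
            if task in config.rate_curves:
                if fraud:
                    rate = float(rng.uniform(0.3, 9.0))
                else:
                    true_rate = float(config.rate_curves[task].clamped(x_end))
                    if sigma > 0:
                        z = float(_truncnorm(rng, 0.0, 1.0))
                        noise = float(np.exp(sigma * z - sigma**2 / 2.0))
                    else:
                        noise = 1.0
                    rate = true_rate * noise
                specimens = int(round(minutes * rate))
            else:
                specimens = 0
            cum_hours[task] = x_end
            rows.append(
                {
                    "reporter_id": reporter,
                    "session_date": day.isoformat(),
                    "collection_code": code,
                    "task": task,
                    "minutes": minutes,
                    "specimens": specimens,
                    "setback_text": "",
                    "_label": "fraudulent_reporter" if fraud else "clean",
                }
            )
            day += timedelta(days=int(rng.integers(1, 6)))

    sessions = pd.DataFrame(rows)
    sessions.insert(0, "entry_id", [f"s{i:05d}" for i in range(len(sessions))])

    _inject_setbacks(sessions, config, rng)
    _inject_swaps(sessions, config, rng)
    _inject_outliers(sessions, config, rng)
    _mark_workflow_entries(sessions, config, rng)
    _fill_no_setback_text(sessions, rng)

    labels = sessions[["entry_id", "_label"]].rename(columns={"_label": "label"})
    sessions = sessions.drop(columns="_label")
    sessions = sessions.astype(
        {"minutes": float, "specimens": "int64"}
    )[list(SESSION_COLUMNS)]
    return sessions.reset_index(drop=True), labels.reset_index(drop=True)


def _inject_setbacks(df: pd.DataFrame, config: GeneratorConfig, rng) -> None:
    # Setback time is lost time: reported minutes grow, production does not.
    clean = df.index[df["_label"] == "clean"]
    hit = clean[rng.random(len(clean)) < config.setback_probability]
    df.loc[hit, "minutes"] = _round5(
        df.loc[hit, "minutes"] * config.setback_minutes_inflation
    )
    df.loc[hit, "setback_text"] = rng.choice(_SETBACK_POOL, size=len(hit))
    df.loc[hit, "_label"] = "setback"


def _inject_swaps(df: pd.DataFrame, config: GeneratorConfig, rng) -> None:
    # Swap candidates sit within 1 SD of their task's realized mean rate,
    # so the post-swap inverse ratio is unambiguously "typical".
    clean_primary = df.index[
        (df["_label"] == "clean")
        & df["task"].isin(PRIMARY_TASKS)
        & (df["specimens"] > 0)
    ]
    if len(clean_primary) == 0:
        return
    n_swaps = int(round(config.swap_error_probability * len(clean_primary)))
    if n_swaps == 0:
        return
    rate = df.loc[clean_primary, "specimens"] / df.loc[clean_primary, "minutes"]
    task = df.loc[clean_primary, "task"]
    mu = rate.groupby(task).transform("mean")
    sd = rate.groupby(task).transform("std")
    eligible = clean_primary[np.abs(rate - mu) <= sd]
    n_swaps = min(n_swaps, len(eligible))
    chosen = rng.choice(eligible, size=n_swaps, replace=False)
    m = df.loc[chosen, "minutes"].copy()
    df.loc[chosen, "minutes"] = df.loc[chosen, "specimens"].astype(float)
    df.loc[chosen, "specimens"] = m.round().astype(int)
    df.loc[chosen, "_label"] = "swapped_fields"


def _inject_outliers(df: pd.DataFrame, config: GeneratorConfig, rng) -> None:
    # Minutes-outliers mimic a timer left running: 8-10 minutes per
    # specimen (at least 3000 minutes), so the inverse ratio sits far
    # above every task's typical-rate band and the swap rule cannot
    # claim the entry.  Specimens-outliers (4000-5000) are implausibly
    # fast in the other direction and never rate-flagged.  Both ranges
    # are kept homogeneous so no injected outlier is masked below the
    # 5-SD threshold by larger ones inflating the field SD.
    clean_primary = df.index[
        (df["_label"] == "clean") & df["task"].isin(PRIMARY_TASKS)
    ]
    n_out = int(round(config.outlier_probability * len(clean_primary)))
    if n_out == 0:
        return
    chosen = rng.choice(clean_primary, size=min(n_out, len(clean_primary)), replace=False)
    which_minutes = rng.random(len(chosen)) < 0.5
    m_idx = chosen[which_minutes]
    s_idx = chosen[~which_minutes]
    if len(m_idx):
        per_specimen = rng.uniform(8.0, 10.0, size=len(m_idx))
        df.loc[m_idx, "minutes"] = _round5(
            np.maximum(df.loc[m_idx, "specimens"] * per_specimen, 3000.0)
        )
    if len(s_idx):
        df.loc[s_idx, "specimens"] = rng.integers(4000, 5001, size=len(s_idx))
    df.loc[chosen, "_label"] = "extreme_outlier"


def _mark_workflow_entries(df: pd.DataFrame, config: GeneratorConfig, rng) -> None:
    clean = df.index[df["_label"] == "clean"]
    n = min(config.workflow_entry_count, len(clean))
    if n == 0:
        return
    chosen = rng.choice(clean, size=n, replace=False)
    df.loc[chosen, "_label"] = "nonrepresentative_workflow"


def _fill_no_setback_text(df: pd.DataFrame, rng) -> None:
    ok = df.index[df["_label"] != "setback"]
    df.loc[ok, "setback_text"] = rng.choice(_NO_SETBACK_POOL, size=len(ok))


# ---------------------------------------------------------------------------
# CSV I/O — lossless round trips, blank setback text preserved as "".

def write_sessions(sessions: pd.DataFrame, path) -> None:
    sessions.to_csv(path, index=False, columns=list(SESSION_COLUMNS))


def read_sessions(path) -> pd.DataFrame:
    df = pd.read_csv(
        Path(path),
        dtype={
            "entry_id": str,
            "reporter_id": str,
            "session_date": str,
            "collection_code": str,
            "task": str,
            "minutes": float,
            "specimens": "int64",
            "setback_text": str,
        },
        keep_default_na=False,
    )
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sessions file {path} is missing columns {sorted(missing)}")
    return df[list(SESSION_COLUMNS)]


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, index=False, columns=list(LABEL_COLUMNS))


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), dtype=str, keep_default_na=False)[list(LABEL_COLUMNS)]
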