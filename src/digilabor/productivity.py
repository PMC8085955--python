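"""Project-wide and per-task productivity summaries.

A project-wide "digitization rate" depends on two accounting choices:
what counts as a digitized specimen and which hours count toward the
effort.  Because every specimen passes through all three primary tasks
(barcoding, imaging, skeletal databasing), the number of specimens
digitized is taken as the arithmetic mean of the three per-task specimen
totals; three divisor conventions are then offered:

``A``  pre-cleaning specimens mean / pre-cleaning hours on all tasks;
``B``  post-cleaning specimens mean / post-cleaning hours on all tasks;
``C``  post-cleaning specimens mean / post-cleaning hours on the three
       primary tasks only.

All rate functions return unrounded specimens-per-minute values;
rounding (2 decimals for task rates, 3 for project-wide rates) belongs
to the report writer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .cleaning import CleaningOutcome, classify_setback, normalize_free_text
from .ratemodels import PRIMARY_TASKS

__all__ = [
    "ProductivityTotals",
    "project_wide_rate",
    "task_rate",
    "setback_summary",
    "word_frequencies",
    "totals_from_sessions",
]


@dataclass(frozen=True)
class ProductivityTotals:
    """Specimen and hour totals at one cleaning stage."""

    specimens_by_task: Mapping[str, float]  # the three primary tasks
    total_hours: float  # all tasks
    primary_task_hours: float  # primary digitization tasks only
    stage: Literal["pre_cleaning", "post_cleaning"]

    def __post_init__(self) -> None:
        missing = set(PRIMARY_TASKS) - set(self.specimens_by_task)
        if missing:
            raise ValueError(f"missing specimen totals for {sorted(missing)}")
        if any(v < 0 for v in self.specimens_by_task.values()):
            raise ValueError("specimen totals must be non-negative")
        if self.total_hours < 0 or self.primary_task_hours < 0:
            raise ValueError("hour totals must be non-negative")
        if self.primary_task_hours > self.total_hours:
            raise ValueError("primary-task hours cannot exceed total hours")

    @property
    def mean_specimens(self) -> float:
        return float(np.mean([self.specimens_by_task[t] for t in PRIMARY_TASKS]))


def totals_from_sessions(
    sessions: pd.DataFrame, stage: Literal["pre_cleaning", "post_cleaning"]
) -> ProductivityTotals:
    """Aggregate a session table into :class:`ProductivityTotals`."""
    primary = sessions[sessions["task"].isin(PRIMARY_TASKS)]
    specimens = {
        t: float(primary.loc[primary["task"] == t, "specimens"].sum())
        for t in PRIMARY_TASKS
    }
    return ProductivityTotals(
        specimens_by_task=specimens,
        total_hours=float(sessions["minutes"].sum()) / 60.0,
        primary_task_hours=float(primary["minutes"].sum()) / 60.0,
        stage=stage,
    )


def project_wide_rate(totals: ProductivityTotals, method: Literal["A", "B", "C"]) -> float:
    """Project-wide digitization rate in specimens per minute (unrounded).

    Method A requires pre-cleaning totals; B and C post-cleaning totals.
    """
    required_stage = "pre_cleaning" if method == "A" else "post_cleaning"
    if method not in ("A", "B", "C"):
        raise ValueError("method must be 'A', 'B' or 'C'")
    if totals.stage != required_stage:
        raise ValueError(f"method {method} requires {required_stage} totals")
    hours = totals.primary_task_hours if method == "C" else totals.total_hours
    if hours <= 0:
        raise ZeroDivisionError("cannot compute a rate over zero hours")
    return totals.mean_specimens / (hours * 60.0)


def task_rate(specimens: float, hours: float) -> float:
    """Task throughput in specimens per minute (unrounded)."""
    if hours <= 0:
        raise ZeroDivisionError("cannot compute a rate over zero hours")
    return specimens / (hours * 60.0)


def setback_summary(
    all_entries: pd.DataFrame, outcome: CleaningOutcome
) -> pd.DataFrame:
    """Setback incidence and duration, overall and per task.

    Sessions excluded in the ``setback`` category are compared with all
    other input sessions: counts, hour totals, mean session minutes with
    and without a setback, and the setback share of pre-cleaning hours.
    Rows where no setback (or no other) session exists report NaN means.
    """
    setbacks = outcome.excluded["setback"]
    setback_ids = set(setbacks["entry_id"])
    others = all_entries[~all_entries["entry_id"].isin(setback_ids)]

    def _row(scope: str, sb: pd.DataFrame, rest: pd.DataFrame, total_minutes: float):
        return {
            "scope": scope,
            "n_setback": len(sb),
            "setback_hours": float(sb["minutes"].sum()) / 60.0,
            "mean_minutes_setback": float(sb["minutes"].mean()) if len(sb) else float("nan"),
            "mean_minutes_no_setback": float(rest["minutes"].mean()) if len(rest) else float("nan"),
            "setback_hour_share": (
                float(sb["minutes"].sum()) / total_minutes if total_minutes > 0 else float("nan")
            ),
        }

    rows = [_row("all", setbacks, others, float(all_entries["minutes"].sum()))]
    for task in sorted(all_entries["task"].unique()):
        sb = setbacks[setbacks["task"] == task]
        rest = others[others["task"] == task]
        total = float(all_entries.loc[all_entries["task"] == task, "minutes"].sum())
        rows.append(_row(task, sb, rest, total))
    return pd.DataFrame(rows)


def word_frequencies(setback_texts: Iterable[str]) -> list[tuple[str, int]]:
    """Token counts over normalized setback descriptions.

    Tokens are whitespace-split words of the normalized text, counted
    across all descriptions and ranked by descending count, ties broken
    lexicographically.
    """
    counts: Counter[str] = Counter()
    for text in setback_texts:
        norm = normalize_free_text(text)
        if norm:
            counts.update(norm.split(" "))
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
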