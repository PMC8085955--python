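"""Five-stage cleaning of technician session reports.

Self-reported session logs contain entries that would bias any rate
analysis: reporters known to be unreliable, sessions produced under an
atypical workflow, swapped-field data-entry errors, sessions disrupted
by setbacks, and extreme numeric outliers.  :func:`clean_sessions`
partitions an input table into a kept set and five exclusion categories,
applied in a fixed order with full audit accounting:

1. ``nonrepresentative_reporter`` — reporter on the configured exclusion
   list (these are identified by human investigation, not an algorithm);
2. ``nonrepresentative_workflow`` — entry id on the configured list;
3. ``entry_error`` — specimens/minutes so low that the inverse ratio
   matches a typical task rate, i.e. the two fields were swapped;
4. ``setback`` — free-text setback description that does not normalize
   onto the acceptable-phrase whitelist;
5. ``extreme_outlier`` — minutes or specimens beyond a 5-SD band of its
   task's distribution among the survivors of stages 1-4.

Every entry lands in exactly one place, and per-category entry counts
and hour totals are reported so the cost of cleaning is visible.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_WHITELIST",
    "EXCLUSION_CATEGORIES",
    "CleaningConfig",
    "CleaningOutcome",
    "normalize_free_text",
    "classify_setback",
    "detect_swapped_entry",
    "flag_field_outliers",
    "clean_sessions",
]

#: Canonical phrases meaning "no setback occurred".
DEFAULT_WHITELIST = frozenset({"no", "none", "no setbacks"})

EXCLUSION_CATEGORIES = (
    "nonrepresentative_reporter",
    "nonrepresentative_workflow",
    "entry_error",
    "setback",
    "extreme_outlier",
)

_PUNCT_RE = re.compile(r"[^\w\s]|_", flags=re.UNICODE)
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds and manual exclusion lists for :func:`clean_sessions`."""

    acceptable_phrases: frozenset[str] = DEFAULT_WHITELIST
    excluded_reporters: frozenset[str] = frozenset()
    excluded_workflow_entries: frozenset[str] = frozenset()
    outlier_sd_threshold: float = 5.0
    swap_low_rate_quantile: float = 0.05
    swap_tolerance_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.outlier_sd_threshold <= 0:
            raise ValueError("outlier_sd_threshold must be positive")
        if not 0.0 < self.swap_low_rate_quantile < 1.0:
            raise ValueError("swap_low_rate_quantile must lie in (0, 1)")
        if self.swap_tolerance_sd <= 0:
            raise ValueError("swap_tolerance_sd must be positive")
        object.__setattr__(self, "acceptable_phrases", frozenset(self.acceptable_phrases))
        object.__setattr__(self, "excluded_reporters", frozenset(self.excluded_reporters))
        object.__setattr__(
            self, "excluded_workflow_entries", frozenset(self.excluded_workflow_entries)
        )


@dataclass(frozen=True)
class CleaningOutcome:
    """Partition of an input table into kept rows and exclusion categories."""

    kept: pd.DataFrame
    excluded: Mapping[str, pd.DataFrame]
    audit: pd.DataFrame  # per category + kept: n_entries, hours

    @property
    def n_input(self) -> int:
        return len(self.kept) + sum(len(df) for df in self.excluded.values())


def normalize_free_text(text: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace, trim."""
    if text is None:
        return ""
    text = unicodedata.normalize("NFKC", str(text)).lower()
    text = _PUNCT_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


def classify_setback(text: str, whitelist: Iterable[str] = DEFAULT_WHITELIST) -> bool:
    """True iff the free text reports a genuine setback.

    Blank text counts as "nothing to report".  Any non-blank text whose
    normalized form is absent from the whitelist indicates a setback.
    """
    norm = normalize_free_text(text)
    return bool(norm) and norm not in set(whitelist)


def detect_swapped_entry(
    report: Mapping,
    task_stats: Mapping[str, float],
    *,
    swap_tolerance_sd: float = 2.0,
) -> bool:
    """True iff a report's minutes and specimens look exchanged.

    ``task_stats`` must provide ``mean_rate``, ``sd_rate`` and
    ``low_rate_cutoff`` (the low quantile of the task's specimens/minute
    distribution) computed over candidate clean entries for the same
    task.  An entry is a swap when its rate falls below the cutoff while
    the inverse ratio (minutes per specimen) is within
    ``swap_tolerance_sd`` rate SDs of the task's mean rate — i.e. the
    numbers are only typical if read the other way round.
    """
    specimens = report["specimens"]
    minutes = report["minutes"]
    if specimens <= 0 or minutes <= 0:
        return False
    sd = task_stats["sd_rate"]
    if not np.isfinite(sd) or sd <= 0:
        return False
    rate = specimens / minutes
    inverse = minutes / specimens
    return (
        rate < task_stats["low_rate_cutoff"]
        and abs(inverse - task_stats["mean_rate"]) <= swap_tolerance_sd * sd
    )


def compute_task_rate_stats(
    entries: pd.DataFrame, low_quantile: float = 0.05
) -> dict[str, dict[str, float]]:
    """Per-task rate mean/SD and low-rate cutoff from candidate clean data.

    Only entries with positive specimen counts contribute (zero-specimen
    sessions, e.g. curation work, carry no rate information).
    """
    usable = entries[entries["specimens"] > 0]
    out: dict[str, dict[str, float]] = {}
    for task, grp in usable.groupby("task"):
        rate = grp["specimens"] / grp["minutes"]
        out[task] = {
            "mean_rate": float(rate.mean()),
            "sd_rate": float(rate.std(ddof=1)) if len(rate) > 1 else float("nan"),
            "low_rate_cutoff": float(rate.quantile(low_quantile)),
        }
    return out


def flag_field_outliers(
    entries: pd.DataFrame, threshold_sd: float = 5.0
) -> set[str]:
    """Entry ids whose minutes or specimens lie strictly beyond ``threshold_sd``.

    Mean and SD are computed per task over the provided entries.  Fields
    with zero variance (or a single entry) yield no flags.
    """
    flagged: set[str] = set()
    for _, grp in entries.groupby("task"):
        for fld in ("minutes", "specimens"):
            vals = grp[fld].astype(float)
            if len(vals) < 2:
                continue
            sd = vals.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                continue
            z = (vals - vals.mean()).abs() / sd
            flagged.update(grp.loc[z > threshold_sd, "entry_id"])
    return flagged


def clean_sessions(
    entries: pd.DataFrame, config: CleaningConfig | None = None
) -> CleaningOutcome:
    """Partition session reports into kept rows and five exclusion categories.

    Stages run in a fixed order; each entry is claimed by the first
    stage that matches it.  Swap detection statistics are computed on
    the survivors of stages 1-2 minus whitelist-classified setbacks and
    provisional 5-SD field outliers, so a handful of corrupt values
    cannot distort the typical-rate bands.  Outlier statistics (stage 5)
    are recomputed per task on the survivors of stages 1-4.
    """
    if config is None:
        config = CleaningConfig()
    entries = entries.reset_index(drop=True)
    excluded: dict[str, pd.DataFrame] = {}

    mask_reporter = entries["reporter_id"].isin(config.excluded_reporters)
    excluded["nonrepresentative_reporter"] = entries[mask_reporter]
    rest = entries[~mask_reporter]

    mask_workflow = rest["entry_id"].isin(config.excluded_workflow_entries)
    excluded["nonrepresentative_workflow"] = rest[mask_workflow]
    rest = rest[~mask_workflow]

    # Stage 3: swapped-field entry errors.
    if len(rest):
        is_setback = rest["setback_text"].map(
            lambda t: classify_setback(t, config.acceptable_phrases)
        )
        stat_pool = rest[~is_setback]
        provisional = flag_field_outliers(stat_pool, config.outlier_sd_threshold)
        stat_pool = stat_pool[~stat_pool["entry_id"].isin(provisional)]
        task_stats = compute_task_rate_stats(stat_pool, config.swap_low_rate_quantile)
        mask_swap = rest.apply(
            lambda row: row["task"] in task_stats
            and detect_swapped_entry(
                row,
                task_stats[row["task"]],
                swap_tolerance_sd=config.swap_tolerance_sd,
            ),
            axis=1,
        )
    else:
        is_setback = pd.Series(False, index=rest.index)
        mask_swap = pd.Series(False, index=rest.index)
    excluded["entry_error"] = rest[mask_swap]
    is_setback = is_setback[~mask_swap]
    rest = rest[~mask_swap]

    excluded["setback"] = rest[is_setback]
    rest = rest[~is_setback]

    outlier_ids = flag_field_outliers(rest, config.outlier_sd_threshold) if len(rest) else set()
    mask_outlier = rest["entry_id"].isin(outlier_ids)
    excluded["extreme_outlier"] = rest[mask_outlier]
    kept = rest[~mask_outlier]

    audit_rows = [
        {
            "category": cat,
            "n_entries": len(df),
            "hours": float(df["minutes"].sum()) / 60.0,
        }
        for cat, df in excluded.items()
    ]
    audit_rows.append(
        {"category": "kept", "n_entries": len(kept), "hours": float(kept["minutes"].sum()) / 60.0}
    )
    audit = pd.DataFrame(audit_rows, columns=["category", "n_entries", "hours"])

    outcome = CleaningOutcome(
        kept=kept.reset_index(drop=True),
        excluded={k: v.reset_index(drop=True) for k, v in excluded.items()},
        audit=audit,
    )
    assert outcome.n_input == len(entries), "cleaning must conserve entries"
    return outcome


def exclusions_frame(outcome: CleaningOutcome) -> pd.DataFrame:
    """All excluded entries in one table with a ``category`` column."""
    parts = [
        df.assign(category=cat)
        for cat, df in outcome.excluded.items()
        if len(df)
    ]
    if not parts:
        cols = list(outcome.kept.columns) + ["category"]
        return pd.DataFrame(columns=cols)
    return pd.concat(parts, ignore_index=True)
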