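"""Turnover-constrained labor projections.

The simulator answers: how many labor hours are needed to push N
specimens through one digitization task when technicians work fixed
contract durations and each departing technician is replaced by a
novice?  Production advances in whole-hour steps.  During a technician's
k-th hour on the task their rate is the task curve evaluated at
end-of-hour experience, clamped by the task's rate limit; experience is
frozen one hour past the 64-hour model boundary, so hours beyond that
use the curve value at 65 cumulative hours.  At each contract boundary
the hour index resets to 1 (a fresh technician) while cumulative
production carries over.

The default grid — contract durations {15, 30, 45, 60, 90, 135} hours and
thirteen specimen counts from 10,000 to 500,000 — regenerates the
reference labor-projection table for the three primary tasks plus their
Combined total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ratemodels import CANONICAL_MODELS, PRIMARY_TASKS, RateModel

__all__ = [
    "DEFAULT_DURATIONS",
    "DEFAULT_COUNTS",
    "ProjectionSpec",
    "effective_hourly_rate",
    "contract_production",
    "simulate_labor_hours",
    "projection_table",
    "retention_savings",
]

DEFAULT_DURATIONS: tuple[int, ...] = (15, 30, 45, 60, 90, 135)
DEFAULT_COUNTS: tuple[int, ...] = (
    10_000, 20_000, 30_000, 40_000, 50_000, 75_000, 100_000,
    125_000, 150_000, 200_000, 250_000, 300_000, 500_000,
)

#: Experience (hours) at which the curve is frozen during simulation:
#: the hour that *ends* at 65 cumulative hours is the last one evaluated
#: on the curve, one step past the 64-hour bin threshold.
FREEZE_HOUR = 65


@dataclass(frozen=True)
class ProjectionSpec:
    """One projection scenario: a model, a contract length, a target count."""

    contract_duration: int
    specimen_count: int
    model: RateModel

    def __post_init__(self) -> None:
        if self.contract_duration < 1:
            raise ValueError("contract_duration must be >= 1 hour")
        if self.specimen_count < 1:
            raise ValueError("specimen_count must be >= 1")


def effective_hourly_rate(model: RateModel, k: int) -> float:
    """Specimens produced during hour ``k`` (1-based) of a contract.

    The curve is evaluated at end-of-hour experience ``min(k, 65)`` and
    clamped by the model's rate limit; the result is converted from
    specimens/minute to specimens/hour.
    """
    if k < 1:
        raise ValueError("hour index k is 1-based")
    return 60.0 * float(model.clamped(min(k, FREEZE_HOUR)))


def _hourly_rates(model: RateModel, duration: int) -> np.ndarray:
    k = np.arange(1, duration + 1)
    x = np.minimum(k, FREEZE_HOUR).astype(float)
    return 60.0 * np.asarray(model.clamped(x), dtype=float)


def contract_production(model: RateModel, duration: int) -> float:
    """Total specimens one technician produces over a ``duration``-hour contract."""
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if duration == 0:
        return 0.0
    return float(np.sum(_hourly_rates(model, duration)))


def simulate_labor_hours(
    model: RateModel, contract_duration: int, specimen_count: int
) -> int:
    """Hours of labor until cumulative production first reaches the target.

    Technicians are replaced every ``contract_duration`` hours: the hour
    index (and hence the experience-dependent rate) resets while the
    production total carries over.  Returns the integer hour at which
    cumulative production first meets or exceeds ``specimen_count``.
    """
    ProjectionSpec(contract_duration, specimen_count, model)  # validate
    rates = _hourly_rates(model, contract_duration)
    per_contract = rates.sum()
    n_contracts = int(np.ceil(specimen_count / per_contract)) + 1
    cumulative = np.cumsum(np.tile(rates, n_contracts))
    return int(np.searchsorted(cumulative, specimen_count, side="left")) + 1


def simulate_spec(spec: ProjectionSpec) -> int:
    """:func:`simulate_labor_hours` for a bundled :class:`ProjectionSpec`."""
    return simulate_labor_hours(spec.model, spec.contract_duration, spec.specimen_count)


def projection_table(
    models: Mapping[str, RateModel] | None = None,
    durations: Sequence[int] = DEFAULT_DURATIONS,
    counts: Sequence[int] = DEFAULT_COUNTS,
) -> pd.DataFrame:
    """Labor-hour estimates for every (duration, task, count) combination.

    Returns a DataFrame indexed by ``(contract_duration, task)`` — task
    includes ``"combined"``, the per-count sum over the three primary
    tasks — with one integer column per specimen count.
    """
    if models is None:
        models = CANONICAL_MODELS
    if not durations or not counts:
        raise ValueError("durations and counts must be non-empty")
    tasks = [t for t in PRIMARY_TASKS if t in models]
    rows = {}
    for d in durations:
        for task in tasks:
            rows[(d, task)] = [
                simulate_labor_hours(models[task], d, n) for n in counts
            ]
        if len(tasks) == len(PRIMARY_TASKS):
            rows[(d, "combined")] = [
                sum(rows[(d, t)][i] for t in tasks) for i in range(len(counts))
            ]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(counts))
    table.index = pd.MultiIndex.from_tuples(
        table.index, names=["contract_duration", "task"]
    )
    table.columns.name = "specimen_count"
    return table


def projection_table_tidy(table: pd.DataFrame) -> pd.DataFrame:
    """Long-format view: contract_duration, task, specimen_count, hours."""
    tidy = table.stack().rename("hours").reset_index()
    return tidy.sort_values(
        ["contract_duration", "task", "specimen_count"], ignore_index=True
    )


def retention_savings(table: pd.DataFrame, count: int) -> float:
    """Fractional labor saved by the longest vs. shortest contract duration.

    Compares the Combined rows of a :func:`projection_table` at one
    specimen count: ``(hours_shortest - hours_longest) / hours_shortest``.
    """
    if count not in table.columns:
        raise KeyError(f"specimen count {count} not in table")
    durations = table.index.get_level_values("contract_duration")
    shortest, longest = durations.min(), durations.max()
    h_short = table.loc[(shortest, "combined"), count]
    h_long = table.loc[(longest, "combined"), count]
    return float((h_short - h_long) / h_short)
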