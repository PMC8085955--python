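"""Cumulative experience, two-hour rate bins, and curve fitting.

Each technician's cumulative time on each task is accumulated over their
date-sorted session history; experience is attributed at the moment a
report is submitted, i.e. the session's own minutes count toward it.
Session rates (specimens per minute) are then pooled into shared
two-hour experience bins — so non-contemporary technicians are compared
at equal experience — and the per-bin mean rates are fit by ordinary
least squares against bin midpoints: a straight line for tasks that
improve steadily (imaging, skeletal databasing) or a second-order
polynomial for barcoding, whose rate peaks and then declines.  A 64-hour
experience threshold bounds the fits; participation thins out beyond it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .ratemodels import CANONICAL_MODELS, PRIMARY_TASKS, RateModel

__all__ = [
    "cumulative_task_hours",
    "bin_by_experience",
    "fit_rate_model",
    "fit_all_tasks",
]

BIN_WIDTH_HOURS = 2.0
EXPERIENCE_LIMIT_HOURS = 64.0


def cumulative_task_hours(entries: pd.DataFrame) -> pd.DataFrame:
    """Attach cumulative task experience and session rate to each entry.

    Within each (reporter, task) group, sorted by session date (ties
    keep input order), ``cumulative_task_hours`` for entry *i* is the
    running sum of session minutes through *i*, in hours.  ``rate`` is
    specimens per minute for the session itself.
    """
    records = entries.sort_values("session_date", kind="stable").copy()
    records["cumulative_task_hours"] = (
        records.groupby(["reporter_id", "task"], sort=False)["minutes"].cumsum() / 60.0
    )
    records["rate"] = records["specimens"] / records["minutes"]
    return records.reset_index(drop=True)


def bin_by_experience(
    records: pd.DataFrame,
    bin_width: float = BIN_WIDTH_HOURS,
    limit: float = EXPERIENCE_LIMIT_HOURS,
) -> pd.DataFrame:
    """Group session rates into shared experience bins per task.

    Each record with ``cumulative_task_hours < limit`` falls in exactly
    one half-open bin ``[k*w, (k+1)*w)``; records at or past the limit
    are dropped.  Zero-rate records (sessions that process no specimens,
    e.g. curation work) carry no throughput information and are
    excluded.  Returns one row per non-empty (task, bin) with the
    unweighted mean, min, max rate and the entry count.
    """
    usable = records[
        (records["cumulative_task_hours"] < limit) & (records["rate"] > 0)
    ].copy()
    usable["bin_start"] = (
        np.floor(usable["cumulative_task_hours"] / bin_width) * bin_width
    )
    grouped = usable.groupby(["task", "bin_start"])["rate"].agg(
        mean_rate="mean", n_entries="size", min_rate="min", max_rate="max"
    )
    bins = grouped.reset_index()
    bins["bin_end"] = bins["bin_start"] + bin_width
    return bins[
        ["task", "bin_start", "bin_end", "mean_rate", "n_entries", "min_rate", "max_rate"]
    ].sort_values(["task", "bin_start"], ignore_index=True)


def fit_rate_model(bins: pd.DataFrame, form: str, task: str | None = None) -> RateModel:
    """Least-squares fit of mean bin rate against bin midpoint.

    ``bins`` must contain a single task (or ``task`` names which one to
    select).  Linear fits use :func:`scipy.stats.linregress`; quadratic
    fits use :func:`numpy.polyfit`.  The fitted model inherits the
    task's canonical rate limit and the 64-hour experience limit.
    """
    if task is not None:
        bins = bins[bins["task"] == task]
    tasks = bins["task"].unique()
    if len(tasks) != 1:
        raise ValueError("bins must contain exactly one task; pass task= to select")
    task = str(tasks[0])
    needed = {"linear": 2, "quadratic": 3}.get(form)
    if needed is None:
        raise ValueError(f"unknown fit form {form!r}")
    if len(bins) < needed + 1:
        raise ValueError(
            f"need at least {needed + 1} bins for a {form} fit, got {len(bins)}"
        )
    x = (bins["bin_start"] + BIN_WIDTH_HOURS / 2.0).to_numpy(dtype=float)
    y = bins["mean_rate"].to_numpy(dtype=float)
    if form == "linear":
        fit = _scipy_stats.linregress(x, y)
        coeffs = (float(fit.intercept), float(fit.slope))
    else:
        c2, c1, c0 = np.polyfit(x, y, 2)
        coeffs = (float(c0), float(c1), float(c2))
    reference = CANONICAL_MODELS[task]
    return RateModel(
        task=task,
        form=form,
        coefficients=coeffs,
        rate_limit=reference.rate_limit,
        limit_direction=reference.limit_direction,
        experience_limit=EXPERIENCE_LIMIT_HOURS,
    )


#: Curve family used for each primary task.
TASK_FORMS = {
    "imaging": "linear",
    "skeletal_databasing": "linear",
    "barcoding": "quadratic",
}


def fit_all_tasks(bins: pd.DataFrame) -> dict[str, RateModel]:
    """Fit every primary task present in a bins table."""
    models = {}
    for task in PRIMARY_TASKS:
        if (bins["task"] == task).any():
            models[task] = fit_rate_model(bins, TASK_FORMS[task], task=task)
    return models
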