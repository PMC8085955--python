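"""Experience-dependent task-rate curves.

A :class:`RateModel` describes how a technician's throughput on one
digitization task (specimens per minute, SPM) changes with cumulative
hours of experience on that task.  Imaging and skeletal databasing
improve roughly linearly with practice; barcode application follows a
concave quadratic that peaks and then declines.  Each curve carries a
rate limit — an upper cap for the improving tasks (physical/technical
ceiling) or a lower floor for barcoding — and an experience limit beyond
which the curve is not trusted (the observational record thins out past
64 cumulative hours).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "TASKS",
    "PRIMARY_TASKS",
    "RateModel",
    "CANONICAL_MODELS",
    "canonical_model",
]

#: The four task categories a session report may carry.
TASKS = ("barcoding", "imaging", "skeletal_databasing", "other")

#: The three primary digitization tasks with rate curves.
PRIMARY_TASKS = ("barcoding", "imaging", "skeletal_databasing")


@dataclass(frozen=True)
class RateModel:
    """A task's rate-vs-experience curve.

    Parameters
    ----------
    task
        One of the primary task names.
    form
        ``"linear"`` (2 coefficients) or ``"quadratic"`` (3 coefficients).
    coefficients
        Ascending-order polynomial coefficients ``(c0, c1[, c2])``:
        ``rate(x) = c0 + c1*x [+ c2*x**2]`` with ``x`` in cumulative hours
        and the rate in specimens per minute.
    rate_limit
        The clamping rate in SPM.
    limit_direction
        ``"max"`` — the curve is capped from above (imaging, databasing);
        ``"min"`` — the curve is floored from below (barcoding).
    experience_limit
        Hours beyond which the curve is no longer extrapolated.
    """

    task: str
    form: Literal["linear", "quadratic"]
    coefficients: tuple[float, ...]
    rate_limit: float
    limit_direction: Literal["max", "min"]
    experience_limit: float = 64.0

    def __post_init__(self) -> None:
        expected = {"linear": 2, "quadratic": 3}.get(self.form)
        if expected is None:
            raise ValueError(f"unknown model form {self.form!r}")
        if len(self.coefficients) != expected:
            raise ValueError(
                f"{self.form} model needs {expected} coefficients, "
                f"got {len(self.coefficients)}"
            )
        if self.rate_limit <= 0:
            raise ValueError("rate_limit must be positive")
        if self.limit_direction not in ("max", "min"):
            raise ValueError("limit_direction must be 'max' or 'min'")
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))

    def curve(self, x):
        """Raw polynomial rate at experience ``x`` hours (no clamping)."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for power, c in enumerate(self.coefficients):
            out = out + c * x**power
        return out if out.ndim else float(out)

    def clamped(self, x):
        """Rate at experience ``x`` with the rate limit applied."""
        r = self.curve(x)
        if self.limit_direction == "max":
            return np.minimum(r, self.rate_limit) if np.ndim(r) else min(r, self.rate_limit)
        return np.maximum(r, self.rate_limit) if np.ndim(r) else max(r, self.rate_limit)


#: Reference curves for the three primary tasks (SPM vs cumulative hours),
#: with the rate limits used by the labor projections.
CANONICAL_MODELS: dict[str, RateModel] = {
    "imaging": RateModel(
        task="imaging",
        form="linear",
        coefficients=(1.95170, 0.02118),
        rate_limit=4.00,
        limit_direction="max",
    ),
    "skeletal_databasing": RateModel(
        task="skeletal_databasing",
        form="linear",
        coefficients=(2.55659, 0.02760),
        rate_limit=6.50,
        limit_direction="max",
    ),
    "barcoding": RateModel(
        task="barcoding",
        form="quadratic",
        coefficients=(3.7216, 0.09928, -0.00175),
        rate_limit=3.00,
        limit_direction="min",
    ),
}


def canonical_model(task: str) -> RateModel:
    """Return the reference :class:`RateModel` for a primary task."""
    try:
        return CANONICAL_MODELS[task]
    except KeyError:
        raise KeyError(
            f"no canonical rate model for task {task!r}; "
            f"expected one of {sorted(CANONICAL_MODELS)}"
        ) from None
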