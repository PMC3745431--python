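"""Replicate data generation.

Predictors are i.i.d. standard normal; a "dichotomous" predictor is a
standard-normal variate median-split at its population median (0) and coded
as a 0/1 indicator, so category counts are Binomial(n, 1/2) — an
approximately equal split.  The outcome follows the linear interaction
model with Gaussian error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .scenarios import ScenarioSpec, VariablePairKind

__all__ = ["ReplicateDataset", "draw_predictors", "generate_replicate", "write_replicate"]


@dataclass(frozen=True)
class ReplicateDataset:
    """One simulated sample: two predictors, their product, and the outcome."""

    x1: np.ndarray
    x2: np.ndarray
    x1x2: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        lengths = {len(self.x1), len(self.x2), len(self.x1x2), len(self.y)}
        if len(lengths) != 1:
            raise ValueError(f"column lengths differ: {lengths}")
        if not np.array_equal(self.x1x2, self.x1 * self.x2):
            raise ValueError("x1x2 is not the elementwise product of x1 and x2")

    @property
    def n(self) -> int:
        return len(self.y)

    def design_matrix(self) -> np.ndarray:
        """The n x 4 design (intercept, x1, x2, x1x2)."""
        return np.column_stack([np.ones(self.n), self.x1, self.x2, self.x1x2])


def _dichotomize(z: np.ndarray) -> np.ndarray:
    # Population-median split of a standard normal; z == 0 (probability zero)
    # goes to category 1.
    return (z >= 0.0).astype(float)


def draw_predictors(
    pair_kind: VariablePairKind | str, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw the predictor pair and their product for one replicate.

    For ``cont_dich`` the first predictor is continuous and the second is
    the 0/1 indicator.
    """
    kind = VariablePairKind.parse(pair_kind)
    if n < 10:
        raise ValueError(f"n must be >= 10, got {n}")
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x1 = z1 if kind is not VariablePairKind.DICH_DICH else _dichotomize(z1)
    x2 = z2 if kind is VariablePairKind.CONT_CONT else _dichotomize(z2)
    return x1, x2, x1 * x2


def generate_replicate(
    spec: ScenarioSpec,
    predictors: tuple[np.ndarray, np.ndarray, np.ndarray],
    rng: np.random.Generator,
) -> ReplicateDataset:
    """Attach a stochastic outcome to already-drawn predictors.

    y = beta0 + beta1*x1 + beta2*x2 + beta3*x1x2 + e with e ~ N(0, sigma^2).
    """
    x1, x2, x1x2 = predictors
    if len(x1) != spec.n:
        raise ValueError(f"predictors have length {len(x1)} but spec.n = {spec.n}")
    e = spec.sigma * rng.standard_normal(spec.n)
    y = spec.beta0 + spec.beta1 * x1 + spec.beta2 * x2 + spec.beta3 * x1x2 + e
    return ReplicateDataset(x1=x1, x2=x2, x1x2=x1x2, y=y)


def write_replicate(data: ReplicateDataset, path: str | Path) -> None:
    """Dump one replicate as a comma-delimited text file for external re-analysis."""
    table = np.column_stack([data.x1, data.x2, data.x1x2, data.y])
    np.savetxt(path, table, delimiter=",", header="x1,x2,x1x2,y", comments="")
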