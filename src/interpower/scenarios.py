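"""Scenario definitions and the default simulation grid.

A *scenario* is one cell of the study: the kind of predictor pair entering
the product term, the sample size ``n``, the standardized interaction
coefficient ``beta3``, and the nominal Type 1 error rate ``alpha`` applied
to the interaction p-value.  The default grid crosses four error rates,
five sample sizes, four effect sizes and three variable-pair kinds, giving
240 scenarios.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

import yaml

__all__ = [
    "VariablePairKind",
    "DesignMode",
    "ScenarioSpec",
    "SimulationSettings",
    "GridSpec",
    "default_grid",
    "load_grid_config",
    "save_grid_config",
]


class VariablePairKind(str, enum.Enum):
    """The distributional kind of the two predictors forming the product term."""

    CONT_CONT = "cont_cont"
    CONT_DICH = "cont_dich"
    DICH_DICH = "dich_dich"

    @classmethod
    def parse(cls, value: "VariablePairKind | str") -> "VariablePairKind":
        """Accept enum members, full names, or the short codes cc / cd / dd."""
        if isinstance(value, cls):
            return value
        aliases = {"cc": cls.CONT_CONT, "cd": cls.CONT_DICH, "dd": cls.DICH_DICH}
        key = str(value).lower()
        if key in aliases:
            return aliases[key]
        try:
            return cls(key)
        except ValueError:
            raise ValueError(
                f"unknown variable-pair kind {value!r}; "
                f"expected one of {[m.value for m in cls]} or cc/cd/dd"
            ) from None

    @property
    def short(self) -> str:
        return {"cont_cont": "cc", "cont_dich": "cd", "dich_dich": "dd"}[self.value]


class DesignMode(str, enum.Enum):
    """How the predictor matrix is treated across Monte Carlo replicates.

    ``FRESH`` redraws the predictors every replicate and estimates
    unconditional power.  ``FIXED`` draws the predictors once per scenario
    and redraws only the error term, estimating power conditional on that
    one realized design.
    """

    FRESH = "fresh"
    FIXED = "fixed"

    @classmethod
    def parse(cls, value: "DesignMode | str") -> "DesignMode":
        if isinstance(value, cls):
            return value
        key = str(value).lower()
        for member in cls:
            if key in (member.value, member.name.lower(), f"{member.value}_design"):
                return member
        raise ValueError(f"unknown design mode {value!r}; expected 'fresh' or 'fixed'")


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the power study.

    The data-generating model is

        y = beta0 + beta1*x1 + beta2*x2 + beta3*x1*x2 + e,   e ~ N(0, sigma^2)

    with standard-normal predictors (optionally median-split to 0/1
    indicators).  The lower-order coefficients default to 1; the interaction
    t-test is invariant to them, so only ``beta3``, ``n``, ``alpha``,
    ``sigma`` and the pair kind affect power.
    """

    pair_kind: VariablePairKind
    n: int
    beta3: float
    alpha: float
    beta0: float = 1.0
    beta1: float = 1.0
    beta2: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair_kind", VariablePairKind.parse(self.pair_kind))
        if int(self.n) != self.n or self.n < 10:
            raise ValueError(f"n must be an integer >= 10, got {self.n}")
        object.__setattr__(self, "n", int(self.n))
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not self.sigma > 0.0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def df_resid(self) -> int:
        """Residual degrees of freedom of the 4-parameter fit."""
        return self.n - 4

    def with_alpha(self, alpha: float) -> "ScenarioSpec":
        return replace(self, alpha=alpha)


@dataclass(frozen=True)
class SimulationSettings:
    """Replication count, master seed, and replicate design mode."""

    n_reps: int = 10_000
    seed: int = 0
    design_mode: DesignMode = DesignMode.FRESH

    def __post_init__(self) -> None:
        object.__setattr__(self, "design_mode", DesignMode.parse(self.design_mode))
        if int(self.n_reps) != self.n_reps or self.n_reps < 1:
            raise ValueError(f"n_reps must be a positive integer, got {self.n_reps}")
        object.__setattr__(self, "n_reps", int(self.n_reps))


# Axes of the full study design.
DEFAULT_ALPHAS = (0.05, 0.10, 0.15, 0.20)
DEFAULT_NS = (50, 200, 300, 500, 1000)
DEFAULT_BETA3S = (0.05, 0.14, 0.26, 0.39)


@dataclass(frozen=True)
class GridSpec:
    """Cartesian product of scenario axes.

    Enumeration order is pair_kind (outermost), then beta3, then n, then
    alpha (innermost), so that the four alphas of one (kind, beta3, n)
    triple are adjacent and can share simulated p-values.
    """

    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    ns: tuple[int, ...] = DEFAULT_NS
    beta3s: tuple[float, ...] = DEFAULT_BETA3S
    pair_kinds: tuple[VariablePairKind, ...] = tuple(VariablePairKind)
    beta0: float = 1.0
    beta1: float = 1.0
    beta2: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphas", tuple(float(a) for a in self.alphas))
        object.__setattr__(self, "ns", tuple(int(n) for n in self.ns))
        object.__setattr__(self, "beta3s", tuple(float(b) for b in self.beta3s))
        object.__setattr__(
            self,
            "pair_kinds",
            tuple(VariablePairKind.parse(k) for k in self.pair_kinds),
        )
        for axis in ("alphas", "ns", "beta3s", "pair_kinds"):
            values = getattr(self, axis)
            if not values:
                raise ValueError(f"grid axis {axis!r} is empty")
            if len(set(values)) != len(values):
                raise ValueError(f"grid axis {axis!r} has duplicate values: {values}")

    @property
    def n_cells(self) -> int:
        return len(self.alphas) * len(self.ns) * len(self.beta3s) * len(self.pair_kinds)

    @property
    def n_triples(self) -> int:
        return len(self.ns) * len(self.beta3s) * len(self.pair_kinds)

    def iter_triples(self) -> Iterator[tuple[VariablePairKind, float, int]]:
        """Yield (pair_kind, beta3, n) triples in enumeration order."""
        for kind in self.pair_kinds:
            for beta3 in self.beta3s:
                for n in self.ns:
                    yield kind, beta3, n

    def iter_cells(self) -> Iterator[ScenarioSpec]:
        """Yield every scenario exactly once, alphas innermost."""
        for kind, beta3, n in self.iter_triples():
            for alpha in self.alphas:
                yield ScenarioSpec(
                    pair_kind=kind,
                    n=n,
                    beta3=beta3,
                    alpha=alpha,
                    beta0=self.beta0,
                    beta1=self.beta1,
                    beta2=self.beta2,
                    sigma=self.sigma,
                )

    def __iter__(self) -> Iterator[ScenarioSpec]:
        return self.iter_cells()


def default_grid() -> GridSpec:
    """The published 240-cell study grid (4 alphas x 5 ns x 4 beta3s x 3 kinds)."""
    return GridSpec()


def save_grid_config(
    path: str | Path, grid: GridSpec, settings: SimulationSettings | None = None
) -> None:
    """Write a grid (and optional simulation settings) to a YAML config file."""
    payload: dict = {
        "alphas": list(grid.alphas),
        "ns": list(grid.ns),
        "beta3s": list(grid.beta3s),
        "pair_kinds": [k.value for k in grid.pair_kinds],
    }
    if settings is not None:
        payload.update(
            n_reps=settings.n_reps,
            seed=settings.seed,
            design_mode=settings.design_mode.value,
        )
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_grid_config(path: str | Path) -> tuple[GridSpec, SimulationSettings]:
    """Read a YAML config written by :func:`save_grid_config`.

    Missing settings keys fall back to the ``SimulationSettings`` defaults.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    grid = GridSpec(
        alphas=tuple(raw.get("alphas", DEFAULT_ALPHAS)),
        ns=tuple(raw.get("ns", DEFAULT_NS)),
        beta3s=tuple(raw.get("beta3s", DEFAULT_BETA3S)),
        pair_kinds=tuple(raw.get("pair_kinds", [k.value for k in VariablePairKind])),
    )
    settings = SimulationSettings(
        n_reps=int(raw.get("n_reps", 10_000)),
        seed=int(raw.get("seed", 0)),
        design_mode=DesignMode.parse(raw.get("design_mode", "fresh")),
    )
    return grid, settings
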