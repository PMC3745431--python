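"""Monte Carlo power estimation for the interaction test.

One *triple* (pair_kind, beta3, n) is simulated once, storing all replicate
p-values; the nominal error rates only threshold those stored p-values, so
power is exactly non-decreasing in alpha and the four alphas of a triple
share replicates.  Per-triple random streams are derived from the master
seed and the triple index with ``numpy.random.SeedSequence([master, index])``,
making every cell independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ols import batch_interaction_pvalues
from .scenarios import (
    DesignMode,
    GridSpec,
    ScenarioSpec,
    SimulationSettings,
    VariablePairKind,
)

__all__ = [
    "PowerEstimate",
    "DegenerateDataError",
    "estimate_power",
    "simulate_pvalues",
    "run_grid",
    "calibration_check",
    "estimates_to_frame",
    "triple_seed_sequence",
]

# Replicate-row budget per linear-algebra batch (keeps peak memory ~100 MB).
_CHUNK_BUDGET = 2_000_000


class DegenerateDataError(RuntimeError):
    """Too many degenerate (rank-deficient) replicates; the scenario is unusable."""


@dataclass(frozen=True)
class PowerEstimate:
    """Empirical power for one scenario with its Monte Carlo uncertainty."""

    scenario: ScenarioSpec
    n_reps: int
    n_reject: int
    power: float
    mc_se: float
    design_mode: DesignMode
    seed: int
    n_redraws: int = 0


def triple_seed_sequence(master_seed: int, triple_index: int) -> np.random.SeedSequence:
    """Independent, reproducible stream identity for one grid triple."""
    return np.random.SeedSequence([int(master_seed), int(triple_index)])


def _has_dich(kind: VariablePairKind) -> tuple[bool, bool]:
    return (
        kind is VariablePairKind.DICH_DICH,
        kind is not VariablePairKind.CONT_CONT,
    )


def _draw_predictor_block(
    kind: VariablePairKind, n_rows: int, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    d1, d2 = _has_dich(kind)
    x1 = rng.standard_normal((n_rows, n))
    x2 = rng.standard_normal((n_rows, n))
    if d1:
        x1 = (x1 >= 0.0).astype(float)
    if d2:
        x2 = (x2 >= 0.0).astype(float)
    return x1, x2


def _degenerate_rows(kind: VariablePairKind, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Rows whose realized design (1, x1, x2, x1*x2) is exactly rank deficient.

    With continuous predictors this happens with probability zero.  For
    cont_dich the design loses rank when fewer than two observations fall
    in either indicator category; for dich_dich, when any cell of the
    implied 2x2 layout (x1, x2) is empty.
    """
    n = x1.shape[1]
    bad = np.zeros(x1.shape[0], dtype=bool)
    if kind is VariablePairKind.CONT_DICH:
        ones = x2.sum(axis=1)
        bad |= (ones <= 1) | (ones >= n - 1)
    elif kind is VariablePairKind.DICH_DICH:
        n11 = (x1 * x2).sum(axis=1)
        n10 = (x1 * (1.0 - x2)).sum(axis=1)
        n01 = ((1.0 - x1) * x2).sum(axis=1)
        n00 = n - n11 - n10 - n01
        bad |= (n11 == 0) | (n10 == 0) | (n01 == 0) | (n00 == 0)
    return bad


def simulate_pvalues(
    spec: ScenarioSpec, settings: SimulationSettings, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, int]:
    """All replicate interaction p-values for one triple.

    Returns (p-values of length ``n_reps``, number of degenerate replicates
    redrawn).  ``spec.alpha`` is not consulted here.  In ``FIXED`` design
    mode the predictors are drawn once and only the error is redrawn; in
    ``FRESH`` mode everything is redrawn each replicate.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(settings.seed)]))
    n, n_reps = spec.n, settings.n_reps
    kind = spec.pair_kind
    max_redraws = 100 * n_reps
    n_redraws = 0

    pvals = np.empty(n_reps)
    chunk = max(1, min(n_reps, _CHUNK_BUDGET // n))

    fixed_design: tuple[np.ndarray, np.ndarray] | None = None
    if settings.design_mode is DesignMode.FIXED:
        while True:
            x1, x2 = _draw_predictor_block(kind, 1, n, rng)
            if not _degenerate_rows(kind, x1, x2)[0]:
                break
            n_redraws += 1
            if n_redraws > max_redraws:
                raise DegenerateDataError(
                    f"exceeded {max_redraws} redraws drawing a non-degenerate fixed design for {spec}"
                )
        fixed_design = (x1[0], x2[0])

    done = 0
    while done < n_reps:
        rows = min(chunk, n_reps - done)
        if fixed_design is not None:
            x1 = np.broadcast_to(fixed_design[0], (rows, n))
            x2 = np.broadcast_to(fixed_design[1], (rows, n))
        else:
            x1, x2 = _draw_predictor_block(kind, rows, n, rng)
            bad = _degenerate_rows(kind, x1, x2)
            while bad.any():
                n_redraws += int(bad.sum())
                if n_redraws > max_redraws:
                    raise DegenerateDataError(
                        f"exceeded {max_redraws} degenerate-replicate redraws for {spec}"
                    )
                r1, r2 = _draw_predictor_block(kind, int(bad.sum()), n, rng)
                x1[bad], x2[bad] = r1, r2
                bad = _degenerate_rows(kind, x1, x2)
        e = spec.sigma * rng.standard_normal((rows, n))
        y = spec.beta0 + spec.beta1 * x1 + spec.beta2 * x2 + spec.beta3 * (x1 * x2) + e
        pvals[done : done + rows] = batch_interaction_pvalues(x1, x2, y)
        done += rows
    return pvals, n_redraws


def _estimate_from_pvalues(
    spec: ScenarioSpec,
    pvals: np.ndarray,
    settings: SimulationSettings,
    seed: int,
    n_redraws: int,
) -> PowerEstimate:
    # Strict inequality: reject when p < alpha.
    n_reject = int(np.count_nonzero(pvals < spec.alpha))
    power = n_reject / settings.n_reps
    mc_se = float(np.sqrt(power * (1.0 - power) / settings.n_reps))
    return PowerEstimate(
        scenario=spec,
        n_reps=settings.n_reps,
        n_reject=n_reject,
        power=power,
        mc_se=mc_se,
        design_mode=settings.design_mode,
        seed=seed,
        n_redraws=n_redraws,
    )


def estimate_power(spec: ScenarioSpec, settings: SimulationSettings) -> PowerEstimate:
    """Empirical power of the interaction test for one scenario."""
    pvals, n_redraws = simulate_pvalues(spec, settings)
    return _estimate_from_pvalues(spec, pvals, settings, settings.seed, n_redraws)


def run_grid(grid: GridSpec, settings: SimulationSettings) -> list[PowerEstimate]:
    """One PowerEstimate per grid cell, in enumeration order.

    Each (pair_kind, beta3, n) triple is simulated once with its own
    derived stream; its stored p-values are thresholded at every grid
    alpha, so power is exactly monotone in alpha within a triple.
    """
    estimates: list[PowerEstimate] = []
    for idx, (kind, beta3, n) in enumerate(grid.iter_triples()):
        base = ScenarioSpec(
            pair_kind=kind,
            n=n,
            beta3=beta3,
            alpha=grid.alphas[0],
            beta0=grid.beta0,
            beta1=grid.beta1,
            beta2=grid.beta2,
            sigma=grid.sigma,
        )
        rng = np.random.default_rng(triple_seed_sequence(settings.seed, idx))
        try:
            pvals, n_redraws = simulate_pvalues(base, settings, rng=rng)
        except DegenerateDataError as err:
            raise DegenerateDataError(
                f"grid cell (pair_kind={kind.value}, beta3={beta3}, n={n}): {err}"
            ) from err
        for alpha in grid.alphas:
            estimates.append(
                _estimate_from_pvalues(
                    base.with_alpha(alpha), pvals, settings, settings.seed, n_redraws
                )
            )
    return estimates


def estimates_to_frame(estimates: list[PowerEstimate]) -> pd.DataFrame:
    """Tabulate estimates (one row per cell, deterministic order)."""
    return pd.DataFrame(
        {
            "pair_kind": [e.scenario.pair_kind.value for e in estimates],
            "n": [e.scenario.n for e in estimates],
            "beta3": [e.scenario.beta3 for e in estimates],
            "alpha": [e.scenario.alpha for e in estimates],
            "n_reps": [e.n_reps for e in estimates],
            "n_reject": [e.n_reject for e in estimates],
            "power": [e.power for e in estimates],
            "mc_se": [e.mc_se for e in estimates],
            "design_mode": [e.design_mode.value for e in estimates],
            "seed": [e.seed for e in estimates],
        }
    )


def calibration_check(
    grid: GridSpec, settings: SimulationSettings, n_se: float = 4.0
) -> pd.DataFrame:
    """Null-calibration audit: with beta3 = 0, rejection rate should equal alpha.

    Runs the grid with every beta3 forced to zero and flags any cell whose
    empirical rejection rate sits more than ``n_se`` binomial standard
    errors (computed at the null rate alpha) from alpha.  Returns the full
    per-cell table with a boolean ``passed`` column.
    """
    null_grid = GridSpec(
        alphas=grid.alphas,
        ns=grid.ns,
        beta3s=(0.0,),
        pair_kinds=grid.pair_kinds,
        beta0=grid.beta0,
        beta1=grid.beta1,
        beta2=grid.beta2,
        sigma=grid.sigma,
    )
    frame = estimates_to_frame(run_grid(null_grid, settings))
    null_se = np.sqrt(frame["alpha"] * (1.0 - frame["alpha"]) / frame["n_reps"])
    frame["band_lo"] = frame["alpha"] - n_se * null_se
    frame["band_hi"] = frame["alpha"] + n_se * null_se
    frame["passed"] = (frame["power"] >= frame["band_lo"]) & (
        frame["power"] <= frame["band_hi"]
    )
    return frame
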