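"""The "useful gain in power" taxonomy.

A (pair_kind, n, beta3) triple is judged on its power at the nominal 5%
error rate and at the elevated 20% rate:

* ``never_sufficient``  — power at alpha=0.20 below the floor (default 0.80);
  elevating the error rate never buys adequate power.
* ``already_sufficient`` — power at alpha=0.05 already at or above the floor.
* ``useful_gain``       — reaches the floor at 0.20 with a relative power
  increase of at least the gain threshold (default 10%).
* ``marginal``          — reaches the floor at 0.20 but the gain is too
  small to justify the extra Type 1 errors.

The four categories partition all triples; precedence is never, already,
useful, marginal.  Threshold comparisons are inclusive (>=).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .simulate import PowerEstimate
from .scenarios import VariablePairKind

__all__ = ["GainCategory", "GainClassification", "relative_gain", "classify_scenario", "taxonomy_table"]

LOW_ALPHA = 0.05
HIGH_ALPHA = 0.20


class GainCategory(str, enum.Enum):
    USEFUL_GAIN = "useful_gain"
    NEVER_SUFFICIENT = "never_sufficient"
    ALREADY_SUFFICIENT = "already_sufficient"
    MARGINAL = "marginal"


@dataclass(frozen=True)
class GainClassification:
    pair_kind: VariablePairKind | None
    n: int | None
    beta3: float | None
    power_by_alpha: dict[float, float]
    relative_gain_pct: float | None
    category: GainCategory
    borderline: bool = False


def relative_gain(power_low: float, power_high: float) -> float:
    """Relative power increase, in percent, from the low- to high-alpha power."""
    if power_low <= 0.0:
        raise ValueError(
            "relative gain is undefined at zero baseline power; "
            "such a triple is never_sufficient"
        )
    return 100.0 * (power_high - power_low) / power_low


def classify_scenario(
    power_by_alpha: Mapping[float, float],
    gain_pct: float = 10.0,
    power_floor: float = 0.80,
    low_alpha: float = LOW_ALPHA,
    high_alpha: float = HIGH_ALPHA,
    mc_se: float | None = None,
    pair_kind: VariablePairKind | None = None,
    n: int | None = None,
    beta3: float | None = None,
) -> GainClassification:
    """Assign one triple to its gain category.

    ``power_by_alpha`` must contain the low and high alphas.  When
    ``mc_se`` is given, triples within 2 standard errors of the power floor
    (at either alpha) or within a 2-SE-equivalent band of the gain
    threshold are flagged borderline: their category is simulation-noise
    sensitive.
    """
    missing = [a for a in (low_alpha, high_alpha) if a not in power_by_alpha]
    if missing:
        raise ValueError(f"power_by_alpha is missing required alpha(s) {missing}")
    p_lo = float(power_by_alpha[low_alpha])
    p_hi = float(power_by_alpha[high_alpha])

    gain = relative_gain(p_lo, p_hi) if p_lo > 0.0 else None
    if p_hi < power_floor:
        category = GainCategory.NEVER_SUFFICIENT
    elif p_lo >= power_floor:
        category = GainCategory.ALREADY_SUFFICIENT
    elif gain is not None and gain >= gain_pct:
        category = GainCategory.USEFUL_GAIN
    else:
        category = GainCategory.MARGINAL

    borderline = False
    if mc_se is not None and mc_se > 0.0:
        near_floor = (
            abs(p_hi - power_floor) <= 2.0 * mc_se or abs(p_lo - power_floor) <= 2.0 * mc_se
        )
        near_gain = False
        if gain is not None and p_lo > 0.0:
            # Delta-method SE of the gain (independent numerator/denominator powers).
            gain_se = (
                100.0
                * np.sqrt(mc_se**2 / p_lo**2 + (p_hi * mc_se / p_lo**2) ** 2)
            )
            near_gain = abs(gain - gain_pct) <= 2.0 * gain_se
        borderline = bool(near_floor or near_gain)

    return GainClassification(
        pair_kind=pair_kind,
        n=n,
        beta3=beta3,
        power_by_alpha=dict(power_by_alpha),
        relative_gain_pct=gain,
        category=category,
        borderline=borderline,
    )


def _power_frame(estimates: Iterable[PowerEstimate] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(estimates, pd.DataFrame):
        return estimates
    from .simulate import estimates_to_frame

    return estimates_to_frame(list(estimates))


def taxonomy_table(
    estimates: Iterable[PowerEstimate] | pd.DataFrame,
    gain_pct: float = 10.0,
    power_floor: float = 0.80,
    low_alpha: float = LOW_ALPHA,
    high_alpha: float = HIGH_ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every (pair_kind, beta3, n) triple and count categories per kind.

    Accepts either PowerEstimate lists or a power table with columns
    pair_kind, n, beta3, alpha, power (and optionally mc_se).  Every triple
    must cover both classification alphas.  Returns ``(table, counts)``:
    one row per triple (powers at each available alpha, relative gain,
    category, borderline flag) and the per-kind category counts.
    """
    frame = _power_frame(estimates)
    rows = []
    for (kind, beta3, n), group in frame.groupby(["pair_kind", "beta3", "n"], sort=False):
        by_alpha = dict(zip(group["alpha"], group["power"]))
        if low_alpha not in by_alpha or high_alpha not in by_alpha:
            raise ValueError(
                f"triple (pair_kind={kind}, beta3={beta3}, n={n}) lacks power at "
                f"alpha={low_alpha} and/or alpha={high_alpha}"
            )
        mc_se = float(group["mc_se"].max()) if "mc_se" in group else None
        cls = classify_scenario(
            by_alpha,
            gain_pct=gain_pct,
            power_floor=power_floor,
            low_alpha=low_alpha,
            high_alpha=high_alpha,
            mc_se=mc_se,
            pair_kind=VariablePairKind.parse(kind),
            n=int(n),
            beta3=float(beta3),
        )
        row = {"pair_kind": kind, "n": int(n), "beta3": float(beta3)}
        for alpha in sorted(by_alpha):
            row[f"power_{int(round(alpha * 100)):02d}"] = by_alpha[alpha]
        row["relative_gain_pct"] = cls.relative_gain_pct
        row["category"] = cls.category.value
        row["borderline"] = cls.borderline
        rows.append(row)
    table = pd.DataFrame(rows)
    counts = (
        table.groupby("pair_kind")["category"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=[c.value for c in GainCategory], fill_value=0)
        .rename_axis(columns=None)
    )
    return table, counts
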