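"""Incremental cost-effectiveness: ΔC, ΔE, ICER, dominance and net monetary benefit.

With two strategies the incremental analysis reduces to the differences
ΔC = C_intervention − C_comparator and ΔE = E_intervention − E_comparator.
The ICER ΔC/ΔE is reported when ΔE ≠ 0, but decisions rest on the
cost-effectiveness-plane quadrant: a negative ICER is ambiguous (it arises
both when the intervention dominates and when it is dominated), so every
result carries an explicit dominance label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .model import ArmValuation

__all__ = [
    "Dominance",
    "IncrementalResult",
    "incremental_analysis",
    "classify_dominance",
    "net_monetary_benefit",
]


class Dominance(str, Enum):
    """Quadrant of the cost-effectiveness plane, from the intervention's view."""

    INTERVENTION_DOMINANT = "intervention_dominant"  # cheaper, at least as effective
    COMPARATOR_DOMINANT = "comparator_dominant"      # costlier, at most as effective
    TRADEOFF_NE = "tradeoff_ne"                      # costlier and more effective
    TRADEOFF_SW = "tradeoff_sw"                      # cheaper and less effective
    EQUIVALENT = "equivalent"


@dataclass(frozen=True)
class IncrementalResult:
    delta_cost: float
    delta_effect: float
    icer: float | None
    dominance: Dominance


def classify_dominance(delta_cost: float, delta_effect: float) -> Dominance:
    """Quadrant label for (ΔC, ΔE); axis ties resolve toward dominance."""
    if delta_cost == 0 and delta_effect == 0:
        return Dominance.EQUIVALENT
    if delta_cost <= 0 and delta_effect >= 0:
        return Dominance.INTERVENTION_DOMINANT
    if delta_cost >= 0 and delta_effect <= 0:
        return Dominance.COMPARATOR_DOMINANT
    if delta_cost > 0:
        return Dominance.TRADEOFF_NE
    return Dominance.TRADEOFF_SW


def incremental_analysis(
    intervention: ArmValuation, comparator: ArmValuation
) -> IncrementalResult:
    """ΔC, ΔE, ICER and dominance of the intervention versus the comparator.

    The ICER is computed from the unrounded deltas (rounding the inputs
    first shifts the ratio) and is ``None`` when ΔE = 0.
    """
    delta_cost = intervention.cost - comparator.cost
    delta_effect = intervention.effect - comparator.effect
    icer = delta_cost / delta_effect if delta_effect != 0 else None
    return IncrementalResult(
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=icer,
        dominance=classify_dominance(delta_cost, delta_effect),
    )


def net_monetary_benefit(valuation: ArmValuation, wtp: float) -> float:
    """NMB = wtp × effect − cost at willingness-to-pay ``wtp`` per unit effect.

    The strategy with the higher NMB is cost-effective at that
    willingness-to-pay; at wtp = 0 this is simply the negative cost.
    """
    if wtp < 0 or math.isnan(wtp):
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * valuation.effect - valuation.cost
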