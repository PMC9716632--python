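"""Decision-tree rollback: expected cost and effectiveness per strategy.

The tree has one decision node (choice of dressing strategy) and, per
strategy, one chance node (complete healing at the end of the horizon, or
not). Rolling back the tree gives per strategy:

* expected effectiveness — the healing probability itself (terminal
  payoffs 1/0 weighted by the chance-node probabilities), and
* expected cost — identical on both branches, since dressings are applied
  for the whole horizon regardless of when healing occurs:

  ``cost = horizon_weeks * units_per_week * (unit_price + change_tariff)``

Each applied dressing unit implies one billed dressing change (home-care
visit), so the weekly cost couples the unit price and the change tariff
through the same utilisation count. Costs are carried at full floating
precision; rounding happens only at reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .config import Scenario, StrategyArm

__all__ = [
    "ArmValuation",
    "weekly_cost",
    "strategy_cost",
    "healing_rate_from_counts",
    "rollback",
]


@dataclass(frozen=True)
class ArmValuation:
    """Expected cost (currency units over the horizon) and probability of
    complete healing for one strategy."""

    strategy_name: str
    cost: float
    effect: float

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError(f"cost must be >= 0, got {self.cost}")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError(f"effect must lie in [0, 1], got {self.effect}")


def weekly_cost(units_per_week: float, unit_price: float, change_tariff: float) -> float:
    """Cost of one treatment week: each unit applied is one dressing plus
    one billed change, so ``units_per_week * (unit_price + change_tariff)``."""
    if units_per_week < 0 or unit_price < 0 or change_tariff < 0:
        raise ValueError("weekly_cost arguments must be >= 0")
    return units_per_week * (unit_price + change_tariff)


def strategy_cost(arm: StrategyArm, change_tariff: float, horizon_weeks: int) -> float:
    """Expected cost of a strategy at its baseline inputs over the horizon."""
    if horizon_weeks < 1:
        raise ValueError("horizon_weeks must be >= 1")
    return horizon_weeks * weekly_cost(
        arm.units_per_week.baseline, arm.unit_price.baseline, change_tariff
    )


def healing_rate_from_counts(healed: int, total: int) -> float:
    """Pooled complete-healing probability from patient counts.

    E.g. 125 of 206 patients healed gives 0.6068; 148 of 254 gives 0.5827.
    """
    if total <= 0:
        raise ValueError("total must be a positive integer")
    if healed < 0 or healed > total:
        raise ValueError("healed must satisfy 0 <= healed <= total")
    return healed / total


def rollback(
    scenario: Scenario,
    overrides: Mapping[str, float] | None = None,
) -> tuple[ArmValuation, ArmValuation]:
    """Evaluate the tree, returning (intervention, comparator) valuations.

    ``overrides`` maps parameter names (see ``Scenario.parameter_map``) to
    values, leaving every other parameter at its baseline; this is the
    single evaluation primitive reused by the one-way and probabilistic
    sensitivity analyses. Unknown names raise ``ValueError``.
    """
    params = scenario.parameter_map()
    overrides = dict(overrides or {})
    unknown = set(overrides) - set(params)
    if unknown:
        raise ValueError(f"overrides name unknown parameters: {sorted(unknown)}")

    def value(name: str) -> float:
        return overrides.get(name, params[name].baseline)

    tariff = value(scenario.change_tariff.name)
    out = []
    for arm in scenario.arms:
        cost = scenario.horizon_weeks * weekly_cost(
            value(arm.units_per_week.name), value(arm.unit_price.name), tariff
        )
        out.append(ArmValuation(strategy_name=arm.name, cost=cost, effect=value(arm.healing_rate.name)))
    return out[0], out[1]
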