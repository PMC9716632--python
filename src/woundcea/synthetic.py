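"""Synthetic two-strategy scenarios with analytically known ground truth.

Every pipeline stage can be exercised without external data by generating
random but internally *consistent* scenarios: each PSA distribution is
moment-matched to its baseline (gamma prices with the baseline as mean,
binomial units with np equal to the baseline count, beta healing rates with
the baseline as mean), so closed-form expectations are available as oracles.

By independence of the draws, the expected 12-week cost of an arm factorises

    E[cost] = horizon · E[units] · (E[price] + E[tariff]),

which :func:`analytic_expected_cost` evaluates from distribution means
alone — the oracle against which Monte-Carlo output is checked.

Note the published input table deliberately does *not* have this
moment-matched property (its binomial means differ from the baseline unit
counts); synthetic scenarios trade that fidelity for exact oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (
    DistributionSpec,
    Family,
    ParameterSpec,
    Role,
    Scenario,
    StrategyArm,
)
from .incremental import Dominance, classify_dominance
from .psa import distribution_mean, moment_match_gamma

__all__ = [
    "SyntheticTruth",
    "generate_scenario",
    "analytic_expected_cost",
    "degenerate_scenario",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """A generated scenario together with its closed-form expectations."""

    scenario: Scenario
    expected_cost: dict[str, float]      # arm name -> analytic E[12-week cost]
    expected_effect: dict[str, float]    # arm name -> analytic E[healing rate]
    dominance_at_baseline: Dominance


def analytic_expected_cost(
    unit_price: DistributionSpec,
    units_per_week: DistributionSpec,
    change_tariff: DistributionSpec,
    horizon_weeks: int,
) -> float:
    """E[cost] = horizon · E[units] · (E[price] + E[tariff]), by independence."""
    return (
        horizon_weeks
        * distribution_mean(units_per_week)
        * (distribution_mean(unit_price) + distribution_mean(change_tariff))
    )


def _price_param(name: str, role: Role, baseline: float) -> ParameterSpec:
    return ParameterSpec(
        name=name, role=role, baseline=baseline,
        owsa_low=baseline * 0.9, owsa_high=baseline * 1.1,
        distribution=moment_match_gamma(baseline, baseline / 100.0),
    )


def _units_param(name: str, baseline: int) -> ParameterSpec:
    n_trials = 8  # p = baseline/8 keeps the binomial mean at the baseline count
    return ParameterSpec(
        name=name, role=Role.UNITS_PER_WEEK, baseline=baseline,
        owsa_low=max(0, baseline - 1), owsa_high=baseline + 1,
        distribution=DistributionSpec(family=Family.BINOMIAL, params=(n_trials, baseline / n_trials)),
    )


def _healing_param(name: str, baseline: float) -> ParameterSpec:
    conc = 10.0  # beta concentration alpha+beta; mean = baseline
    return ParameterSpec(
        name=name, role=Role.HEALING_RATE, baseline=baseline,
        owsa_low=baseline / 2, owsa_high=baseline + (1 - baseline) / 2,
        distribution=DistributionSpec(
            family=Family.BETA, params=(baseline * conc, (1 - baseline) * conc)
        ),
    )


def generate_scenario(
    rng: np.random.Generator,
    price_range: tuple[float, float] = (5.0, 50.0),
    units_range: tuple[int, int] = (1, 4),
    rate_range: tuple[float, float] = (0.1, 0.9),
    horizon_weeks: int = 12,
) -> SyntheticTruth:
    """Draw a random valid scenario with moment-matched PSA distributions.

    Baselines are uniform over the given ranges (unit counts uniform over the
    integer range); OWSA bounds bracket the baselines by construction; the
    truth fields are filled analytically, never by simulation.
    """
    if price_range[0] <= 0 or price_range[0] > price_range[1]:
        raise ValueError("price_range must satisfy 0 < low <= high")
    if units_range[0] < 1 or units_range[0] > units_range[1]:
        raise ValueError("units_range must satisfy 1 <= low <= high")
    if not (0 < rate_range[0] <= rate_range[1] < 1):
        raise ValueError("rate_range must lie inside (0, 1)")

    def make_arm(name: str) -> StrategyArm:
        return StrategyArm(
            name=name,
            unit_price=_price_param(
                f"{name}.unit_price", Role.UNIT_PRICE, float(rng.uniform(*price_range))
            ),
            units_per_week=_units_param(
                f"{name}.units_per_week", int(rng.integers(units_range[0], units_range[1] + 1))
            ),
            healing_rate=_healing_param(
                f"{name}.healing_rate", float(rng.uniform(*rate_range))
            ),
        )

    intervention = make_arm("synthA")
    comparator = make_arm("synthB")
    tariff_baseline = float(rng.uniform(5.0, 20.0))
    tariff = ParameterSpec(
        name="change_tariff", role=Role.CHANGE_TARIFF, baseline=tariff_baseline,
        owsa_low=tariff_baseline * 0.8, owsa_high=tariff_baseline * 1.2,
        distribution=moment_match_gamma(tariff_baseline, tariff_baseline / 50.0),
    )
    scenario = Scenario(
        intervention=intervention, comparator=comparator, change_tariff=tariff,
        horizon_weeks=horizon_weeks, currency_label="synthetic Euro",
    )

    expected_cost = {
        arm.name: analytic_expected_cost(
            arm.unit_price.distribution,
            arm.units_per_week.distribution,
            tariff.distribution,
            horizon_weeks,
        )
        for arm in scenario.arms
    }
    expected_effect = {arm.name: distribution_mean(arm.healing_rate.distribution) for arm in scenario.arms}
    dom = classify_dominance(
        expected_cost[intervention.name] - expected_cost[comparator.name],
        expected_effect[intervention.name] - expected_effect[comparator.name],
    )
    return SyntheticTruth(
        scenario=scenario,
        expected_cost=expected_cost,
        expected_effect=expected_effect,
        dominance_at_baseline=dom,
    )


def degenerate_scenario(
    cost_intervention: float,
    effect_intervention: float,
    cost_comparator: float,
    effect_comparator: float,
    horizon_weeks: int = 12,
) -> Scenario:
    """A point-mass scenario whose rollback yields exactly the given valuations.

    Units are fixed at 1/week, the tariff at 0, and each unit price at
    cost/horizon, so the PSA degenerates to the base case — the brute-force
    oracle for CEAC behaviour under strict dominance and exact ties.
    """
    for label, c in (("intervention", cost_intervention), ("comparator", cost_comparator)):
        if c < 0:
            raise ValueError(f"{label} cost must be >= 0")
    for label, e in (("intervention", effect_intervention), ("comparator", effect_comparator)):
        if not 0.0 <= e <= 1.0:
            raise ValueError(f"{label} effect must lie in [0, 1]")

    def fixed(value: float) -> DistributionSpec:
        return DistributionSpec(family=Family.FIXED, params=(value,))

    def make_arm(name: str, cost: float, effect: float) -> StrategyArm:
        price = cost / horizon_weeks  # units fixed at 1, tariff at 0
        return StrategyArm(
            name=name,
            unit_price=ParameterSpec(
                name=f"{name}.unit_price", role=Role.UNIT_PRICE, baseline=price,
                owsa_low=price, owsa_high=price, distribution=fixed(price),
            ),
            units_per_week=ParameterSpec(
                name=f"{name}.units_per_week", role=Role.UNITS_PER_WEEK, baseline=1,
                owsa_low=1, owsa_high=1, distribution=fixed(1),
            ),
            healing_rate=ParameterSpec(
                name=f"{name}.healing_rate", role=Role.HEALING_RATE, baseline=effect,
                owsa_low=effect, owsa_high=effect, distribution=fixed(effect),
            ),
        )

    tariff = ParameterSpec(
        name="change_tariff", role=Role.CHANGE_TARIFF, baseline=0.0,
        owsa_low=0.0, owsa_high=0.0, distribution=fixed(0.0),
    )
    return Scenario(
        intervention=make_arm("degenA", cost_intervention, effect_intervention),
        comparator=make_arm("degenB", cost_comparator, effect_comparator),
        change_tariff=tariff,
        horizon_weeks=horizon_weeks,
        currency_label="synthetic Euro",
    )
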