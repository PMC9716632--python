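"""Model/results facade tying the pipeline stages together.

``DecisionTreeCEA`` is constructed from a :class:`~woundcea.config.Scenario`
(or a JSON document); ``fit()`` evaluates the tree at baseline and returns a
:class:`BaseCaseResult` carrying both arm valuations, the incremental
quantities and a printable summary; ``owsa()`` and ``psa()`` run the
sensitivity analyses and return their results objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import Scenario, builtin_paper_scenario, load_scenario
from .incremental import IncrementalResult, incremental_analysis
from .model import ArmValuation, rollback
from .owsa import OwsaRow, run_owsa, tornado_table
from .psa import DEFAULT_WTP_GRID, PsaResult, run_psa

__all__ = ["DecisionTreeCEA", "BaseCaseResult", "OwsaResult"]


@dataclass(frozen=True)
class BaseCaseResult:
    """Deterministic evaluation of the tree at baseline (or overridden) inputs."""

    intervention: ArmValuation
    comparator: ArmValuation
    incremental: IncrementalResult

    def to_frame(self) -> pd.DataFrame:
        """Two strategy rows plus one incremental row, with full-precision and
        report-precision (2 dp costs / 4 dp rates) columns."""
        inc = self.incremental
        rows = [
            {
                "row_type": "strategy", "name": arm.strategy_name,
                "cost": arm.cost, "effect": arm.effect,
                "cost_report": round(arm.cost, 2), "effect_report": round(arm.effect, 4),
            }
            for arm in (self.intervention, self.comparator)
        ]
        rows.append(
            {
                "row_type": "incremental",
                "name": f"{self.intervention.strategy_name} vs {self.comparator.strategy_name}",
                "delta_cost": inc.delta_cost, "delta_effect": inc.delta_effect,
                "icer": inc.icer, "dominance": inc.dominance.value,
                "delta_cost_report": round(inc.delta_cost, 2),
                "delta_effect_report": round(inc.delta_effect, 4),
                "icer_report": None if inc.icer is None else round(inc.icer, 2),
            }
        )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        inc = self.incremental
        icer = "undefined" if inc.icer is None else f"{inc.icer:,.2f}"
        return "\n".join(
            [
                f"{'strategy':<12}{'cost':>12}{'healing rate':>15}",
                f"{self.intervention.strategy_name:<12}{self.intervention.cost:>12,.2f}{self.intervention.effect:>15.4f}",
                f"{self.comparator.strategy_name:<12}{self.comparator.cost:>12,.2f}{self.comparator.effect:>15.4f}",
                "",
                f"incremental cost:    {inc.delta_cost:,.2f}",
                f"incremental healing: {inc.delta_effect:.4f}",
                f"ICER:                {icer}",
                f"dominance:           {inc.dominance.value}",
            ]
        )


@dataclass(frozen=True)
class OwsaResult:
    """One-way sensitivity rows plus tornado ordering and table export."""

    rows: tuple[OwsaRow, ...]
    reference_wtp: float

    def tornado(self) -> list[OwsaRow]:
        return tornado_table(list(self.rows))

    def to_frame(self, tornado_order: bool = True) -> pd.DataFrame:
        rows = self.tornado() if tornado_order else list(self.rows)
        return pd.DataFrame(
            {
                "parameter": [r.parameter_name for r in rows],
                "low": [r.low_value for r in rows],
                "high": [r.high_value for r in rows],
                "outcome_low": [r.outcome_at_low for r in rows],
                "outcome_high": [r.outcome_at_high for r in rows],
                "width": [r.range_width for r in rows],
            }
        )

    def summary(self) -> str:
        lines = [f"OWSA (incremental NMB at wtp={self.reference_wtp:g})"]
        for r in self.tornado():
            lines.append(
                f"  {r.parameter_name:<28} [{r.low_value:g}, {r.high_value:g}]"
                f" -> outcome [{r.outcome_at_low:,.2f}, {r.outcome_at_high:,.2f}] width {r.range_width:,.2f}"
            )
        return "\n".join(lines)


class DecisionTreeCEA:
    """Two-strategy decision-tree cost-effectiveness model.

    Parameters
    ----------
    scenario : Scenario
        Validated scenario; see :func:`woundcea.config.load_scenario` and
        :func:`woundcea.config.builtin_paper_scenario`.

    Examples
    --------
    >>> from woundcea import DecisionTreeCEA
    >>> model = DecisionTreeCEA.from_builtin()
    >>> res = model.fit()
    >>> round(res.incremental.delta_cost, 2)
    -133.25
    """

    def __init__(self, scenario: Scenario):
        self.scenario = scenario

    @classmethod
    def from_json(cls, config_text: str) -> "DecisionTreeCEA":
        return cls(load_scenario(config_text))

    @classmethod
    def from_builtin(cls, tariff_gamma: str = "moment_matched") -> "DecisionTreeCEA":
        return cls(builtin_paper_scenario(tariff_gamma))

    def fit(self, overrides: Mapping[str, float] | None = None) -> BaseCaseResult:
        """Roll the tree back at baseline values (or with overrides)."""
        intervention, comparator = rollback(self.scenario, overrides)
        return BaseCaseResult(
            intervention=intervention,
            comparator=comparator,
            incremental=incremental_analysis(intervention, comparator),
        )

    def owsa(self, reference_wtp: float = 0.0) -> OwsaResult:
        return OwsaResult(rows=tuple(run_owsa(self.scenario, reference_wtp)), reference_wtp=reference_wtp)

    def psa(
        self,
        n_iterations: int = 10_000,
        seed: int | np.random.Generator | None = None,
    ) -> PsaResult:
        return run_psa(self.scenario, n_iterations=n_iterations, seed=seed)

    def ceac(
        self,
        n_iterations: int = 10_000,
        seed: int | np.random.Generator | None = None,
        wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
    ):
        return self.psa(n_iterations=n_iterations, seed=seed).ceac(wtp_grid)
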