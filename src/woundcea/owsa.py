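"""One-way deterministic sensitivity analysis with tornado ranking.

Each model parameter is pushed, one at a time, to the low and then the high
end of its range while all other parameters stay at baseline. The outcome
recorded per evaluation is the *incremental net monetary benefit* of the
intervention, wtp × ΔE − ΔC, at a configurable reference willingness-to-pay
(default 0, where it reduces to −ΔC). NMB is bounded where the ICER is not:
healing-rate ranges here can flip the sign of ΔE, which makes the ratio
explode through ±∞ and unusable as a tornado axis.

Note that at the default wtp = 0 the healing-rate rows have zero width
(they do not touch cost), and the shared change tariff cancels from ΔC
whenever both arms use the same baseline number of units per week.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import Scenario
from .incremental import incremental_analysis
from .model import rollback

__all__ = ["OwsaRow", "run_owsa", "tornado_table"]


@dataclass(frozen=True)
class OwsaRow:
    parameter_name: str
    low_value: float
    high_value: float
    outcome_at_low: float
    outcome_at_high: float

    @property
    def range_width(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


def _incremental_nmb(scenario: Scenario, overrides: dict[str, float], wtp: float) -> float:
    inc = incremental_analysis(*rollback(scenario, overrides))
    return wtp * inc.delta_effect - inc.delta_cost


def run_owsa(scenario: Scenario, reference_wtp: float = 0.0) -> list[OwsaRow]:
    """One row per parameter, in scenario order; exactly one parameter is
    off-baseline in every model evaluation."""
    if reference_wtp < 0:
        raise ValueError("reference_wtp must be >= 0")
    rows = []
    for name, spec in scenario.parameter_map().items():
        rows.append(
            OwsaRow(
                parameter_name=name,
                low_value=spec.owsa_low,
                high_value=spec.owsa_high,
                outcome_at_low=_incremental_nmb(scenario, {name: spec.owsa_low}, reference_wtp),
                outcome_at_high=_incremental_nmb(scenario, {name: spec.owsa_high}, reference_wtp),
            )
        )
    return rows


def tornado_table(rows: list[OwsaRow]) -> list[OwsaRow]:
    """Rows sorted by descending outcome range (tornado order); ties break
    lexicographically by parameter name."""
    if not rows:
        raise ValueError("tornado_table requires at least one row")
    return sorted(rows, key=lambda r: (-r.range_width, r.parameter_name))
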