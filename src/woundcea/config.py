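"""Scenario configuration: domain types, JSON (de)serialisation and the built-in scenario.

A *scenario* describes a two-strategy comparison of wound-dressing
treatments over a fixed horizon: for each strategy a dressing unit price,
a number of dressing units applied per week, and a probability of complete
wound healing at the end of the horizon, plus a single dressing-change
tariff shared by both arms (in Germany the change tariff is negotiated
centrally and does not depend on the dressing used).

Every model input is a :class:`ParameterSpec` carrying three layers of
information:

* ``baseline`` — the point estimate used in the base-case analysis,
* ``owsa_low`` / ``owsa_high`` — the deterministic one-way sensitivity range,
* ``distribution`` — the sampling distribution for probabilistic
  sensitivity analysis (gamma for prices, binomial for unit counts,
  beta for probabilities, or a point mass).

The JSON schema is documented in ``docs/methods.md``; percentage OWSA
ranges (``"owsa": {"pct": 5}``) are materialised to absolute bounds at
load time so downstream code treats all ranges uniformly.
"""

from __future__ import annotations

import json
from enum import Enum
from typing import Any, Mapping

import pydantic
from pydantic import BaseModel, Field

__all__ = [
    "Family",
    "Role",
    "DistributionSpec",
    "ParameterSpec",
    "StrategyArm",
    "Scenario",
    "ScenarioValidationError",
    "load_scenario",
    "write_scenario",
    "builtin_paper_scenario",
    "TARIFF_GAMMA_MODES",
]


class ScenarioValidationError(ValueError):
    """A scenario document violates the schema or a model invariant."""


class Family(str, Enum):
    GAMMA = "gamma"
    BINOMIAL = "binomial"
    BETA = "beta"
    FIXED = "fixed"


class Role(str, Enum):
    UNIT_PRICE = "unit_price"
    UNITS_PER_WEEK = "units_per_week"
    HEALING_RATE = "healing_rate"
    CHANGE_TARIFF = "change_tariff"


class DistributionSpec(BaseModel, frozen=True):
    """A PSA sampling distribution.

    ``params`` are ordered by family convention:

    * gamma: ``(theta, kappa)`` = (scale, shape); mean ``kappa * theta``
    * binomial: ``(n, p)``; integer support ``0..n``, mean ``n * p``
    * beta: ``(alpha, beta)``; support ``[0, 1]``
    * fixed: ``(value,)`` — a point mass
    """

    family: Family
    params: tuple[float, ...]

    @pydantic.model_validator(mode="after")
    def _check_params(self) -> "DistributionSpec":
        fam, p = self.family, self.params
        if fam is Family.GAMMA:
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ValueError("gamma requires (theta, kappa) with theta > 0 and kappa > 0")
        elif fam is Family.BINOMIAL:
            if len(p) != 2:
                raise ValueError("binomial requires (n, p)")
            n, prob = p
            if n < 1 or n != int(n):
                raise ValueError("binomial n must be a positive integer")
            if not 0.0 <= prob <= 1.0:
                raise ValueError("binomial p must lie in [0, 1]")
        elif fam is Family.BETA:
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ValueError("beta requires alpha > 0 and beta > 0")
        elif fam is Family.FIXED:
            if len(p) != 1:
                raise ValueError("fixed requires a single value")
        return self


class ParameterSpec(BaseModel, frozen=True):
    """One model input with its baseline, OWSA range and PSA distribution."""

    name: str
    role: Role
    baseline: float
    owsa_low: float
    owsa_high: float
    distribution: DistributionSpec

    @pydantic.model_validator(mode="after")
    def _check_invariants(self) -> "ParameterSpec":
        if not self.owsa_low <= self.baseline <= self.owsa_high:
            raise ValueError(
                f"parameter {self.name!r}: OWSA range must bracket the baseline "
                f"(low={self.owsa_low}, baseline={self.baseline}, high={self.owsa_high})"
            )
        if self.role is Role.HEALING_RATE:
            for label, v in (("owsa_low", self.owsa_low), ("baseline", self.baseline), ("owsa_high", self.owsa_high)):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"parameter {self.name!r}: healing-rate {label}={v} outside [0, 1]")
        else:
            if self.owsa_low < 0:
                raise ValueError(f"parameter {self.name!r}: prices and unit counts must be >= 0")
        return self


class StrategyArm(BaseModel, frozen=True):
    """One treatment strategy: price, utilisation and effectiveness inputs."""

    name: str
    unit_price: ParameterSpec
    units_per_week: ParameterSpec
    healing_rate: ParameterSpec

    @pydantic.model_validator(mode="after")
    def _check_roles(self) -> "StrategyArm":
        expected = {
            "unit_price": Role.UNIT_PRICE,
            "units_per_week": Role.UNITS_PER_WEEK,
            "healing_rate": Role.HEALING_RATE,
        }
        for field, role in expected.items():
            spec: ParameterSpec = getattr(self, field)
            if spec.role is not role:
                raise ValueError(f"arm {self.name!r}: field {field} has role {spec.role.value!r}")
        return self


class Scenario(BaseModel, frozen=True):
    """A two-strategy comparison with a shared dressing-change tariff."""

    intervention: StrategyArm
    comparator: StrategyArm
    change_tariff: ParameterSpec
    horizon_weeks: int = Field(default=12, ge=1)
    currency_label: str = "2021 Euro"

    @pydantic.model_validator(mode="after")
    def _check(self) -> "Scenario":
        if self.intervention.name == self.comparator.name:
            raise ValueError("strategy names must be distinct")
        if self.change_tariff.role is not Role.CHANGE_TARIFF:
            raise ValueError("change_tariff parameter must have role 'change_tariff'")
        return self

    @property
    def arms(self) -> tuple[StrategyArm, StrategyArm]:
        return (self.intervention, self.comparator)

    def parameter_map(self) -> dict[str, ParameterSpec]:
        """All parameters keyed by name, in the documented sampling order.

        Order: intervention price, units, healing rate; comparator price,
        units, healing rate; shared change tariff.
        """
        out: dict[str, ParameterSpec] = {}
        for arm in self.arms:
            for spec in (arm.unit_price, arm.units_per_week, arm.healing_rate):
                out[spec.name] = spec
        out[self.change_tariff.name] = self.change_tariff
        return out


# ---------------------------------------------------------------------------
# JSON (de)serialisation


def _param_from_json(obj: Mapping[str, Any], name: str, role: Role) -> ParameterSpec:
    if not isinstance(obj, Mapping) or "baseline" not in obj:
        raise ScenarioValidationError(f"parameter {name!r}: missing 'baseline'")
    baseline = obj["baseline"]
    owsa = obj.get("owsa")
    if owsa is None:
        low = high = baseline
    elif "pct" in owsa:
        frac = owsa["pct"] / 100.0
        low, high = baseline * (1 - frac), baseline * (1 + frac)
    else:
        try:
            low, high = owsa["low"], owsa["high"]
        except KeyError as exc:
            raise ScenarioValidationError(
                f"parameter {name!r}: owsa must carry 'low'/'high' or 'pct'"
            ) from exc
    dist_obj = obj.get("dist")
    if dist_obj is None:
        dist = DistributionSpec(family=Family.FIXED, params=(baseline,))
    else:
        try:
            dist = DistributionSpec(family=dist_obj["family"], params=tuple(dist_obj["params"]))
        except (KeyError, pydantic.ValidationError) as exc:
            raise ScenarioValidationError(f"parameter {name!r}: invalid distribution: {exc}") from exc
    try:
        return ParameterSpec(
            name=name, role=role, baseline=baseline,
            owsa_low=low, owsa_high=high, distribution=dist,
        )
    except pydantic.ValidationError as exc:
        raise ScenarioValidationError(str(exc)) from exc


def load_scenario(config_text: str | Mapping[str, Any]) -> Scenario:
    """Parse and validate a JSON scenario document.

    Accepts either the raw JSON text or an already-parsed mapping.
    Raises :class:`ScenarioValidationError` naming the offending field on
    any schema or invariant violation.
    """
    if isinstance(config_text, (str, bytes)):
        try:
            doc = json.loads(config_text)
        except json.JSONDecodeError as exc:
            raise ScenarioValidationError(f"not valid JSON: {exc}") from exc
    else:
        doc = config_text
    strategies = doc.get("strategies")
    if not isinstance(strategies, list) or len(strategies) != 2:
        raise ScenarioValidationError("'strategies' must be an array of exactly 2 strategies")
    arms = []
    for raw in strategies:
        arm_name = raw.get("name")
        if not arm_name:
            raise ScenarioValidationError("each strategy requires a 'name'")
        try:
            arm = StrategyArm(
                name=arm_name,
                unit_price=_param_from_json(raw["unit_price"], f"{arm_name}.unit_price", Role.UNIT_PRICE),
                units_per_week=_param_from_json(
                    raw["units_per_week"], f"{arm_name}.units_per_week", Role.UNITS_PER_WEEK
                ),
                healing_rate=_param_from_json(
                    raw["healing_rate"], f"{arm_name}.healing_rate", Role.HEALING_RATE
                ),
            )
        except KeyError as exc:
            raise ScenarioValidationError(f"strategy {arm_name!r}: missing field {exc}") from exc
        except pydantic.ValidationError as exc:
            raise ScenarioValidationError(str(exc)) from exc
        arms.append(arm)
    if "change_tariff" not in doc:
        raise ScenarioValidationError("missing 'change_tariff'")
    tariff = _param_from_json(doc["change_tariff"], "change_tariff", Role.CHANGE_TARIFF)
    try:
        return Scenario(
            intervention=arms[0],
            comparator=arms[1],
            change_tariff=tariff,
            horizon_weeks=doc.get("horizon_weeks", 12),
            currency_label=doc.get("currency", "2021 Euro"),
        )
    except pydantic.ValidationError as exc:
        raise ScenarioValidationError(str(exc)) from exc


def _param_to_json(spec: ParameterSpec) -> dict[str, Any]:
    return {
        "baseline": spec.baseline,
        "owsa": {"low": spec.owsa_low, "high": spec.owsa_high},
        "dist": {"family": spec.distribution.family.value, "params": list(spec.distribution.params)},
    }


def write_scenario(scenario: Scenario) -> str:
    """Serialise a scenario to its JSON document form.

    Round-trip stable: ``load_scenario(write_scenario(s)) == s``.
    Percentage OWSA ranges are written as the absolute bounds they were
    materialised to at load time.
    """
    doc = {
        "currency": scenario.currency_label,
        "horizon_weeks": scenario.horizon_weeks,
        "strategies": [
            {
                "name": arm.name,
                "unit_price": _param_to_json(arm.unit_price),
                "units_per_week": _param_to_json(arm.units_per_week),
                "healing_rate": _param_to_json(arm.healing_rate),
            }
            for arm in scenario.arms
        ],
        "change_tariff": _param_to_json(scenario.change_tariff),
    }
    return json.dumps(doc, indent=2)


# ---------------------------------------------------------------------------
# Built-in scenario (published input table, 2021 Euro)

TARIFF_GAMMA_MODES = ("moment_matched", "as_printed")

#: Printed change-tariff gamma parameters (scale, shape). Their implied mean
#: (112.4) contradicts the printed baseline 12.1667 — an apparent misprint in
#: the source table. The default mode keeps the printed scale and rescales the
#: shape so the distribution mean equals the baseline; see docs/methods.md.
_TARIFF_THETA = 0.5264
_TARIFF_KAPPA_PRINTED = 213.55
_TARIFF_BASELINE = 12.1667


def builtin_paper_scenario(tariff_gamma: str = "moment_matched") -> Scenario:
    """The published two-strategy input set: hyaluronic-acid vs silver dressings.

    Unit prices (2021 Euro per dressing unit), dressing units per week,
    12-week complete-healing probabilities, and the shared dressing-change
    tariff, each with its OWSA range and PSA distribution.

    Parameters
    ----------
    tariff_gamma : {"moment_matched", "as_printed"}
        How to build the change-tariff gamma distribution.
        ``moment_matched`` (default) keeps the printed scale 0.5264 and sets
        the shape to baseline/scale ≈ 23.113 so the mean equals the baseline
        12.1667. ``as_printed`` uses the literal printed (0.5264, 213.55),
        whose mean 112.4 is inconsistent with the baseline.
    """
    if tariff_gamma not in TARIFF_GAMMA_MODES:
        raise ValueError(f"tariff_gamma must be one of {TARIFF_GAMMA_MODES}")
    if tariff_gamma == "moment_matched":
        tariff_kappa = _TARIFF_BASELINE / _TARIFF_THETA
    else:
        tariff_kappa = _TARIFF_KAPPA_PRINTED

    def gamma(theta: float, kappa: float) -> DistributionSpec:
        return DistributionSpec(family=Family.GAMMA, params=(theta, kappa))

    def binom(n: int, p: float) -> DistributionSpec:
        return DistributionSpec(family=Family.BINOMIAL, params=(n, p))

    def beta(a: float, b: float) -> DistributionSpec:
        return DistributionSpec(family=Family.BETA, params=(a, b))

    ha = StrategyArm(
        name="HA",
        unit_price=ParameterSpec(
            name="HA.unit_price", role=Role.UNIT_PRICE, baseline=19.0750,
            owsa_low=19.0750 * 0.95, owsa_high=19.0750 * 1.05,
            distribution=gamma(0.0477, 400),
        ),
        units_per_week=ParameterSpec(
            name="HA.units_per_week", role=Role.UNITS_PER_WEEK, baseline=2,
            owsa_low=2, owsa_high=3, distribution=binom(8, 0.18),
        ),
        healing_rate=ParameterSpec(
            name="HA.healing_rate", role=Role.HEALING_RATE, baseline=0.6068,
            owsa_low=0.24, owsa_high=0.96, distribution=beta(2.03, 1.2960),
        ),
    )
    silver = StrategyArm(
        name="Silver",
        unit_price=ParameterSpec(
            name="Silver.unit_price", role=Role.UNIT_PRICE, baseline=24.6270,
            owsa_low=24.6270 * 0.95, owsa_high=24.6270 * 1.05,
            distribution=gamma(0.0616, 400),
        ),
        units_per_week=ParameterSpec(
            name="Silver.units_per_week", role=Role.UNITS_PER_WEEK, baseline=2,
            owsa_low=2, owsa_high=5, distribution=binom(8, 0.23),
        ),
        healing_rate=ParameterSpec(
            name="Silver.healing_rate", role=Role.HEALING_RATE, baseline=0.5962,
            owsa_low=0.07, owsa_high=0.64, distribution=beta(1.82, 1.4323),
        ),
    )
    tariff = ParameterSpec(
        name="change_tariff", role=Role.CHANGE_TARIFF, baseline=_TARIFF_BASELINE,
        owsa_low=9.14, owsa_high=14.44,
        distribution=gamma(_TARIFF_THETA, tariff_kappa),
    )
    return Scenario(
        intervention=ha, comparator=silver, change_tariff=tariff,
        horizon_weeks=12, currency_label="2021 Euro",
    )
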