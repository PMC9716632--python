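"""Probabilistic sensitivity analysis: Monte-Carlo propagation, CE plane, CEAC.

Parameter uncertainty is propagated by sampling every model input from its
assigned distribution — gamma for prices (support > 0), binomial for weekly
unit counts (discrete, bounded), beta for healing probabilities — and
re-rolling the decision tree per iteration. One *shared* change-tariff draw
per iteration feeds both arms; all other draws are independent (no
correlation structure is modelled).

From the iteration-level (cost, effect) pairs two standard summaries are
derived:

* the cost-effectiveness plane — the per-iteration (ΔE, ΔC) scatter, and
* the cost-effectiveness acceptability curve (CEAC) — for each
  willingness-to-pay λ on a grid, the share of iterations in which the
  intervention has the higher net monetary benefit λ·E − C. Exact NMB ties
  (which occur with positive probability at λ = 0 when both arms draw zero
  units) are split half/half so the two curves stay complementary.

All draws come from a single seeded ``numpy.random.Generator`` in a fixed
documented order (intervention price, units, healing; comparator price,
units, healing; tariff), so identical (scenario, n, seed) gives identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import DistributionSpec, Family, Scenario

__all__ = [
    "PsaIteration",
    "PsaResult",
    "CeacPoint",
    "CeacCurve",
    "sample_parameter",
    "distribution_mean",
    "moment_match_gamma",
    "run_psa",
    "ce_plane",
    "ceac",
    "DEFAULT_WTP_GRID",
]

#: Default willingness-to-pay grid: 0 to 10,000 in steps of 100.
DEFAULT_WTP_GRID = tuple(range(0, 10001, 100))


def _sample(spec: DistributionSpec, rng: np.random.Generator, size: int | None):
    fam, p = spec.family, spec.params
    if fam is Family.GAMMA:
        theta, kappa = p
        return rng.gamma(shape=kappa, scale=theta, size=size)
    if fam is Family.BINOMIAL:
        n, prob = p
        return rng.binomial(int(n), prob, size=size)
    if fam is Family.BETA:
        return rng.beta(p[0], p[1], size=size)
    if fam is Family.FIXED:
        return p[0] if size is None else np.full(size, p[0])
    raise ValueError(f"unknown distribution family: {fam}")


def sample_parameter(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """One draw from a parameter's PSA distribution.

    Gamma uses (scale=theta, shape=kappa), mean kappa·theta; binomial returns
    an integer in [0, n]; beta lies in [0, 1]; fixed returns the point value.
    """
    return float(_sample(spec, rng, None))


def distribution_mean(spec: DistributionSpec) -> float:
    """Analytic mean: gamma κθ, binomial np, beta α/(α+β), fixed its value."""
    fam, p = spec.family, spec.params
    if fam is Family.GAMMA:
        return p[0] * p[1]
    if fam is Family.BINOMIAL:
        return p[0] * p[1]
    if fam is Family.BETA:
        return p[0] / (p[0] + p[1])
    if fam is Family.FIXED:
        return p[0]
    raise ValueError(f"unknown distribution family: {fam}")


def moment_match_gamma(mean: float, theta: float) -> DistributionSpec:
    """Gamma spec with scale ``theta`` and shape ``mean/theta``, so the
    distribution mean equals ``mean``; used to repair or construct price
    distributions from a target mean and a dispersion scale."""
    if mean <= 0 or theta <= 0:
        raise ValueError("mean and theta must be > 0")
    return DistributionSpec(family=Family.GAMMA, params=(theta, mean / theta))


@dataclass(frozen=True)
class PsaIteration:
    """One Monte-Carlo replication: the sampled inputs and both valuations."""

    index: int
    draws: dict[str, float]
    intervention_cost: float
    intervention_effect: float
    comparator_cost: float
    comparator_effect: float


@dataclass(frozen=True)
class CeacPoint:
    wtp: float
    probability_intervention: float
    probability_comparator: float


@dataclass(frozen=True)
class CeacCurve:
    """CEAC sampled on a willingness-to-pay grid; rows sum to 1 by tie-splitting."""

    points: tuple[CeacPoint, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wtp": [p.wtp for p in self.points],
                "p_intervention": [p.probability_intervention for p in self.points],
                "p_comparator": [p.probability_comparator for p in self.points],
            }
        )

    def at(self, wtp: float) -> CeacPoint:
        for p in self.points:
            if p.wtp == wtp:
                return p
        raise KeyError(f"wtp {wtp} not on the evaluated grid")


@dataclass(frozen=True)
class PsaResult:
    """Container for a full PSA run; see :func:`run_psa`.

    ``frame`` holds one row per iteration: every sampled parameter (named as
    in ``Scenario.parameter_map``), both arms' cost and effect, and the
    incremental columns ``delta_cost``/``delta_effect``.
    """

    scenario: Scenario
    frame: pd.DataFrame = field(repr=False)
    n_iterations: int
    seed: int | None

    @property
    def iterations(self) -> list[PsaIteration]:
        names = list(self.scenario.parameter_map())
        out = []
        for d in self.frame.to_dict("records"):
            out.append(
                PsaIteration(
                    index=int(d["iteration"]),
                    draws={n: d[n] for n in names},
                    intervention_cost=d["cost_intervention"],
                    intervention_effect=d["effect_intervention"],
                    comparator_cost=d["cost_comparator"],
                    comparator_effect=d["effect_comparator"],
                )
            )
        return out

    def ce_plane(self) -> pd.DataFrame:
        return ce_plane(self)

    def ceac(self, wtp_grid: Sequence[float] = DEFAULT_WTP_GRID) -> CeacCurve:
        return ceac(self, wtp_grid)

    def summary(self) -> str:
        f = self.frame
        share_dominant = float(((f["delta_cost"] <= 0) & (f["delta_effect"] >= 0)).mean())
        lines = [
            f"PSA: {self.n_iterations} iterations, seed={self.seed}",
            f"mean cost   {self.scenario.intervention.name}: {f['cost_intervention'].mean():.2f}"
            f"   {self.scenario.comparator.name}: {f['cost_comparator'].mean():.2f}",
            f"mean effect {self.scenario.intervention.name}: {f['effect_intervention'].mean():.4f}"
            f"   {self.scenario.comparator.name}: {f['effect_comparator'].mean():.4f}",
            f"share of iterations with intervention dominant: {share_dominant:.4f}",
        ]
        return "\n".join(lines)


def run_psa(
    scenario: Scenario,
    n_iterations: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> PsaResult:
    """Monte-Carlo PSA: ``n_iterations`` independent replications.

    Per iteration each arm's unit price, weekly units and healing rate are
    drawn independently, plus one shared change-tariff draw applied to both
    arms; the tree is rolled back with those values.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = n_iterations
    draws: dict[str, np.ndarray] = {}
    for arm in scenario.arms:
        for spec in (arm.unit_price, arm.units_per_week, arm.healing_rate):
            draws[spec.name] = np.asarray(_sample(spec.distribution, rng, n), dtype=float)
    tariff_name = scenario.change_tariff.name
    draws[tariff_name] = np.asarray(_sample(scenario.change_tariff.distribution, rng, n), dtype=float)

    horizon = scenario.horizon_weeks
    arm_cols = {}
    for label, arm in (("intervention", scenario.intervention), ("comparator", scenario.comparator)):
        cost = horizon * draws[arm.units_per_week.name] * (
            draws[arm.unit_price.name] + draws[tariff_name]
        )
        arm_cols[f"cost_{label}"] = cost
        arm_cols[f"effect_{label}"] = draws[arm.healing_rate.name]

    frame = pd.DataFrame({"iteration": np.arange(n), **draws, **arm_cols})
    frame["delta_cost"] = frame["cost_intervention"] - frame["cost_comparator"]
    frame["delta_effect"] = frame["effect_intervention"] - frame["effect_comparator"]
    return PsaResult(
        scenario=scenario,
        frame=frame,
        n_iterations=n,
        seed=seed if isinstance(seed, int) else None,
    )


def ce_plane(psa: PsaResult) -> pd.DataFrame:
    """Per-iteration (ΔE, ΔC) points of the cost-effectiveness plane."""
    if len(psa.frame) == 0:
        raise ValueError("empty PSA")
    return psa.frame[["iteration", "delta_effect", "delta_cost"]].copy()


def ceac(psa: PsaResult, wtp_grid: Sequence[float] = DEFAULT_WTP_GRID) -> CeacCurve:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    At each λ: probability the intervention is cost-effective =
    (#{NMB_i > NMB_c} + ½·#{ties}) / n; the comparator gets the complement.
    """
    if len(psa.frame) == 0:
        raise ValueError("empty PSA")
    grid = np.asarray(list(wtp_grid), dtype=float)
    if len(grid) == 0:
        raise ValueError("empty willingness-to-pay grid")
    if np.any(grid < 0):
        raise ValueError("willingness-to-pay values must be >= 0")

    f = psa.frame
    ci = f["cost_intervention"].to_numpy()
    ei = f["effect_intervention"].to_numpy()
    cc = f["cost_comparator"].to_numpy()
    ec = f["effect_comparator"].to_numpy()
    # NMB_i > NMB_c  <=>  λ·ΔE − ΔC > 0
    margin = grid[:, None] * (ei - ec)[None, :] - (ci - cc)[None, :]
    n = margin.shape[1]
    p_i = (np.count_nonzero(margin > 0, axis=1) + 0.5 * np.count_nonzero(margin == 0, axis=1)) / n
    points = tuple(
        CeacPoint(wtp=float(w), probability_intervention=float(p), probability_comparator=float(1 - p))
        for w, p in zip(grid, p_i)
    )
    return CeacCurve(points=points)
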