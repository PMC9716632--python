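# Methods

## Model structure and assumptions

The model is a two-strategy, single-period decision tree. One decision node
selects the dressing strategy (hyaluronic acid vs silver-containing
hydrofiber); per strategy one chance node resolves complete wound healing
at the end of a fixed horizon (default 12 weeks). Rolling the tree back,
the expected effectiveness of a strategy is its healing probability, and
its expected cost is

    cost = horizon_weeks × units_per_week × (unit_price + change_tariff).

Assumptions baked into that formula:

* **One billed change per applied unit.** Each dressing unit applied
  implies one home-care dressing-change visit, so the unit price and the
  change tariff are coupled through the same weekly utilisation count.
  This is the unique costing rule that reproduces the built-in scenario's
  published totals (749.80 € and 883.05 €) from its inputs:
  12 × 2 × (19.075 + 12.1667) and 12 × 2 × (24.627 + 12.1667).
* **Cost independent of outcome.** Both the healed and the unhealed branch
  accrue the full-horizon cost; healing time within the horizon is not
  modelled. This matches the payer data available (no time-to-heal cost
  evidence) and tends to overstate the cost of the faster-healing arm.
* **No discounting.** The horizon is under a year.
* **Only dressing and change costs.** Adverse events, other resource use,
  and costs of the underlying disease are out of scope.

Arithmetic is carried at full double precision; rounding (2 dp for costs,
4 dp for rates) happens only in report columns and summaries. The ICER is
computed from unrounded ΔC and ΔE — computing −133.248/0.010600 gives the
reported −12,570.57, whereas dividing the already-rounded −133.25 would
give −12,570.75. Negative ICERs are reported but always accompanied by the
dominance quadrant, which is what decisions rest on.

## Parameters and the built-in scenario

Every input is a `ParameterSpec` with a baseline (base case), an OWSA range
and a PSA distribution. The built-in scenario (2021 Euro):

| parameter | baseline | OWSA | PSA |
|---|---|---|---|
| HA unit price | 19.0750 | ±5% | gamma(θ=0.0477, κ=400) |
| Silver unit price | 24.6270 | ±5% | gamma(θ=0.0616, κ=400) |
| HA units/week | 2 | 2–3 | binomial(8, 0.18) |
| Silver units/week | 2 | 2–5 | binomial(8, 0.23) |
| HA 12-week healing | 0.6068 | 0.24–0.96 | beta(2.03, 1.2960) |
| Silver 12-week healing | 0.5962 | 0.07–0.64 | beta(1.82, 1.4323) |
| change tariff (shared) | 12.1667 | 9.14–14.44 | gamma(θ=0.5264, κ — see below) |

Gamma parameters are read as (scale θ, shape κ): with that convention the
price means κθ (19.08 and 24.64) agree with the baselines, which pins the
parameterisation. The HA healing baseline is the pooled count 125/206 =
0.6068 from the underlying meta-analysis; `healing_rate_from_counts` also
documents the silver pooled count 148/254 = 0.5827, although the scenario's
silver baseline is 0.5962 as analysed in the source tables (the two are
not reconciled there; the scenario preserves the analysed value).

**Change-tariff repair.** The source's printed tariff gamma (θ=0.5264,
κ=213.55) has mean 112.4 under any parameter ordering, irreconcilable with
its baseline 12.1667 — an apparent misprint. The default
(`tariff_gamma="moment_matched"`) keeps the printed scale θ=0.5264 and sets
κ = 12.1667/0.5264 ≈ 23.113 so the mean equals the baseline, preserving the
printed dispersion scale while honouring the baseline; `as_printed` uses
the literal parameters. Both modes are exposed in the library, the CLI
(`--tariff-gamma`) and the run manifest.

Note the binomial PSA means (8×0.18 = 1.44, 8×0.23 = 1.84) are below the
baseline counts of 2 — the built-in scenario is preserved as analysed,
without recalibration, so PSA mean costs sit below base-case costs.

## One-way sensitivity analysis

Each parameter in turn is set to its low and high bound, all others at
baseline (exactly one parameter off-baseline per evaluation). The tornado
outcome is the **incremental net monetary benefit** of the intervention,
λ·ΔE − ΔC, at a configurable reference willingness-to-pay λ (default 0,
where it reduces to −ΔC). The ICER is unusable as a tornado axis here: the
healing-rate ranges flip the sign of ΔE and send the ratio through ±∞. Two
consequences users should expect at λ = 0: healing-rate bars have zero
width (they do not touch cost), and the shared change tariff cancels from
ΔC whenever both arms share the same baseline utilisation. Tornado rows
sort by descending outcome range, ties broken lexicographically by name.

## Probabilistic sensitivity analysis

A Monte-Carlo simulation (default 10,000 replications) draws, per
iteration, each arm's unit price, weekly unit count and healing rate
independently, plus **one shared change-tariff draw** applied to both arms
(it is a single model parameter). No correlation structure is imposed.
Binomial draws of 0 units are retained as zero-cost weeks; excluding them
would bias the mean away from np. A single seeded
`numpy.random.Generator` drives all draws in a fixed order (intervention
price, units, healing; comparator price, units, healing; tariff — each as
a length-n vector), so identical (scenario, n, seed) reproduces outputs
byte-for-byte; bit-identity across numpy versions or other implementations
is not claimed.

The CEAC evaluates, per λ on a grid (default 0–10,000 € in steps of 100),
the share of iterations where NMB_intervention > NMB_comparator; exact ties
— which occur with positive probability at λ = 0 when both arms draw zero
units — count half to each side, keeping the two curves complementary.

At seed 1 and n = 10,000 the built-in scenario gives an HA acceptability
of 0.706 at λ = 0, levelling off to 0.592 at λ = 10,000 (the test suite
and `scripts/acceptance.py` recompute these).

## Synthetic scenarios

`woundcea.synthetic.generate_scenario` produces random valid scenarios
whose PSA distributions are *moment-matched* to their baselines (gamma
prices with mean = baseline, binomial with np = baseline count, beta with
mean = baseline rate), unlike the built-in scenario. By independence,

    E[cost] = horizon · E[units] · (E[price] + E[tariff]),

so expected costs are available in closed form (`analytic_expected_cost`)
and parameter-recovery and convergence tests have exact oracles.
`degenerate_scenario` builds point-mass scenarios hitting prescribed
(cost, effect) pairs exactly — the brute-force oracle for CEAC values of
1, 0 and ½ under strict dominance, strict domination and exact ties.

What the generator emulates: the *shape* of the decision problem (two
arms, linear costing, bounded probabilities, the four distribution
families). What it does not: real-world correlation between price and
utilisation, time-to-heal dynamics, adverse-event costs, or the built-in
scenario's deliberate baseline/PSA-mean mismatch. Passing tests on
synthetic scenarios therefore validate the pipeline's arithmetic and
statistics, not the clinical realism of any particular input set.

## Numerical and design choices

* Problem sizes: statistical tests use n = 10⁵ draws (mean-recovery within
  3.29 SE, ≈99.9% pass rate at fixed seeds; cost convergence within 1%
  relative); reproduction runs use the analysis' own n = 10,000.
* OWSA ranges given as ±percentages are materialised to absolute bounds at
  load time; the JSON round trip writes absolute bounds.
* CSV exports are locale-independent (UTF-8, comma delimiter, period
  decimal point) at full float precision; re-reading requires
  `float_precision="round_trip"` (pandas' default parser can be one ulp
  off), which `woundcea.report.read_table` applies.
* `psa`/`ceac` CLI commands require `--seed`: no silent nondeterminism.
* Validation is fail-fast at load: distribution-parameter domains, OWSA
  ranges bracketing baselines, probabilities in [0, 1], exactly two
  strategies.

## JSON scenario schema

Top level: `currency` (string), `horizon_weeks` (int ≥ 1), `strategies`
(array of exactly 2, first = intervention), `change_tariff`. Each strategy
has `name`, `unit_price`, `units_per_week`, `healing_rate`; each parameter
object is

```json
{"baseline": 19.075,
 "owsa": {"low": 18.12, "high": 20.03},   // or {"pct": 5}
 "dist": {"family": "gamma", "params": [0.0477, 400]}}
```

with families `gamma` (θ, κ), `binomial` (n, p), `beta` (α, β), `fixed`
(value). `owsa` defaults to the baseline (zero-width range) and `dist` to a
point mass at the baseline when omitted.

## Limitations

Two strategies only; no Markov/state-transition structure, per-week healing
dynamics, QALYs or cost-utility, extended dominance or efficiency
frontiers, correlated sampling, or value-of-information analysis. The
tornado's bar values depend on the chosen reference λ; only the ranking at
λ = 0 is anchored to the source analysis.
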