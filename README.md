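# woundcea

Decision-analytic cost-effectiveness analysis of chronic-wound dressing
strategies from a payer (German statutory health insurance) perspective.

Chronic wounds are typically managed by ambulatory care services that visit
patients and change dressings several times a week. Comparing an active
dressing such as hyaluronic acid (HA) against the standard of care
(silver-containing hydrofiber) therefore comes down to two quantities per
strategy over a 12-week horizon: the expected dressing cost and the
probability of complete wound healing. `woundcea` implements the full
pipeline for that comparison: deterministic decision-tree rollback,
incremental analysis with dominance classification, one-way deterministic
sensitivity analysis (tornado), and probabilistic sensitivity analysis with
cost-effectiveness acceptability curves.

## Model

A two-strategy decision tree: a decision node chooses the dressing, a
chance node per arm resolves complete healing at 12 weeks. With each
applied dressing unit implying one billed dressing change,

```
cost_s   = H · u_s · (p_s + c)          (H = horizon in weeks, u = units/week,
effect_s = π_s                           p = unit price, c = change tariff,
                                         π = 12-week complete-healing probability)
```

Incremental quantities for intervention *i* vs comparator *j*:

```
ΔC = C_i − C_j,   ΔE = E_i − E_j,   ICER = ΔC / ΔE   (ΔE ≠ 0)
NMB_s(λ) = λ · E_s − C_s            (λ = willingness to pay per healed patient)
```

A strategy is *dominant* when ΔC ≤ 0 and ΔE ≥ 0 with at least one strict.
The PSA draws prices from gamma, weekly unit counts from binomial, and
healing probabilities from beta distributions; the CEAC reports, per λ, the
share of Monte-Carlo iterations in which a strategy has the higher NMB
(exact ties split half/half).

## Worked example

```python
from woundcea import DecisionTreeCEA

model = DecisionTreeCEA.from_builtin()   # built-in HA vs silver scenario
print(model.fit().summary())
```

```
strategy            cost   healing rate
HA                749.80         0.6068
Silver            883.05         0.5962

incremental cost:    -133.25
incremental healing: 0.0106
ICER:                -12,570.57
dominance:           intervention_dominant
```

HA costs 133.25 € less over 12 weeks and heals 1.06 percentage points more
patients, so it dominates; the negative ICER is reported but the decision
rests on the dominance label. Propagating parameter uncertainty:

```python
psa = model.psa(n_iterations=10_000, seed=1)
curve = psa.ceac()
print(curve.at(0).probability_intervention, curve.at(10_000).probability_intervention)
# 0.7062 0.5923
```

i.e. HA is cost-effective in ~71% of iterations at a willingness to pay of
0 € (pure cost minimisation), levelling off near 59% at 10,000 € per
additional healed patient.

The same stages are available from the shell:

```
wound-cea base-case --outdir out
wound-cea owsa --outdir out
wound-cea ceac --seed 1 --iterations 10000 --outdir out
wound-cea demo --seed 5 --outdir out      # synthetic scenario, full pipeline
```

Each run writes CSV tables (`base_case.csv`, `owsa.csv`, `psa_samples.csv`,
`ce_plane.csv`, `ceac.csv`) and a `manifest.json` that fully determines the
outputs. Custom scenarios are single JSON documents (schema in
`docs/methods.md`) passed with `--config`.

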