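# gdmcost

A decision-analytic model of the **short-term healthcare costs of maternal
overweight, gestational diabetes mellitus (GDM), and related macrosomia**,
for health economists and HTA analysts who want a transparent, scriptable
version of the perinatal cost framework: cohort decision trees for the
pregnancy/delivery period, a Markov engine for post-delivery follow-up,
national budget-impact analysis, and one-way deterministic sensitivity
analysis — parameterized out of the box with published complication
probabilities and 2011 USA unit costs.

## The model

Each pregnancy arm (normal, GDM, overweight) is a decision tree whose
expected per-case cost is the probability-weighted sum of accumulated costs
over all root-to-leaf paths (conventional rollback):

```
E[C] = Σ_paths  (Π_edges p) · (Σ_edges c + payoff),
```

with costs carried as mother/child pairs in USD. In **mechanistic** mode the
trees are wired from marginal complication probabilities and unit costs, so
`E[C] = routine + Σ_k p_k·c_k`; in **calibrated** mode (the default) each
arm is pinned to its published per-case breakdown. The budget impact chains

```
pregnancies = population × rate/1000
cases       = pregnancies × incidence
BIA         = cases × (E[C_condition] − E[C_normal])
```

and the sensitivity analysis perturbs incidence, the condition arm's total
cost, the routine normal-pregnancy cost, and the mother/child complication
components by ±20% each, one at a time.

## Worked example

```python
>>> import gdmcost as g
>>> cfg = g.builtin_pilot_parameters()        # 2011-USA pilot parameters
>>> gdm = g.build_arm("gdm", cfg)             # calibrated GDM arm
>>> normal = g.build_arm("normal", cfg)
>>> b = g.per_case_cost(gdm)
>>> (b.mother, b.child, b.total)
(11794.0, 3799.0, 15593.0)
>>> g.incremental_cost(gdm, normal)
7803.0
>>> r = g.compute_budget_impact(cfg, gdm, normal)
>>> r.annual_cases_display
236139
>>> round(r.annual_budget_impact)
1842591517
```

A GDM pregnancy/delivery costs an expected $15,593 ($11,794 maternal,
$3,799 neonatal) against $7,790 for a normal pregnancy — an incremental
$7,803 per case. At 13.68 pregnancies per 1,000 in a population of
313,847,500 and a 5.5% GDM incidence, that is 236,139 GDM cases per year
and an annual national burden of about **$1.84 billion**, short-term
obstetric costs only.

The same pipeline from a shell:

```sh
gdmcost evaluate                      # per-arm mother/child/total table
gdmcost bia --arm gdm                 # national budget impact
gdmcost sensitivity --deltas -0.2,0.2 # one-way sensitivity table
gdmcost pilot                         # everything above in one report
```

Reports are JSON (or CSV with `--format csv`), embed a run manifest
(config checksum, flags, software version), and are byte-identical across
runs up to the manifest timestamp.

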