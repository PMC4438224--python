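# Methods

## Scope and perspective

`gdmcost` estimates the direct short-term (pregnancy + delivery) healthcare
costs of maternal overweight/obesity and gestational diabetes mellitus
(GDM), including the complications of the related macrosomic birth, from a
national payer perspective. Costs of diagnosing or managing GDM itself,
long-term sequelae (maternal type 2 diabetes, childhood obesity), utilities
and QALYs, and intervention costs are all out of scope: the model prices
complication events only, on top of a routine pregnancy/delivery cost.

## Cohort decision trees

Each pregnancy arm — `normal`, `gdm`, `overweight` — is a decision tree
evaluated by expected-value rollback. The engine supports chance nodes
(branch probabilities summing to 1 within 1e-9), decision nodes (which
require an explicit arm selection; the model never auto-optimises, since the
delivery-strategy comparison it ships is descriptive), and terminal nodes.
Costs are mother/child pairs in USD and accrue both on edges and terminal
payoffs. Trees may share subtrees (DAG shape; rollback is memoized) but
must be acyclic. Serialized trees (JSON/YAML, `schema_version: 1`) may mark
one branch of a chance node `"complement"`; it resolves at load time to one
minus the sum of its siblings, because the source tables list event
probabilities only, never the residual no-event branch.

An exhaustive path-enumeration oracle recomputes every rollback value as
Σ (Π p)·(Σ c) over root-to-leaf paths; the two routes agree within 1e-9 on
200 seeded random trees in the test suite, and path probabilities conserve
to 1. Enumeration refuses trees beyond 10^6 paths.

### Calibrated vs mechanistic arms

The published description of the tree names the complication sets but not
the exact wiring, and the published per-case totals cannot be derived from
the probability and cost tables alone. The package therefore ships two arm
modes:

* **calibrated** (default): the arm's tree is pinned to the published
  per-case breakdown — normal $7,790/$0, GDM $11,794/$3,799, overweight
  $13,047/$5,243 — so the budget-impact and sensitivity pipelines reproduce
  the published base case exactly. The routine cost still accrues on the
  tree's edge, with the excess on the terminal payoff.
* **mechanistic**: complications are modeled as independent events whose
  expected costs add, `E[C] = routine + Σ p·c`, wired as a linear chain of
  chance nodes (event / no-event, rejoining) so that every complication
  combination is still a distinct enumerable path. Independence is the
  minimal assumption consistent with the marginal probabilities the sources
  publish, and any tree wiring with the same marginals has the same
  expectation. Mechanistic GDM totals ≈ $15,486 — close to, but not equal
  to, the calibrated $15,593, which is why calibrated mode is the default
  for reproduction work.

The GDM arm uses the usual-care (untreated) trial probabilities — the
conservative reading — and the overweight arm the obese-registry
probabilities. The child cost component is an average over all births in
the arm, not conditional on macrosomia (calibrated mode is agnostic to this
reading). The overweight arm does not nest a GDM sub-branch by default;
`options.gdm_given_overweight` adds one with a user-supplied conditional
incidence.

## Parameters

All parameters live in one validated YAML bundle
(`gdmcost/data/us_2011_pilot.yaml`, `schema_version: 1`); percentages may
carry a `%` suffix and are converted to proportions at load time; unknown
keys are rejected. The canonical complication vocabulary is the cost
table's 28 item names (e.g. `Child_hyperbili`, `Mother_pre eclampsia`);
`params.OUTCOME_ALIASES` maps study outcome labels onto them. Zero-cost
items (anemia, stillbirth, hydramnion, weight gain, body mass) stay in the
vocabulary so the events remain representable. Eclampsia has no dedicated
cost item and is costed as pregnancy-induced hypertension ($19,184), the
closest severe hypertensive-disorder item; insulin-treated and other
diabetes in pregnancy are costed as GDM management ($1,786).

Choices where the sources were ambiguous or silent:

* **Statistical significance** flags are stored as metadata only;
  non-significant point estimates enter unchanged (conservative
  point-estimate approach, no CI weighting).
* **Treatment-effect odds ratios** (macrosomia OR 0.38 treated vs usual
  care, etc.) are shipped but not applied in the base case — the trial
  already provides both arms' probabilities, and applying the OR on top
  would double-count the effect. `or_to_probability(b, OR) =
  OR·b/(1−b+OR·b)` makes them usable as an opt-in transformation.
* **Shoulder dystocia**: a cohort source reports a "much higher"
  probability than the trial's 4.0% but prints no number;
  `options.shoulder_dystocia_override` defaults to unset rather than an
  invented value.
* **Perinatal mortality** is cited as an input without a printed value and
  defaults to 0. Stillbirth/IUFD enter as cost events only; no life-years
  are computed.

## Markov follow-up engine

Post-delivery follow-up is a generic discrete-time cohort Markov process:
occupancy at cycle t is `initial @ T^t`; cumulative cost is
`Σ_t occ_t·c / (1+r)^t` over cycles 0…n−1, with a half-cycle-correction
flag (default off) and defaults of 1-year cycles and 0% discounting. The
source framework names the Markov process but reports no long-term results
and no states, so the engine stays generic and no long-term cost is
reproduced; a 2-state healthy→diabetic chain (4%/year, ≈50% converted by
year 17) serves as a plausibility fixture in the tests, not as a target.

## Budget impact and sensitivity

Budget impact is bilinear: `BIA = population × rate/1000 × incidence ×
(E[C_cond] − E[C_ref])`. Case counts stay real-valued internally
(236,138.859 for the built-in parameters) and round half-away-from-zero
only for display (236,139) — the published sensitivity values are only
consistent with unrounded intermediates. All rounding anywhere in the
package follows that convention and happens at reporting time only.

The one-way analysis perturbs five parameters by ±20% (arbitrary deltas
allowed): incidence (per-case unchanged, BIA scales exactly),
condition-arm total cost, routine normal-pregnancy cost (reference arm
only — note this parameter is *inversely* related to the incremental cost,
so its +20% scenario lowers the BIA), and the child / mother complication
components of the condition arm. `tornado_order` ranks parameters by
|BIA(+δ) − BIA(−δ)|, ties alphabetical.

### Known discrepancies in the published sensitivity table

Computed from the printed per-case values, the base BIA is
$1,842,591,517; the published table's base cell ($1,842,525,634) implies
an unrounded per-case incremental of ≈$7,802.72 that is never printed
(3.6×10⁻⁵ relative difference — documented, not matched). The +20%
condition-cost cell rounds to $10,922 from printed inputs where the table
prints $10,921. The published "cost normal pregnancy" per-case cells match
±20% scaling of the *incremental* cost rather than of the normal cost, and
the "baby" and "mother" blocks match each other's labels (component
scaling puts $7,043/$8,563 on the child side and $5,444/$10,162 on the
mother side); the package keeps the literal parameter semantics and
reproduces the internally consistent cells.

## Numerical and reporting conventions

Internal arithmetic is full double precision; whole-dollar rounding
(half-away-from-zero) applies only at display. Machine reports (JSON/CSV)
carry raw numbers; thousands separators appear only in human-readable log
lines. Every CLI report embeds a run manifest (config SHA-256, command,
flags, schema and software versions, timestamp); identical inputs give
byte-identical report bodies apart from the timestamp.

## What the tests do and do not show

The test suite verifies the arithmetic fabric (rollback vs enumeration,
conservation, linearity, closed-form Markov agreement, bilinearity) and
exact reproduction of the published base case, budget impact, and the
internally consistent sensitivity cells. The random-tree generator covers
engine correctness, not clinical realism; nothing in the suite validates
the epidemiological inputs themselves, their transferability outside the
2011 USA setting, or any long-term outcome — the published framework
explicitly cautions against extrapolating the cost results to other
countries.
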