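# Methods

## The model

`floodbn` evaluates the mental-health impact of flood interventions with a
discrete Bayesian network (BN). A BN over categorical variables
X₁…Xₙ is a pair **B = {G, θ}**: a directed acyclic graph G and one
conditional probability table (CPT) per variable, defining the joint
distribution

P(X₁,…,Xₙ) = ∏ᵢ P(Xᵢ | pa(Xᵢ)).

The packaged network has five binary nodes (states `present`/`absent`):

```
Flood ──▶ LOSI ──▶ PPD ──▶ Lsever
                      └──▶ Msever
```

* **Flood** — exposure to flooding (prevalence 20.1%).
* **LOSI** — loss of sentimental items, a secondary stressor (62%).
* **PPD** — probable depression (18.6%).
* **Lsever / Msever** — less- and more-severe depression (48.3% / 21.1%).

Severity is two separate binary nodes, not one three-state node, because the
two severity states may overlap within an individual. Two further
quantities, CU (change in utility) and CQALY (change in QALYs), are
deterministic arithmetic downstream of the network — they carry no CPTs and
are computed by `flood_model`, not by inference.

## Marginal-to-conditional calibration

The elicited inputs are *marginal* prevalences, which do not determine the
conditional tables. `build_flood_network` processes nodes in topological
order and solves each child's conditional rows against the joint
distribution of its already-calibrated parents. The residual degree of
freedom is fixed by a **risk ratio** r (default 2.0): the probability of
`present` in a parent configuration is proportional to r^(number of
`present` parents), scaled so the child's marginal matches its elicited
value exactly.

The default r = 2.0 is *infeasible* for LOSI: with a 62% marginal and a
20.1% exposure prevalence, a doubled risk among the flooded would require a
conditional probability of 1.032. The calibration therefore water-fills:
rows that would exceed 1 are clamped at 1 (for LOSI this is equivalent to
the maximum feasible ratio ≈ 1.907) and the remaining rows are re-solved,
with a warning logged. The elicited marginal is always honored to machine
precision; only the dependence strength is capped. All five marginals hold
simultaneously because each child is calibrated against its parents' exact
joint distribution.

Consequence worth knowing: in the default network, every flooded individual
loses sentimental items with probability 1. Pass a smaller `risk_ratio`
(anything ≤ 1.9) to `FloodNetworkConfig` for a non-degenerate table.

## Inference

Posterior queries use exact variable elimination with min-degree ordering
(ties broken lexicographically). The network is seven factors at most, so
junction trees would add machinery without benefit. The posterior is
provably invariant to the elimination order; the test suite checks this and
checks equality with brute-force joint-table conditioning on random
networks of up to 8 binary nodes.

Evidence with probability zero raises `InconsistentEvidenceError` rather
than returning NaNs. Querying a variable that is itself observed returns a
point mass on the observed state.

`backpropagate_to_roots` ranks root nodes by how much observed downstream
evidence shifts them: shift = maxₛ |P(root = s | evidence) − P(root = s)|.
The "most influential risk factor" notion has no canonical metric; the
max-state absolute probability shift is this package's documented choice
(it is symmetric in states and bounded in [0, 1]).

## Learning

* **Parameters.** `fit_cpts` uses complete-data maximum likelihood with an
  optional Dirichlet pseudocount: entry = (count + c) / (total + c·r),
  r = child cardinality. Default c = 1 (Laplace) for CLI use; c = 0 gives
  exact relative frequencies, with never-observed parent rows falling back
  to uniform (logged). Missing-data EM is out of scope.
* **Structures.** BIC = log L̂ − (k/2)·ln N, with k the number of free CPT
  parameters. BIC was chosen over marginal-likelihood scores because it has
  no hyperparameters and is exactly reproducible. It decomposes over node
  families, so `hill_climb_structure` (greedy add/delete/reverse moves,
  lexicographic tie-break, parent-count cap) rescores only the touched
  families per move. The search is deterministic; its `seed` argument is
  accepted for signature stability and unused.
* **DAG space.** `count_dags` implements the alternating-sum recurrence for
  the number of labeled DAGs (1, 3, 25, 543, 29281, …), verified against
  brute-force enumeration for p ≤ 4. It documents why exhaustive search is
  impossible and greedy search is used.

## QALYs and cost-effectiveness

Utility weights (0–1 scale, 1 = full health) for the three mental-health
states come from elicited Beta distributions:

| state     | utility mean | Beta(α, β)  | CU = 0.85 − mean |
|-----------|--------------|-------------|------------------|
| Remission | 0.85         | Be(923,163) | 0 (reference)    |
| Lsever    | 0.60         | Be(182,122) | 0.25             |
| Msever    | 0.42         | Be(54,75)   | 0.43             |

`UtilityTable` enforces |Beta mean − printed mean| < 0.005. Over a one-year
horizon, CQALY = CU × horizon × (probability weight). The default pathway
formula implemented by `compute_cqaly` is

CQALY_state = P(state = present ∧ LOSI = present | Flood = present) × CU_state × horizon,

i.e. the utility loss weighted by the probability, among flooded
individuals, of both losing sentimental items and being in the state. **This
formula is one documented reading of the pathway, not a reproduction of the
published scenario values**: the published before/after CQALYs (0.055/0.062
before, 0.033/0.038 after the early-warning intervention) are not derivable
from the stated inputs by any obvious combination, so they are treated as
authoritative printed inputs and shipped verbatim in `scenario_ews.json`.
Everything downstream of them is exact arithmetic:

ΔQALY = CQALY_before − CQALY_after, value = ΔQALY × threshold,

with the threshold defaulting to £20,000/QALY (the lower end of the NICE
£20,000–£30,000 range) and monetary reporting rounded to the nearest pound,
half away from zero. How an intervention alters the network is not
specified either, so scenarios accept explicit before/after forms — either
CQALY values or two network configurations.

## Probabilistic sensitivity analysis and EVPI

`run_psa` draws each state's utility from its Beta distribution (one seeded
`numpy` generator per run, state-major order), recomputes CU against the
sampled remission utility (floored at 0), and re-evaluates the intervention
per draw. The QALY change is linear in CU, so draws are scaled by
CU_draw / CU_mean with CU_mean computed at the **Beta means** (not the
printed 2-dp means): the draws are centered on the Beta means, so this
normalization makes the PSA mean converge to the deterministic result as
the Beta variances shrink — the convergence test would otherwise be off by
the printing error (e.g. 0.42 vs 54/129 = 0.4186).

EVPI uses the {intervene, do nothing} decision set at the scenario's
threshold: EVPI = E[max_d NB_d] − max_d E[NB_d] on common draws, per person,
nonnegative by construction. No population scaling or VoI time horizon is
applied (none is specified). With the packaged scenario the intervention's
net benefit is positive in essentially every draw, so the estimated EVPI is
£0 — there is no decision uncertainty to resolve at these inputs, only
parameter uncertainty.

## Synthetic survey records

No individual-level flooding-and-health dataset is distributed, so
`synthetic_data` forward-samples records from the model itself (ancestral
sampling in topological order, vectorized per node, byte-stable CSV
output). `make_survey_fixture` restricts to the five observable columns and
returns the generating network, enabling parameter-recovery tests.

What a green test does and does not establish: the generator reproduces the
elicited prevalences and the network's dependence structure, so recovery
and convergence tests validate the estimators *under the model*. Real
survey data would add covariates (age, sex, income), survey weights,
missingness and model misspecification, none of which are emulated; a green
suite says nothing about those.

## Numerical choices

* CPT rows must sum to 1 within 1e-9; loaders renormalize deviations up to
  1e-6 (elicited tables are printed to 1–3 significant figures) and refuse
  anything worse.
* Zero probabilities are permitted; 0/0 in downstream divisions is treated
  as 0 with a logged warning (unseen parent rows → uniform).
* Joint enumeration (the test oracle) is capped at 2²⁰ cells.
* Exhaustive DAG counting uses exact integer arithmetic, capped at p = 20.
* Monetary rounding: nearest pound, half away from zero, applied only at
  the reporting boundary.

## Known limitations

* Binary nodes only in the packaged model; the engine supports arbitrary
  categorical cardinalities but the flood calibration assumes binary
  children.
* Complete-data learning only; no EM, no missingness mechanisms.
* The risk-ratio completion is an assumption, not an elicited quantity;
  conclusions that depend on conditional (rather than marginal) structure
  should be checked across a range of `risk_ratio` values.
* EVPI is a basic two-option Monte-Carlo estimator; EVPPI and sample
  information are out of scope.
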