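# Methods

## Model and assumptions

The package works with steady-state stoichiometric models: a metabolite ×
reaction matrix S, flux bounds in mmol/gDW/h, and one GPR boolean rule per
reaction. Fluxes always satisfy S·v = 0; no kinetics, thermodynamics
beyond bounds, or regulation are modeled. Uptake is negative and secretion
positive on exchange reactions (reactions touching a single metabolite),
per SBML/FBC convention; the bundled toy fixtures write their boundary
reactions in the producing orientation for readability, which the
structural exchange detection handles identically.

### Isozyme enumeration

GPR rules are parsed by a recursive-descent parser (errors carry the
character position) and expanded into full disjunctive normal form: one
enzyme per minimal satisfying gene set, with duplicates and supersets
absorbed, sorted for order stability. Nested complexes-of-complexes
therefore flatten into plain gene sets. Nothing in the formalism
distinguishes "a complex of complexes" from its flattened form, so DNF is
the design choice here; rules whose redundant terms matter biologically
(they should not) would need a different enumeration. A knockout zeroes
exactly the enzymes whose gene set intersects the deleted genes; a
reaction is structurally dead only when all of its enzymes are zeroed.

### Reference estimation

The estimator minimizes the confidence-weighted squared MFA misfit plus
the expression-weighted squared enzyme contributions, subject to steady
state, model bounds, the capacity coupling −ΣW ≤ w ≤ ΣW on GPR reactions,
W ≥ 0, and physiology constraints. Choices the problem statement leaves
open, and what this package does:

- **Physiology as hard intervals.** Measured exchange rates and growth
  enter as bound intersections [value − ci, value + ci]; a chemostat
  dilution rate is an equality on biomass. This is the weakest faithful
  reading of "constrained by physiological measurements"; penalized
  deviations would need a weighting the data do not supply.
- **Complex expression = min over subunits** (limiting-subunit
  rationale). Missing genes and values below 1% of the profile median are
  floored so the reciprocal weights 1/Eₙ stay finite; confidence
  half-widths below 0.01 mmol/gDW/h are raised to 0.01.
- **W is nonnegative**; the symmetric capacity constraint then covers both
  directions of reversible reactions with a single contribution pool.
- **Growth enters only as a bound**, never as a least-squares residual.

The estimator is a ridge-type regularized least squares and therefore
*spreads* flux across parallel routes in proportion to expression. Two
consequences worth knowing: with a pinned uptake and expression
proportional to the true contributions the planted state is recovered
exactly (this is how the synthetic scenarios are constructed), and with
disproportionate expression the estimate is biased toward the
higher-expressed route by O(conf²/E) — a property of the objective, not a
solver artifact.

### Prediction

The predictor minimizes relative flux changes over J_act plus α times the
total latent contribution, under the capacity coupling on V, the γ·W cap
on active enzymes (omitted at γ = ∞), zeroed knocked-out enzymes, and
medium-edited bounds. Further choices:

- The latent sum runs over **all** pairs (j, n) with n ∉ N_act(j), for
  every GPR reaction — including reactions entirely inactive in the
  reference — reading the index set literally.
- The biomass reaction, when active in the reference, appears in the
  relative-change sum like any other reaction; the predictor never
  maximizes growth.
- Reactions below the activity threshold are excluded from J_act, which
  simultaneously prevents 1/w² weights from exploding.
- A knockout that only blocks growth reports growth 0 with status
  "optimal"; "infeasible" is reserved for genuinely empty constraint sets
  (e.g. a fixed chemostat growth rate that the crippled network cannot
  reach — the solver then reports whether dropping the growth equality
  restores feasibility).

### Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| α | penalty per mmol/gDW/h of latent contribution | 10 (tight) / 1 (relaxed) | published regime values |
| γ | cap multiplier on active-enzyme contributions | 1.1 (tight) / ∞ (relaxed) | γ ≥ 1; ∞ removes the cap |
| activity threshold | defines J_act, N_act | 1e-6 mmol/gDW/h | solver-noise scale, configurable |
| ROOM δ, ε | relative/absolute window half-widths | 0.03, 0.001 | the values published with ROOM |
| growth cutoff | no-growth call fraction of wild type | 5% | a declared convention; ties call "growth" |
| FVA objective slack | relative cap above the optimum | 1e-9 | plus 1e-9 absolute |

## Numerical choices

All QPs are convex. They are solved with scipy's `trust-constr` (SLSQP
fallback) and then **polished**: the active constraints at the approximate
optimum are re-solved as an equality-constrained KKT system, accepted only
if feasible and non-worsening. On the package's well-conditioned instances
this yields ~1e-12 relative objective accuracy and deterministic results;
the contract tested for is 1e-8 feasibility and 1e-6 relative objective.
Infeasibility is decided up front by a phase-1 LP (HiGHS), not inferred
from solver failure. Flux variability at the fixed optimum is a linear
objective under one convex quadratic cap; failed subproblems fall back to
the incumbent optimum, which is always feasible for the cap, giving a
conservative zero-width bound rather than a gap in the output. The ROOM
MILP uses `scipy.optimize.milp` with big-M windows clamped to the bounds
(windows that fall outside the bounds force their indicator on). FBA
breaks ties among alternate optima by minimizing Σv² at the fixed optimal
growth, making the reported vector deterministic.

Note that the FVA cap tolerance translates into range widths of order
sqrt(slack/curvature): on the diamond reference (curvature ≈ 200) the
"zero" widths come out around 1e-5, which is the expected scale, not
imprecision.

## Synthetic data and oracles

The toy generator defines the study conditions: planted fluxes satisfying
S·w = 0 exactly, MFA values equal to planted fluxes plus zero-mean
Gaussian noise (half-width 0.1 mmol/gDW/h), expression proportional to
planted contributions (latent genes get a small positive value, 0.5),
and physiology pinning the uptakes with zero half-width. Under these
conditions — and only under these conditions — noiseless recovery is
exact (see the bias discussion above). The latent and duplicated-path
topologies gate their bypass routes on a co-substrate whose uptake the
reference physiology closes, so the planted latent flux of exactly zero is
an optimum rather than a boundary approximation.

What the toys do *not* emulate: genome-scale redundancy, realistic
expression distributions, measurement correlations, cofactor/energy
balancing, or biomass compositions. Passing tests demonstrate the
optimization machinery and its formal properties, not predictive accuracy
on real organisms — that requires external models and datasets, which the
package reads (SBML + TSV) but does not bundle.

Solver-independent oracles back every optimization route: exhaustive
active-set/KKT enumeration for convex QPs (exact for instances with ≤ 8
reduced dimensions, after null-space elimination of equalities), vertex
enumeration for LPs, on/off-pattern enumeration with LP feasibility checks
for the significant-change count, and 1-D dense grid refinement for the
closed-form worked examples. Randomized agreement suites use 4-reaction
networks (7 QP variables, ~18 inequalities) so the enumeration stays
exact and fast; 50 seeds per operation run in well under five minutes on
one CPU.

## Known limitations

- The DNF expansion can blow up combinatorially on pathological GPR rules
  (alternating and/or nesting ~20 genes deep); genome-scale models in
  practice stay far below this.
- The dense QP layer targets toy-to-central-metabolism scale. Genome-scale
  models load fine, but the estimator/predictor would need a sparse QP
  backend for comfortable runtimes at thousands of reactions.
- Isozyme-specific degradation of predictions (e.g. a minor isozyme that
  is post-transcriptionally inactive) is invisible to expression
  weighting.
- The estimator's parallel-route spreading bias (above) means reference
  fluxes through redundant pathways follow expression ratios, not ground
  truth, when MFA cannot separate the routes.
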