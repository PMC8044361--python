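# Methods

## The model class

A dynamic fuzzy model (DFM) is a network of 0-order Sugeno fuzzy inference
systems over a set of *linguistic variables*, each holding a crisp state on
a bounded universe (by default `[0, 1]`). Variables are partitioned by role:

* **input** — driven from outside by a user-defined time function (a
  *driver*); inputs appear only in rule antecedents;
* **output** — read-outs of interest (here: apoptosis and necrosis);
  outputs appear only in rule consequents;
* **inner** — everything else; inner variables may appear on both sides.

Interactions are rules `IF <antecedent> THEN (y IS c)` where the antecedent
combines atoms `(x IS term)` with AND (minimum t-norm), OR (maximum),
NOT (complement), and the consequent `c` is a crisp constant in the target
variable's universe. Linguistic terms ("low", "high", ...) carry
piecewise-linear membership functions (triangular or trapezoidal; a crisp
point is also accepted) and a *setpoint*: the crisp value a perturbation
forces when the term is imposed.

The rule norms (min / max / complement) are not the only possible choice of
fuzzy connectives; they are the conventional defaults of Sugeno-type
inference libraries, they preserve the `[0, 1]` closure of the state space,
and they make firing strengths monotone in atom degrees, which the property
tests rely on.

## Dynamics

Time is discrete with unit steps `t = 0 .. t_max`. The update is fully
synchronous: for each non-input variable `y` with rules `i = 1..n`,

    y(t+1) = Σ_i w_i(t) c_i / Σ_i w_i(t),

where `w_i(t)` is rule *i*'s firing strength on the complete state at `t`.
If no rule fires (`Σ w_i = 0`) the weighted average is undefined; the
variable **holds its previous state**. This keeps the dynamics total and is
also what makes the planted test models work (their targets rest at a state
where no rule fires). Inputs take their driver's value at each step.

An elementary perturbation `(L, F, t_b, t_e)` forces variable `L` to follow
`F` on the **closed** interval `[t_b, t_e]`, with inference disabled for
`L` there; a treatment is a list of such forcings. Precedence is
perturbation > driver > inference. The closed-interval reading (value
applied at `t_b` itself) is a deliberate choice — it lets a whole-simulation
forcing cover `t = 0` — and is recorded here rather than asserted as the
only possible convention. Driver and forcing values are clamped to the
variable's universe instead of rejected, since parametric time functions
may legitimately over- or undershoot at interval ends.

Determinism: `simulate` is a pure function of `(model, perturbation)`;
trajectories are bit-identical across calls and invariant to the storage
order of variables and rules.

## The screening problem

A candidate treatment is a genome of `D` symbols from `{0, 1, 2}` over an
ordered list of perturbable variables: 0 = untouched, 1 = force the
variable to its "low" setpoint, 2 = to its "high" setpoint, for the whole
simulation (`t_b = 0`, `t_e = t_max`). Objectives, measured at the
evaluation step Δ:

* maximize `x_apo(Δ) − x_apo(0)` (apoptosis change; negated internally so
  the optimizer minimizes everything);
* minimize `x_nec(Δ) − x_nec(0)` (necrosis change; 3-objective runs only);
* minimize the complexity `k` = number of non-zero genome positions.

The shipped K-ras scaffold fixes the genome order of the 16 perturbable
components of the oncogenic K-ras programmed-cell-death model
(Attachment, Autophagy, BCN1, Bcl2, CI, Ca2+, CHOP, DAPK, DeltaPsi, ERK,
HBP, JNK, N-glycosylation, ROS, Src, UPR) and Δ = 13, the step at which
half of the available glucose has been consumed under the glucose-depletion
driver. The genome position of a variable is its index in that printed
order — the mapping is fixed in one place so results are reportable. The
rule base itself is distributed separately under GPL and is therefore not
bundled; it must be transcribed into the model format (see
`kras_model_howto.md`) and attached before simulation. An experimental
condition such as PKA low/high is applied as a *condition binding*: the
input's driver is replaced by a constant at the chosen term's setpoint for
the whole run (PKA is not among the 16 perturbable components, which
supports the condition-binding reading over encoding it in the genome).

## The optimizer

NSGA-II over ternary genomes, self-contained: Pareto dominance
(minimization; no worse everywhere, strictly better somewhere), fast
non-dominated sorting, crowding distance (boundary individuals get +∞,
interior ones accumulate range-normalized neighbour gaps per objective;
zero-range objectives contribute 0), crowded-comparison binary tournaments,
half-uniform crossover (swap exactly ⌊|H|/2⌋ of the differing positions H,
chosen uniformly), and per-position flip mutation (replace with a uniformly
drawn *different* symbol).

Two bookkeeping conventions matter and are fixed explicitly:

* **Archive merging.** Each generation merges the current population with
  an elite archive `E` of all non-dominated individuals found so far,
  rather than the canonical parent+offspring (μ+λ) merge of the 2002
  algorithm. `E` only improves, so elitism holds; the final answer is `E`,
  the non-dominated set of every point ever evaluated (tested directly).
* **Budget accounting.** The initial population's evaluation counts as
  generation 1, so a run of `Q` individuals for `IT_max` generations costs
  exactly `Q × IT_max` evaluator calls — 10,000 for Q=100 / 100 generations
  and 15,000 for Q=100 / 150. This convention makes the budget exact by
  construction and is instrumented in the acceptance checks.

Defaults: crossover probability 1.0, mutation rate `1/D`, tournament size
2 — the common defaults for integer-genome problems, pinned here explicitly
so behaviour never depends on another library's versioned defaults.
Truncation ties at equal crowding break by insertion order (stable sort)
for reproducibility. Duplicate genomes are allowed inside the population;
deduplication happens at reporting time.

## Pareto post-filters

After optimization the front is deduplicated and filtered by pure
per-solution predicates; the kept set is order-independent (only the
annotated rejection reason depends on the order in which predicates are
checked):

1. complexity ≤ 3 — more than three simultaneous drug targets is
   impractical to validate and dose;
2. complexity ≥ 2 (3-objective preset) — single-target effects are already
   exhaustively studied;
3. no two targets sharing a pathway label or directly connected by an
   interaction-graph edge (either direction) — such pairs are redundant;
4. no forbidden forcings — by default raising reactive oxygen species
   ("ROS high") or hyperactivating the Src oncogene ("Src high"), both
   harmful or impractical as treatments;
5. necrosis change ≤ τ_nec — retain only the low-necrosis part of the
   front. τ_nec defaults to 0.25 on the `[0, 1]` state scale and is a
   configurable knob, not a claim: no canonical value exists, and the
   wording that motivates the filter is ambiguous enough that the
   implementation follows the stated purpose (keep treatments with a low
   necrosis increase) rather than its letter.

## Synthetic test problems

The generators exist so that every layer is testable without external
model files; they emulate the *structure* of real screening problems
(input/inner/output roles, `[0, 1]` states, low/high perturbable terms,
whole-run forcings), not any particular biology.

**Planted problems.** Each of `d` target variables rests at 0.5, where both
its "low" and "high" memberships are zero, so nothing fires unless a
perturbation forces it to a setpoint. Each planted (target, term) pair has
a singleton rule contributing its effect size to the apoptosis output, and
the full planted combination has one conjunction rule with consequent
`min(1, Σ effects)`. Because Sugeno inference *averages* fired consequents
rather than summing them, a literally additive design cannot make a
combination beat its own best element; the conjunction rule is what makes
the complete planted combination strictly the best treatment at its own
complexity. The constructor enforces the sufficient condition
`(Σe + min(1, Σe)) / (k+1) > max e_i`; with the default equal effects it
always holds. Every genome's exact fitness then has a closed form, checked
exhaustively (all `3^d` genomes) against the simulation in the tests. An
*epistatic* variant keeps only the AND-gated conjunction rule, giving a
fully checkable interaction truth table. Necrosis effects can be planted
the same way for 3-objective problems.

**Brute-force oracle.** For `d ≤ 10` every genome is enumerated, evaluated
through the same pipeline, and the true Pareto front extracted by
definition-level all-pairs dominance. This is the independent yardstick for
the optimizer: with Q=40 and 50 generations on planted `d = 6` problems
(729 genomes), the full true front is recovered in every tested seed.

What passing these tests does *not* show: recovery of biologically
meaningful targets on a real rule base. The planted landscapes are far
smoother than a signaling network's; they validate the machinery
(encoding, objectives, elitism, budget), not the biology.

## Numerical and degenerate-input choices

* Membership functions are piecewise-linear with non-decreasing
  breakpoints; degenerate (vertical) edges take degree 1 at the shared
  abscissa, so `triangular(0, 0, 0.5)` is 1 at 0.
* Term setpoints default to the universe minimum for "low", maximum for
  "high", and the peak of the membership function otherwise; all
  overridable per term in the model file. Validation checks that a setpoint
  attains its term's maximal membership (201-point grid, tolerance 1e-9).
* Initial states default to 0.0 (resting baseline) when the model file
  omits them.
* Zero-firing holds are logged at DEBUG level; they are routine in models
  with resting states, not anomalies.
* Model files are canonicalized on write (variables sorted by name, rule
  text normalized through the parser, sorted keys) so load→write
  round-trips are byte-stable and structural equality implies file
  equality.

## Problem sizes used in the checks

The automated checks run on planted problems with 6 targets (9 variables,
`t_max = 20`): exhaustive enumeration is 729 simulations, the 2- and
3-objective budget runs are 10,000 and 15,000 simulations, and front
recovery uses 10 independent seeds of 2,000 evaluations each. These sizes
keep the full exhaustive oracle available; the pipeline itself is the same
one a 16-variable screen uses (3^16 ≈ 4.3×10^7 genomes, which is exactly
why the evolutionary search exists).

## Known limitations

* Only 0-order Sugeno inference: consequents are constants, not fuzzy sets
  (Mamdani) or functions of the antecedents (higher-order Sugeno).
* Synchronous unit-step dynamics only; no asynchronous or continuous-time
  semantics, no stochastic state noise.
* The evaluator contract is sequential and deterministic; no parallel
  evaluation.
* The pathway/adjacency filter needs pathway labels and interaction edges
  in the model file; it fails loudly (configuration error) when labels are
  missing rather than silently passing solutions.
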