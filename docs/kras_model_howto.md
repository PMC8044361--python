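# Attaching the K-ras rule base

The screening scaffold returned by `dfmscreen.kras_problem()` fixes the
genome encoding (the 16 perturbable components in their published order and
Δ = 13) but ships **without** the rule base: the K-ras programmed-cell-death
model is distributed separately under GPL in its authors' repository, and
this package does not bundle or auto-translate it. Simulating the bare
scaffold raises a "model not attached" error by design.

To run the real screen, transcribe the model into the format of
`model_format.md`:

1. Create a model document listing every variable of the K-ras network with
   its role (`PKA` and `Glucose` are inputs; `Apoptosis`, `Necrosis`,
   `Survival` etc. are outputs; the rest are inner), its terms with
   membership functions, and its initial state. Use the plain-text
   identifiers `Ca2+` and `N-glycosylation` (a `display_name` field can
   carry the formatted spelling).
2. Transcribe each fuzzy rule into the `IF ... THEN (...)` grammar. The
   connectives map directly (AND/OR/NOT); 0-order Sugeno consequents are
   the crisp constants.
3. Encode the glucose-depletion input as a `piecewise` driver (the
   published evaluation step Δ = 13 is the point where half of the glucose
   has been consumed, so the driver should cross half of its initial value
   there) and set `t_max` to the value used by the source model.
4. Add the interaction-graph `edges` and per-variable `pathway` labels —
   the 3-objective post-filters need both.
5. Validate: `load_model` surfaces all structural diagnostics at once.
6. Write a problem document whose `perturbable` list is exactly the
   scaffold's order (compare against `dfmscreen.KRAS_PERTURBABLE`), with
   `condition: {PKA: low}` or `{PKA: high}`, then run
   `dfmscreen screen --problem kras_problem.yaml -Q 100 -I 100` (2
   objectives) or `-I 150` with `objectives: 3obj`.

A faithful transcription should reproduce the published behaviour
qualitatively: 2-objective screens yielding ≤3-element solutions such as
"Bcl2 IS low" under PKA high, and 3-objective screens yielding of the order
of 31 (PKA low) and 13 (PKA high) unique ≤3-element solutions — these are
stochastic, seed-dependent plausibility checks, not exact targets.
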