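# dfmscreen

In-silico screening of combination treatments on dynamic fuzzy models of
cellular regulation.

Finding drug-target *combinations* that kill cancer cells cleanly is
expensive in the lab: the space of simultaneous perturbations grows
exponentially with the number of targetable components. `dfmscreen`
attacks this computationally. It simulates **dynamic fuzzy models (DFMs)**
— networks of 0-order Sugeno fuzzy inference systems in which every
component (ion, metabolite, protein, process, phenotype) is a linguistic
variable with a state in [0, 1], updated synchronously by rules like
`IF (Glucose IS low) THEN (Stress IS 1.0)` — and searches the perturbation
space with the elitist multi-objective genetic algorithm **NSGA-II**.

A candidate treatment is a genome of D symbols from {0, 1, 2}: position *i*
leaves component *i* untouched, forces it "low" (inhibition), or forces it
"high" (hyperactivation) for the whole simulation. Objectives, measured at
an evaluation step Δ:

* maximize f_apo = x_apo(Δ) − x_apo(0) — apoptosis (clean, programmed death),
* minimize f_nec = x_nec(Δ) − x_nec(0) — necrosis (inflammatory death),
* minimize f_com = k — the number of perturbed components.

The result is a Pareto front of treatments, post-filtered by practical
rules (at most 3 targets, no single-target solutions, no same-pathway or
directly interacting pairs, no harmful forcings such as "ROS high" or
"Src high", low necrosis). The package ships the screening scaffold for the
oncogenic K-ras programmed-cell-death model — its 16 perturbable components
in fixed genome order with Δ = 13 — to which a transcribed rule base can be
attached (`docs/kras_model_howto.md`); the GPL-licensed rule base itself is
not bundled. Fully-known synthetic problems (planted optima, exhaustive
Pareto oracles) make every layer testable without any external data.

## Worked example

Generate a synthetic screening problem with a planted optimum
(two targets, `Target0 IS high` + `Target1 IS low`, apoptosis effect 0.5
each) and screen it:

```sh
dfmscreen make-fixtures --out fx --seed 1
dfmscreen screen --problem fx/planted_problem.yaml -Q 40 -I 50 --seed 1 --out screen-out
```

which prints

```
evaluations: 2000
kept 4 of 4 unique Pareto solutions
wrote screen-out/solutions.csv
```

and writes this solutions table (plus a Pareto-front figure, a per-generation
history CSV and a run manifest with the config and seed):

```
kept,genome,perturbation,apoptosis_change,necrosis_change,complexity,failed_filter
True,200000,Target0 IS high,0.5,,1,
True,210000,"Target0 IS high, Target1 IS low",0.6666666666666666,,2,
True,010000,Target1 IS low,0.5,,1,
True,000000,,0.0,,0,
```

Read it as the apoptosis/complexity trade-off curve: doing nothing changes
apoptosis by 0 at cost 0; either single forcing raises the apoptosis
read-out by 0.5; the planted pair raises it to 2/3 (the Sugeno-weighted
aggregate of both effects and their conjunction) at complexity 2. Each row
is non-dominated — more apoptosis always costs another target. Brute-force
enumeration of all 3^6 = 729 genomes confirms this is exactly the true
Pareto front.

The same pipeline from Python:

```python
from dfmscreen import (PlantedSpec, make_planted_dfm, TherapyProblem,
                       OptimizerConfig, nsga2_run, make_evaluator)

_, definition = make_planted_dfm(PlantedSpec(d=6))
problem = TherapyProblem(definition)
config = OptimizerConfig(genome_length=6, n_objectives=2,
                         population_size=40, generations=50, seed=1)
result = nsga2_run(make_evaluator(problem), config)
print(result.n_evaluations)            # 2000
print(sorted(i.fitness for i in result.nondominated))
```

Single simulations are available too: `dfmscreen simulate --model
src/dfmscreen/examples/glucose_depletion.yaml --perturb "Stress=high"`
writes a tidy trajectory CSV and a line plot of every variable.

## Layout

* `src/dfmscreen/fuzzy.py` — membership functions, rule grammar + parser,
  firing strengths, 0-order Sugeno inference
* `src/dfmscreen/engine.py` — synchronous DFM simulation, perturbations,
  trajectories, model validation
* `src/dfmscreen/model_io.py` — YAML model/problem format, K-ras scaffold
* `src/dfmscreen/nsga2.py` — self-contained NSGA-II over ternary genomes
* `src/dfmscreen/screening.py` — genome decoding, objectives, post-filters,
  reporting
* `src/dfmscreen/synthetic.py` — planted/random model generators and the
  brute-force Pareto oracle
* `src/dfmscreen/cli.py` — `dfmscreen simulate | screen | filter |
  make-fixtures`
* `docs/methods.md` — modeling assumptions, conventions and limitations
* `docs/model_format.md` — file-format and rule-grammar reference
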