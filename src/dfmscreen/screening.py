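"""The therapy-screening problem: genome decoding, objectives, filters.

A candidate treatment is a ternary genome over the problem's perturbable
variables: 0 leaves a variable untouched, 1 forces it to its "low" setpoint
and 2 to its "high" setpoint, for the whole simulation. Objectives
(minimization orientation as handed to the optimizer):

* apoptosis: maximize x_apo(Δ) − x_apo(0)   (negated internally),
* necrosis:  minimize x_nec(Δ) − x_nec(0)   (3-objective runs only),
* complexity: minimize the number of perturbed variables.

Post-optimization filters encode practical constraints on a Pareto front of
candidate treatments: at most three drug targets, no trivial singletons, no
redundant pairs within one pathway or directly interacting, no harmful
forcings (reactive-oxygen-species increase, Src hyperactivation), and a low
necrosis increase.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from .engine import DFModel, Driver, GlobalPerturbation, Perturbation, simulate, state_change
from .errors import DfmError
from .model_io import ProblemDefinition
from .nsga2 import Genome

__all__ = [
    "TherapyProblem",
    "Solution",
    "FilterConfig",
    "decode",
    "evaluate",
    "filter_solutions",
    "render_perturbation",
    "parse_perturbation",
    "report",
]

_SYMBOL_TERMS = {1: "low", 2: "high"}
_TERM_SYMBOLS = {v: k for k, v in _SYMBOL_TERMS.items()}


@dataclass(frozen=True)
class TherapyProblem:
    """A problem definition bound to a concrete model, ready to evaluate.

    The experimental condition (e.g. PKA low vs high) is applied by
    replacing the bound input's driver with a constant at the term's
    setpoint for the whole run.
    """

    definition: ProblemDefinition
    model: DFModel = None  # resolved, condition applied

    def __post_init__(self):
        model = self.definition.require_model()
        for var_name, term_label in self.definition.condition.items():
            var = model.variable(var_name)
            if var.role != "input":
                raise DfmError(
                    f"condition binding targets non-input variable {var_name!r}"
                )
            setpoint = var.term(term_label).setpoint
            drivers = dict(model.drivers)
            drivers[var_name] = Driver(kind="constant", value=setpoint)
            model = replace(model, drivers=drivers)
        for out_name in (self.definition.apoptosis_variable,) + (
            (self.definition.necrosis_variable,) if self.definition.objectives == "3obj" else ()
        ):
            var = model.variable(out_name)  # raises KeyError if absent
            if var.role != "output":
                raise DfmError(f"objective variable {out_name!r} must have role 'output'")
        for name in self.definition.perturbable:
            var = model.variable(name)
            labels = set(var.term_labels)
            if not {"low", "high"} <= labels:
                raise DfmError(
                    f"perturbable variable {name!r} needs 'low' and 'high' terms"
                )
        if self.definition.delta > model.t_max:
            raise DfmError("delta exceeds model t_max")
        from .engine import validate
        from .errors import ModelValidationError

        diags = validate(model)
        if diags:
            raise ModelValidationError(diags)
        object.__setattr__(self, "model", model)

    @property
    def genome_length(self) -> int:
        return self.definition.genome_length

    @property
    def n_objectives(self) -> int:
        return self.definition.n_objectives


@dataclass(frozen=True)
class Solution:
    """A decoded candidate treatment with its raw objective values."""

    genome: Genome
    apoptosis_change: float
    complexity: int
    necrosis_change: float | None = None
    failed_filter: str | None = None

    def fitness(self, objectives: str) -> tuple[float, ...]:
        if objectives == "2obj":
            return (-self.apoptosis_change, float(self.complexity))
        return (-self.apoptosis_change, float(self.necrosis_change), float(self.complexity))


def decode(genome: Sequence[int], problem: TherapyProblem) -> GlobalPerturbation:
    """Ternary genome -> whole-simulation constant forcings.

    Symbol 1 (2) at position i forces ``perturbable[i]`` to its low (high)
    setpoint on [0, t_max]; symbol 0 contributes nothing.
    """
    if len(genome) != problem.genome_length:
        raise DfmError(
            f"genome length {len(genome)} != problem length {problem.genome_length}"
        )
    perts = []
    for i, sym in enumerate(genome):
        sym = int(sym)
        if sym == 0:
            continue
        if sym not in _SYMBOL_TERMS:
            raise DfmError(f"genome symbol {sym} at position {i} outside {{0, 1, 2}}")
        name = problem.definition.perturbable[i]
        setpoint = problem.model.variable(name).term(_SYMBOL_TERMS[sym]).setpoint
        perts.append(Perturbation.constant(name, setpoint, 0, problem.model.t_max))
    return GlobalPerturbation(tuple(perts))


def solve(genome: Sequence[int], problem: TherapyProblem) -> Solution:
    """Simulate one genome and measure the raw objective values."""
    genome = tuple(int(s) for s in genome)
    try:
        traj = simulate(problem.model, decode(genome, problem), check=False)
    except Exception as exc:
        raise DfmError(f"simulation failed for genome {genome}: {exc}") from exc
    d = problem.definition
    apo = state_change(traj, d.apoptosis_variable, d.delta)
    nec = (
        state_change(traj, d.necrosis_variable, d.delta)
        if d.objectives == "3obj"
        else None
    )
    return Solution(
        genome=genome,
        apoptosis_change=apo,
        necrosis_change=nec,
        complexity=sum(1 for s in genome if s != 0),
    )


def evaluate(genome: Sequence[int], problem: TherapyProblem) -> tuple[float, ...]:
    """Fitness vector in minimization orientation for the optimizer."""
    return solve(genome, problem).fitness(problem.definition.objectives)


def make_evaluator(problem: TherapyProblem) -> Callable[[Genome], tuple[float, ...]]:
    return lambda genome: evaluate(genome, problem)


# --- perturbation strings --------------------------------------------------

def render_perturbation(genome: Sequence[int], problem_or_names) -> str:
    """Human-readable treatment string, e.g. ``"Bcl2 IS low, Ca2+ IS high"``.

    Entries follow genome-position order; the empty genome renders as "".
    """
    names = (
        problem_or_names.definition.perturbable
        if isinstance(problem_or_names, TherapyProblem)
        else tuple(problem_or_names)
    )
    parts = [
        f"{names[i]} IS {_SYMBOL_TERMS[int(s)]}"
        for i, s in enumerate(genome)
        if int(s) != 0
    ]
    return ", ".join(parts)


def parse_perturbation(text: str, problem_or_names) -> Genome:
    """Inverse of :func:`render_perturbation`: recover the genome."""
    names = (
        problem_or_names.definition.perturbable
        if isinstance(problem_or_names, TherapyProblem)
        else tuple(problem_or_names)
    )
    genome = [0] * len(names)
    text = text.strip()
    if not text:
        return tuple(genome)
    index = {n: i for i, n in enumerate(names)}
    for chunk in text.split(","):
        try:
            var, term = (s.strip() for s in chunk.strip().split(" IS "))
        except ValueError:
            raise DfmError(f"cannot parse perturbation entry {chunk.strip()!r}")
        if var not in index:
            raise DfmError(f"unknown perturbable variable {var!r} in {text!r}")
        if term.lower() not in _TERM_SYMBOLS:
            raise DfmError(f"unknown term {term!r} in {text!r}")
        genome[index[var]] = _TERM_SYMBOLS[term.lower()]
    return tuple(genome)


# --- filters ---------------------------------------------------------------

@dataclass(frozen=True)
class FilterConfig:
    """Which post-filters to apply; presets via :meth:`for_objectives`.

    ``forbidden`` lists (variable, term) forcings never acceptable in a
    treatment; the defaults exclude raising reactive oxygen species and
    hyperactivating the Src oncogene. ``tau_nec`` is the "low necrosis"
    retention threshold on the raw necrosis change.
    """

    max_elements: int | None = 3
    min_elements: int | None = None
    no_same_pathway_or_adjacent: bool = False
    forbidden: tuple[tuple[str, str], ...] = ()
    tau_nec: float | None = None

    @staticmethod
    def for_objectives(objectives: str, tau_nec: float = 0.25) -> "FilterConfig":
        if objectives == "2obj":
            return FilterConfig(max_elements=3)
        return FilterConfig(
            max_elements=3,
            min_elements=2,
            no_same_pathway_or_adjacent=True,
            forbidden=(("ROS", "high"), ("Src", "high")),
            tau_nec=tau_nec,
        )


def _perturbed_pairs(solution: Solution, names: Sequence[str]):
    return [
        (names[i], _SYMBOL_TERMS[s])
        for i, s in enumerate(solution.genome)
        if s != 0
    ]


def _filter_reason(solution: Solution, problem: TherapyProblem,
                   config: FilterConfig) -> str | None:
    """First failed filter name, or None if the solution passes all."""
    names = problem.definition.perturbable
    targets = _perturbed_pairs(solution, names)
    if config.max_elements is not None and solution.complexity > config.max_elements:
        return "max_elements"
    if config.min_elements is not None and solution.complexity < config.min_elements:
        return "min_elements"
    if config.no_same_pathway_or_adjacent:
        model = problem.model
        var_names = [v for v, _ in targets]
        pathways = {}
        for v in var_names:
            label = model.variable(v).pathway
            if label is None:
                raise DfmError(
                    f"pathway filter enabled but variable {v!r} has no pathway label"
                )
            pathways[v] = label
        adjacency = {(s, d) for s, d, _ in model.graph_edges}
        for i in range(len(var_names)):
            for j in range(i + 1, len(var_names)):
                a, b = var_names[i], var_names[j]
                if pathways[a] == pathways[b]:
                    return "same_pathway"
                if (a, b) in adjacency or (b, a) in adjacency:
                    return "adjacent"
    forbidden = set(config.forbidden)
    if any(pair in forbidden for pair in targets):
        return "forbidden_perturbation"
    if config.tau_nec is not None:
        if solution.necrosis_change is None:
            raise DfmError("necrosis filter enabled but solutions carry no necrosis change")
        if solution.necrosis_change > config.tau_nec:
            return "high_necrosis"
    return None


def filter_solutions(
    front: Sequence[Solution],
    problem: TherapyProblem,
    config: FilterConfig,
) -> tuple[list[Solution], list[Solution]]:
    """Apply the enabled post-filters to a Pareto front.

    Duplicate genomes are dropped first (first occurrence kept). Returns
    (kept, rejected); each rejected solution is annotated with the name of
    the first filter it failed. Since every filter is a pure per-solution
    predicate, the kept set does not depend on filter order — only the
    annotated reason does.
    """
    seen: set[Genome] = set()
    kept: list[Solution] = []
    rejected: list[Solution] = []
    for sol in front:
        if sol.genome in seen:
            continue
        seen.add(sol.genome)
        reason = _filter_reason(sol, problem, config)
        if reason is None:
            kept.append(sol)
        else:
            rejected.append(replace(sol, failed_filter=reason))
    return kept, rejected


# --- reporting -------------------------------------------------------------

def solutions_frame(solutions: Sequence[Solution], problem: TherapyProblem) -> pd.DataFrame:
    names = problem.definition.perturbable
    rows = []
    for sol in solutions:
        rows.append(
            {
                "genome": "".join(str(s) for s in sol.genome),
                "perturbation": render_perturbation(sol.genome, names),
                "apoptosis_change": sol.apoptosis_change,
                "necrosis_change": sol.necrosis_change,
                "complexity": sol.complexity,
                "failed_filter": sol.failed_filter,
            }
        )
    columns = ["genome", "perturbation", "apoptosis_change", "necrosis_change",
               "complexity", "failed_filter"]
    return pd.DataFrame(rows, columns=columns)


def report(
    kept: Sequence[Solution],
    problem: TherapyProblem,
    manifest: dict,
    out_dir: str | Path,
    rejected: Sequence[Solution] = (),
) -> dict[str, Path]:
    """Write the solutions table (CSV + JSON) and the run manifest."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = solutions_frame(list(kept) + list(rejected), problem)
    frame.insert(0, "kept", [True] * len(kept) + [False] * len(rejected))
    csv_path = out_dir / "solutions.csv"
    json_path = out_dir / "solutions.json"
    manifest_path = out_dir / "manifest.json"
    frame.to_csv(csv_path, index=False)
    json_path.write_text(frame.to_json(orient="records", indent=2))
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"csv": csv_path, "json": json_path, "manifest": manifest_path}
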