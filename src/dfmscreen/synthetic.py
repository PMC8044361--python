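"""Small, fully-known dynamic fuzzy models and an exhaustive Pareto oracle.

Everything here exists so that the simulation engine, the optimizer and the
screening pipeline can be tested end-to-end with no external model files:

* :func:`make_random_dfm` builds valid random fuzzy networks for structural
  and closure properties;
* :func:`make_planted_dfm` builds screening problems whose exact objective
  values have a closed form, with a known optimal symbol combination planted
  into the rule base;
* :func:`brute_force_front` enumerates *every* genome of a small problem and
  extracts the true Pareto front by all-pairs dominance — the independent
  oracle the optimizer is judged against.

Planted construction. Each perturbable target variable rests at 0.5, where
both its "low" and "high" memberships are zero, so nothing fires unless the
variable is forced to a setpoint (0 or 1). Each planted (target, term) pair
has a singleton rule contributing its effect size to the apoptosis-like
output, and the full planted combination has one conjunction rule whose
consequent is min(1, sum of effects). Under 0-order Sugeno inference the
output is the *average* of the fired consequents, not their sum, so the
conjunction rule is what makes the complete combination strictly better
than any same-complexity alternative; the constructor enforces the
sufficient condition on effect sizes. The resulting fitness of every genome
is a short closed form, checked exhaustively in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .engine import DFModel, Driver, validate
from .errors import DfmError
from .fuzzy import (
    LinguisticTerm,
    LinguisticVariable,
    MembershipFunction,
    SymbolTable,
    parse_rule,
)
from .model_io import ProblemDefinition
from .nsga2 import Genome, dominates
from .screening import Solution, TherapyProblem, solve

__all__ = [
    "PlantedSpec",
    "OracleFront",
    "make_random_dfm",
    "make_planted_dfm",
    "brute_force_front",
]

_SYMBOL_TERMS = {1: "low", 2: "high"}


def _low_high_terms(universe=(0.0, 1.0)) -> tuple[LinguisticTerm, LinguisticTerm]:
    lo, hi = universe
    mid = (lo + hi) / 2.0
    return (
        LinguisticTerm("low", MembershipFunction("triangular", (lo, lo, mid), universe), lo),
        LinguisticTerm("high", MembershipFunction("triangular", (mid, hi, hi), universe), hi),
    )


@dataclass(frozen=True)
class PlantedSpec:
    """Specification of a planted screening problem.

    ``planted`` maps genome position -> symbol (1 = low, 2 = high) for the
    1–3 positions of the optimal combination; ``effects`` gives each planted
    position's apoptosis effect size in (0, 1]. ``necrosis_effects`` maps
    (position, symbol) pairs to necrosis effect sizes, letting 3-objective
    trade-offs be planted too. ``epistasis`` drops the singleton rules and
    keeps only the AND-gated combination rule.
    """

    d: int = 6
    planted: Mapping[int, int] = field(default_factory=lambda: {0: 2, 1: 1})
    effects: Mapping[int, float] = field(default_factory=dict)
    necrosis_effects: Mapping[tuple[int, int], float] = field(default_factory=dict)
    epistasis: bool = False
    t_max: int = 20
    delta: int = 10
    objectives: str = "2obj"
    seed: int = 0

    def __post_init__(self):
        if not (2 <= self.d <= 10):
            raise DfmError(f"planted problems support 2 <= d <= 10, got {self.d}")
        planted = dict(self.planted)
        if not (1 <= len(planted) <= 3):
            raise DfmError("planted combination must have 1-3 non-zero symbols")
        for pos, sym in planted.items():
            if not (0 <= pos < self.d) or sym not in (1, 2):
                raise DfmError(f"bad planted entry {pos}: {sym}")
        effects = dict(self.effects) or {pos: 0.5 for pos in planted}
        if set(effects) != set(planted):
            raise DfmError("effects must be keyed by exactly the planted positions")
        if any(not (0.0 < e <= 1.0) for e in effects.values()):
            raise DfmError("effect sizes must be in (0, 1]")
        k = len(planted)
        if k >= 2 and not self.epistasis:
            total = sum(effects.values())
            best = (total + min(1.0, total)) / (k + 1)
            if best <= max(effects.values()):
                raise DfmError(
                    "effect sizes too uneven: the full planted combination would "
                    "not beat its best single element under Sugeno averaging"
                )
        object.__setattr__(self, "planted", planted)
        object.__setattr__(self, "effects", effects)
        object.__setattr__(self, "necrosis_effects", dict(self.necrosis_effects))

    @property
    def planted_genome(self) -> Genome:
        return tuple(self.planted.get(i, 0) for i in range(self.d))


def make_planted_dfm(spec: PlantedSpec) -> tuple[DFModel, ProblemDefinition]:
    """Build the planted model and its (attached) problem definition."""
    targets = [f"Target{i}" for i in range(spec.d)]
    variables = [
        LinguisticVariable("Stimulus", "input", _low_high_terms(), initial=1.0),
    ]
    for i, name in enumerate(targets):
        variables.append(
            LinguisticVariable(
                name, "inner", _low_high_terms(), initial=0.5, pathway=f"pathway-{i}"
            )
        )
    variables.append(LinguisticVariable("Apoptosis", "output", _low_high_terms(), initial=0.0))
    variables.append(LinguisticVariable("Necrosis", "output", _low_high_terms(), initial=0.0))

    symbols = SymbolTable(variables)
    rule_texts: list[str] = []
    # rest-state rules: fire only away from the 0.5 resting point, so an
    # unperturbed target simply holds its state
    for name in targets:
        rule_texts.append(f"IF ({name} IS high) THEN ({name} IS 1.0)")

    conj = " AND ".join(
        f"(Target{pos} IS {_SYMBOL_TERMS[sym]})" for pos, sym in sorted(spec.planted.items())
    )
    if not spec.epistasis:
        for pos, sym in sorted(spec.planted.items()):
            rule_texts.append(
                f"IF (Target{pos} IS {_SYMBOL_TERMS[sym]}) THEN (Apoptosis IS {spec.effects[pos]!r})"
            )
    if spec.epistasis or len(spec.planted) >= 2:
        total = min(1.0, sum(spec.effects.values()))
        rule_texts.append(f"IF {conj} THEN (Apoptosis IS {total!r})")

    if spec.necrosis_effects:
        for (pos, sym), eff in sorted(spec.necrosis_effects.items()):
            rule_texts.append(
                f"IF (Target{pos} IS {_SYMBOL_TERMS[sym]}) THEN (Necrosis IS {eff!r})"
            )
    else:
        # contradiction that can never fire: keeps Necrosis at its resting 0
        rule_texts.append(
            "IF (Target0 IS low) AND (Target0 IS high) THEN (Necrosis IS 1.0)"
        )

    edges = [(name, "Apoptosis", "positive") for name in targets]
    edges += [(name, "Necrosis", "positive") for name in targets]
    model = DFModel(
        name=f"planted-d{spec.d}",
        description="synthetic planted screening model with closed-form objectives",
        variables=tuple(variables),
        rules=tuple(parse_rule(t, symbols) for t in rule_texts),
        drivers={"Stimulus": Driver(kind="constant", value=1.0)},
        t_max=spec.t_max,
        graph_edges=tuple(edges),
    )
    definition = ProblemDefinition(
        perturbable=tuple(targets),
        delta=spec.delta,
        objectives=spec.objectives,
        model=model,
    )
    return model, definition


def make_random_dfm(n_vars: int, seed: int = 0, t_max: int = 20) -> DFModel:
    """A valid random fuzzy network: one constant-driven input, at least one
    output, every non-input variable targeted by 1–2 rules with consequents
    in [0, 1]. Deterministic under ``seed``."""
    if n_vars < 3:
        raise DfmError("random models need n_vars >= 3")
    rng = np.random.default_rng(seed)
    names = [f"V{i}" for i in range(n_vars)]
    roles = ["input"] + ["inner"] * (n_vars - 2) + ["output"]
    variables = [
        LinguisticVariable(
            name, role, _low_high_terms(),
            initial=round(float(rng.uniform()), 3),
        )
        for name, role in zip(names, roles)
    ]
    symbols = SymbolTable(variables)
    antecedent_pool = [v.name for v in variables if v.role != "output"]
    rule_texts: list[str] = []
    edges: set[tuple[str, str, str]] = set()
    for v in variables:
        if v.role == "input":
            continue
        for _ in range(int(rng.integers(1, 3))):
            n_atoms = int(rng.integers(1, 3))
            sources = rng.choice(len(antecedent_pool), size=n_atoms, replace=False)
            atoms = []
            for s in sources:
                src = antecedent_pool[int(s)]
                term = "high" if rng.random() < 0.5 else "low"
                atom = f"({src} IS {term})"
                if rng.random() < 0.25:
                    atom = f"(NOT {atom})"
                atoms.append(atom)
                edges.add((src, v.name, "positive" if term == "high" else "negative"))
            joiner = " AND " if rng.random() < 0.5 else " OR "
            value = round(float(rng.uniform()), 3)
            rule_texts.append(f"IF {joiner.join(atoms)} THEN ({v.name} IS {value!r})")
    model = DFModel(
        name=f"random-{n_vars}-{seed}",
        description="synthetic random fuzzy network",
        variables=tuple(variables),
        rules=tuple(parse_rule(t, symbols) for t in rule_texts),
        drivers={names[0]: Driver(kind="constant", value=round(float(rng.uniform()), 3))},
        t_max=t_max,
        graph_edges=tuple(sorted(edges)),
    )
    diags = validate(model)
    if diags:  # pragma: no cover - generator contract
        raise DfmError(f"generator produced an invalid model: {diags}")
    return model


@dataclass(frozen=True)
class OracleFront:
    """Exhaustive evaluation of a small problem: every genome with its exact
    fitness vector, plus the true Pareto-optimal subset."""

    entries: tuple[tuple[Genome, tuple[float, ...]], ...]
    front: tuple[tuple[Genome, tuple[float, ...]], ...]

    @property
    def front_genomes(self) -> set[Genome]:
        return {g for g, _ in self.front}

    @property
    def front_fitnesses(self) -> set[tuple[float, ...]]:
        return {f for _, f in self.front}


def brute_force_front(problem: TherapyProblem, max_d: int = 10) -> OracleFront:
    """Enumerate all 3^D genomes, evaluate exactly, extract the true front.

    Refuses problems with D > ``max_d`` (the default caps enumeration at
    3^10 = 59,049 simulations).
    """
    d = problem.genome_length
    if d > max_d:
        raise DfmError(f"brute force refused: D={d} exceeds the cap of {max_d}")
    objectives = problem.definition.objectives
    entries = []
    for genome in itertools.product(range(3), repeat=d):
        sol = solve(genome, problem)
        entries.append((genome, sol.fitness(objectives)))
    fits = [f for _, f in entries]
    front = [
        entries[i]
        for i in range(len(entries))
        if not any(dominates(fits[j], fits[i]) for j in range(len(entries)) if j != i)
    ]
    return OracleFront(entries=tuple(entries), front=tuple(front))
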