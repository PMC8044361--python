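"""Read/write the YAML model format and screening problem definitions.

The on-disk dialect is single-document YAML restricted to a JSON-compatible
subset (plain scalars, lists, maps). A required ``format_version`` key makes
future schema changes detectable; unknown top-level keys are rejected so
typos fail loudly. ``write_model`` emits a canonical serialization (variables
sorted by name, rule text normalized through the parser) so load/write
round-trips are byte-stable.

The screening scaffold for the oncogenic K-ras programmed-cell-death model
is shipped here: the 16 perturbable components in their fixed genome order
and the evaluation step Δ = 13 (the step at which half of the available
glucose has been consumed). The rule base itself is not bundled — it must be
transcribed into this format (see docs/kras_model_howto.md) and attached
before simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .engine import DFModel, Driver, validate
from .errors import DfmError, ModelNotAttachedError, ModelValidationError
from .fuzzy import (
    LinguisticTerm,
    LinguisticVariable,
    MembershipFunction,
    SymbolTable,
    parse_rule,
)

__all__ = [
    "FORMAT_VERSION",
    "ProblemDefinition",
    "load_model",
    "write_model",
    "load_problem",
    "write_problem",
    "kras_problem",
    "KRAS_PERTURBABLE",
]

FORMAT_VERSION = 1

_MODEL_KEYS = {"format_version", "name", "description", "citation", "t_max",
               "variables", "rules", "drivers", "edges"}
_VARIABLE_KEYS = {"name", "role", "universe", "initial", "terms", "display_name",
                  "pathway", "constant"}
_TERM_KEYS = {"label", "mf", "setpoint"}
_PROBLEM_KEYS = {"format_version", "kind", "model", "perturbable", "delta",
                 "objectives", "condition", "apoptosis_variable", "necrosis_variable"}

# Genome position i of the treatment encoding is perturbable variable i of
# this list; "Ca2+" and "N-glycosylation" are the plain-text identifiers of
# the calcium and N-linked-glycosylation components.
KRAS_PERTURBABLE: tuple[str, ...] = (
    "Attachment", "Autophagy", "BCN1", "Bcl2", "CI", "Ca2+", "CHOP", "DAPK",
    "DeltaPsi", "ERK", "HBP", "JNK", "N-glycosylation", "ROS", "Src", "UPR",
)


def _reject_unknown(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise DfmError(f"unknown key(s) {unknown} in {where}")


def _default_setpoint(label: str, mf: MembershipFunction, universe) -> float:
    if label == "low":
        return float(universe[0])
    if label == "high":
        return float(universe[1])
    # midpoint of the peak region of the membership function
    if mf.kind == "crisp":
        return mf.points[0]
    if mf.kind == "triangular":
        return mf.points[1]
    return (mf.points[1] + mf.points[2]) / 2.0


def _term_from_doc(doc: dict, universe, where: str) -> LinguisticTerm:
    _reject_unknown(doc, _TERM_KEYS, where)
    mf_doc = doc.get("mf")
    if not isinstance(mf_doc, dict) or "kind" not in mf_doc or "points" not in mf_doc:
        raise DfmError(f"{where}: term needs mf: {{kind, points}}")
    mf = MembershipFunction(
        kind=mf_doc["kind"], points=tuple(mf_doc["points"]),
        universe=(universe[0], universe[1]),
    )
    label = doc["label"]
    setpoint = doc.get("setpoint")
    if setpoint is None:
        setpoint = _default_setpoint(label, mf, universe)
    return LinguisticTerm(label=label, mf=mf, setpoint=float(setpoint))


def _variable_from_doc(doc: dict) -> LinguisticVariable:
    if not isinstance(doc, dict) or "name" not in doc or "role" not in doc:
        raise DfmError(f"variable block needs at least 'name' and 'role': {doc!r}")
    where = f"variable {doc['name']!r}"
    _reject_unknown(doc, _VARIABLE_KEYS, where)
    universe = tuple(float(u) for u in doc.get("universe", (0.0, 1.0)))
    terms = tuple(_term_from_doc(t, universe, where) for t in doc.get("terms", ()))
    return LinguisticVariable(
        name=doc["name"],
        role=doc["role"],
        terms=terms,
        universe=universe,
        initial=float(doc.get("initial", 0.0)),
        display_name=doc.get("display_name"),
        pathway=doc.get("pathway"),
        constant=bool(doc.get("constant", False)),
    )


def _driver_from_doc(doc: dict, where: str) -> Driver:
    if not isinstance(doc, dict) or "kind" not in doc:
        raise DfmError(f"{where}: driver needs a 'kind'")
    kind = doc["kind"]
    if kind == "constant":
        return Driver(kind="constant", value=float(doc["value"]))
    if kind == "linear":
        return Driver(kind="linear", start=float(doc["start"]), end=float(doc["end"]))
    if kind == "piecewise":
        return Driver(kind="piecewise", points=tuple((float(t), float(v)) for t, v in doc["points"]))
    raise DfmError(f"{where}: unknown driver kind {kind!r}")


def model_from_document(doc: dict, source: str = "<document>") -> DFModel:
    """Build and validate a DFModel from an already-parsed document."""
    if not isinstance(doc, dict):
        raise DfmError(f"{source}: model document must be a mapping")
    _reject_unknown(doc, _MODEL_KEYS, source)
    if doc.get("format_version") != FORMAT_VERSION:
        raise DfmError(
            f"{source}: format_version must be {FORMAT_VERSION}, got {doc.get('format_version')!r}"
        )
    variables = tuple(_variable_from_doc(v) for v in doc.get("variables", ()))
    symbols = SymbolTable(variables)
    rules = tuple(parse_rule(text, symbols) for text in doc.get("rules", ()))
    drivers = {
        name: _driver_from_doc(d, f"{source}: driver for {name!r}")
        for name, d in (doc.get("drivers") or {}).items()
    }
    edges = tuple((e[0], e[1], e[2]) for e in doc.get("edges", ()))
    model = DFModel(
        name=doc.get("name", "unnamed"),
        description=doc.get("description", ""),
        variables=variables,
        rules=rules,
        drivers=drivers,
        t_max=int(doc.get("t_max", 20)),
        graph_edges=edges,
    )
    diags = validate(model)
    if diags:
        raise ModelValidationError(diags)
    return model


def load_model(path: str | Path) -> DFModel:
    """Load and validate a model file; raises with diagnostics on failure."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise DfmError(f"{path}: YAML syntax error: {exc}") from exc
    return model_from_document(doc, source=str(path))


def _mf_to_doc(mf: MembershipFunction) -> dict:
    return {"kind": mf.kind, "points": [float(p) for p in mf.points]}


def _variable_to_doc(v: LinguisticVariable) -> dict:
    doc: dict = {"name": v.name, "role": v.role}
    if v.universe != (0.0, 1.0):
        doc["universe"] = [v.universe[0], v.universe[1]]
    if v.initial != 0.0:
        doc["initial"] = v.initial
    if v.terms:
        doc["terms"] = [
            {"label": t.label, "mf": _mf_to_doc(t.mf), "setpoint": t.setpoint}
            for t in v.terms
        ]
    if v.display_name:
        doc["display_name"] = v.display_name
    if v.pathway:
        doc["pathway"] = v.pathway
    if v.constant:
        doc["constant"] = True
    return doc


def _driver_to_doc(d: Driver) -> dict:
    if d.kind == "constant":
        return {"kind": "constant", "value": d.value}
    if d.kind == "linear":
        return {"kind": "linear", "start": d.start, "end": d.end}
    return {"kind": "piecewise", "points": [[t, v] for t, v in d.points]}


def model_to_document(model: DFModel) -> dict:
    """Canonical document form: variables sorted by name, rules normalized
    through parse -> render and sorted, so equal models serialize equally."""
    diags = validate(model)
    if diags:
        raise ModelValidationError(diags)
    doc: dict = {
        "format_version": FORMAT_VERSION,
        "name": model.name,
        "t_max": model.t_max,
        "variables": [_variable_to_doc(v) for v in sorted(model.variables, key=lambda v: v.name)],
        "rules": sorted(r.render() for r in model.rules),
    }
    if model.description:
        doc["description"] = model.description
    if model.drivers:
        doc["drivers"] = {n: _driver_to_doc(d) for n, d in sorted(model.drivers.items())}
    if model.graph_edges:
        doc["edges"] = [list(e) for e in sorted(model.graph_edges)]
    return doc


def write_model(model: DFModel, path: str | Path) -> None:
    """Serialize a valid model canonically (refuses invalid models)."""
    doc = model_to_document(model)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True, default_flow_style=None))


# --- screening problem definitions ----------------------------------------

@dataclass(frozen=True)
class ProblemDefinition:
    """What to screen: the perturbable genome, the evaluation step, and the
    experimental condition.

    ``perturbable`` fixes the genome: position i of a ternary treatment
    genome refers to ``perturbable[i]`` (0 = untouched, 1 = forced to its
    "low" setpoint, 2 = forced to its "high" setpoint, for the whole
    simulation). ``delta`` is the step at which objective state changes are
    measured. ``condition`` pins input variables to a term for the whole run
    (e.g. PKA low vs high). ``objectives`` selects the 2-objective
    (apoptosis, complexity) or 3-objective (+ necrosis) formulation.
    """

    perturbable: tuple[str, ...]
    delta: int = 13
    objectives: str = "3obj"
    condition: dict = field(default_factory=dict)
    apoptosis_variable: str = "Apoptosis"
    necrosis_variable: str = "Necrosis"
    model: DFModel | None = None

    def __post_init__(self):
        object.__setattr__(self, "perturbable", tuple(self.perturbable))
        if self.objectives not in ("2obj", "3obj"):
            raise DfmError(f"objectives must be '2obj' or '3obj', got {self.objectives!r}")
        if len(set(self.perturbable)) != len(self.perturbable):
            raise DfmError("perturbable variable list contains duplicates")
        if self.model is not None:
            missing = [n for n in self.perturbable if n not in self.model.variable_names]
            if missing:
                raise DfmError(f"perturbable variables not in model: {missing}")
            if self.delta > self.model.t_max:
                raise DfmError(
                    f"delta={self.delta} exceeds model t_max={self.model.t_max}"
                )

    @property
    def genome_length(self) -> int:
        return len(self.perturbable)

    @property
    def n_objectives(self) -> int:
        return 2 if self.objectives == "2obj" else 3

    def attach(self, model: DFModel) -> "ProblemDefinition":
        """Return a copy of this definition bound to a concrete model."""
        return replace(self, model=model)

    def require_model(self) -> DFModel:
        if self.model is None:
            raise ModelNotAttachedError(
                "this problem definition has no model attached; transcribe the "
                "rule base into the model format and call .attach(model)"
            )
        return self.model


def kras_problem(objectives: str = "3obj", condition: dict | None = None) -> ProblemDefinition:
    """Screening scaffold for the K-ras programmed-cell-death model.

    16 perturbable components in fixed genome order and Δ = 13. The rule
    base is not bundled (it is distributed separately under GPL); attach a
    transcribed model before simulating.
    """
    return ProblemDefinition(
        perturbable=KRAS_PERTURBABLE,
        delta=13,
        objectives=objectives,
        condition=dict(condition or {}),
    )


def load_problem(path: str | Path) -> ProblemDefinition:
    """Load a problem-definition file; resolves a relative model reference."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise DfmError(f"{path}: YAML syntax error: {exc}") from exc
    if not isinstance(doc, dict):
        raise DfmError(f"{path}: problem document must be a mapping")
    _reject_unknown(doc, _PROBLEM_KEYS, str(path))
    if doc.get("format_version") != FORMAT_VERSION:
        raise DfmError(f"{path}: format_version must be {FORMAT_VERSION}")
    model = None
    if doc.get("model"):
        model_path = Path(doc["model"])
        if not model_path.is_absolute():
            model_path = path.parent / model_path
        model = load_model(model_path)
    return ProblemDefinition(
        perturbable=tuple(doc["perturbable"]),
        delta=int(doc.get("delta", 13)),
        objectives=doc.get("objectives", "3obj"),
        condition=dict(doc.get("condition") or {}),
        apoptosis_variable=doc.get("apoptosis_variable", "Apoptosis"),
        necrosis_variable=doc.get("necrosis_variable", "Necrosis"),
        model=model,
    )


def write_problem(problem: ProblemDefinition, path: str | Path,
                  model_ref: str | None = None) -> None:
    doc: dict = {
        "format_version": FORMAT_VERSION,
        "kind": "problem",
        "perturbable": list(problem.perturbable),
        "delta": problem.delta,
        "objectives": problem.objectives,
        "apoptosis_variable": problem.apoptosis_variable,
        "necrosis_variable": problem.necrosis_variable,
    }
    if problem.condition:
        doc["condition"] = dict(problem.condition)
    if model_ref:
        doc["model"] = model_ref
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True, default_flow_style=None))
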