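"""Synchronous time-stepped simulation of a dynamic fuzzy model (DFM).

A DFM is a network of fuzzy inference systems: at every discrete step
``t -> t+1`` all non-input variables are updated simultaneously by 0-order
Sugeno inference evaluated on the complete state at ``t``; input variables
follow user-supplied time functions (drivers). An elementary perturbation
``(L, F, t_b, t_e)`` forces variable ``L`` to follow ``F`` on the closed
step interval ``[t_b, t_e]``, with inference disabled for ``L`` there; a
treatment is a list of such forcings. Precedence is
perturbation > driver > inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import EvaluationError, ModelValidationError, PerturbationError
from .fuzzy import FuzzyRule, LinguisticVariable, SymbolTable, sugeno_infer

logger = logging.getLogger(__name__)

__all__ = [
    "Driver",
    "DFModel",
    "Perturbation",
    "GlobalPerturbation",
    "Trajectory",
    "simulate",
    "validate",
    "state_change",
]


@dataclass(frozen=True)
class Driver:
    """Time function for an input variable, as a named parametric form.

    kinds:
      ``constant``   — value ``value`` at every step;
      ``linear``     — ramp from ``start`` at t=0 to ``end`` at t=t_max;
      ``piecewise``  — linear interpolation through ``points`` [(t, v), ...],
                       held flat outside the listed span.
    """

    kind: str
    value: float | None = None
    start: float | None = None
    end: float | None = None
    points: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.kind not in ("constant", "linear", "piecewise"):
            raise ValueError(f"unknown driver kind {self.kind!r}")
        if self.kind == "constant" and self.value is None:
            raise ValueError("constant driver needs 'value'")
        if self.kind == "linear" and (self.start is None or self.end is None):
            raise ValueError("linear driver needs 'start' and 'end'")
        if self.kind == "piecewise":
            pts = tuple((float(t), float(v)) for t, v in self.points)
            if len(pts) < 2:
                raise ValueError("piecewise driver needs >= 2 points")
            if any(b[0] <= a[0] for a, b in zip(pts, pts[1:])):
                raise ValueError("piecewise driver times must be strictly increasing")
            object.__setattr__(self, "points", pts)

    def at(self, t: int, t_max: int) -> float:
        if self.kind == "constant":
            return float(self.value)
        if self.kind == "linear":
            frac = t / t_max if t_max else 0.0
            return float(self.start) + (float(self.end) - float(self.start)) * frac
        ts = [p[0] for p in self.points]
        vs = [p[1] for p in self.points]
        return float(np.interp(t, ts, vs))


@dataclass(frozen=True)
class DFModel:
    """The full fuzzy network: variables, rules, drivers, topology.

    ``graph_edges`` are signed directed interactions ``(source, target,
    sign)`` with sign ``positive``/``negative``; pathway labels live on the
    variables. ``t_max`` is the number of unit time steps simulated.
    """

    name: str
    variables: tuple[LinguisticVariable, ...]
    rules: tuple[FuzzyRule, ...]
    drivers: Mapping[str, Driver]
    t_max: int = 20
    graph_edges: tuple[tuple[str, str, str], ...] = ()
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "rules", tuple(self.rules))
        object.__setattr__(self, "drivers", dict(self.drivers))
        object.__setattr__(self, "graph_edges", tuple(tuple(e) for e in self.graph_edges))

    @property
    def symbols(self) -> SymbolTable:
        return SymbolTable(self.variables)

    def variable(self, name: str) -> LinguisticVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(f"model has no variable {name!r}")

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def rules_for(self, variable: str) -> tuple[FuzzyRule, ...]:
        return tuple(r for r in self.rules if r.variable == variable)

    def interaction_graph(self):
        """Signed directed interaction graph as a networkx DiGraph."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.variable_names)
        for src, dst, sign in self.graph_edges:
            g.add_edge(src, dst, sign=sign)
        return g


@dataclass(frozen=True)
class Perturbation:
    """Force variable ``variable`` to follow ``function`` on steps
    [t_begin, t_end] (closed); inference is disabled for it there."""

    variable: str
    function: Callable[[int], float]
    t_begin: int
    t_end: int

    @staticmethod
    def constant(variable: str, level: float, t_begin: int, t_end: int) -> "Perturbation":
        return Perturbation(variable, lambda t, _v=float(level): _v, t_begin, t_end)


@dataclass(frozen=True)
class GlobalPerturbation:
    """An ordered list of elementary perturbations (a candidate treatment)."""

    perturbations: tuple[Perturbation, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "perturbations", tuple(self.perturbations))

    def __len__(self) -> int:
        return len(self.perturbations)

    def __iter__(self):
        return iter(self.perturbations)


@dataclass(frozen=True)
class Trajectory:
    """States of every variable over t = 0..t_max."""

    times: np.ndarray
    states: Mapping[str, np.ndarray]
    model_name: str = ""

    def __getitem__(self, variable: str) -> np.ndarray:
        return self.states[variable]

    @property
    def t_max(self) -> int:
        return int(self.times[-1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame with columns (time, variable, state)."""
        rows = []
        for name, series in self.states.items():
            rows.append(pd.DataFrame({"time": self.times, "variable": name, "state": series}))
        return pd.concat(rows, ignore_index=True)


def validate(model: DFModel) -> list[str]:
    """Return all structural diagnostics for ``model`` (empty list = valid).

    Checks, among others: every non-input non-constant variable has at least
    one rule targeting it; inputs never appear in consequents and outputs
    never in antecedents; every input has a driver (or is constant at its
    initial state, which is allowed and noted as valid); rules only
    reference declared variables/terms (enforced at parse time); graph nodes
    are declared variables; term setpoints sit at maximal membership.
    """
    diags: list[str] = []
    names = [v.name for v in model.variables]
    seen: set[str] = set()
    for n in names:
        if n in seen:
            diags.append(f"duplicate variable name {n!r}")
        seen.add(n)
    if model.t_max < 1:
        diags.append(f"t_max must be >= 1, got {model.t_max}")

    by_name = {v.name: v for v in model.variables}
    ruled = {r.variable for r in model.rules}
    for v in model.variables:
        labels = set()
        for t in v.terms:
            if t.label in labels:
                diags.append(f"variable {v.name!r}: duplicate term label {t.label!r}")
            labels.add(t.label)
            lo, hi = v.universe
            if not (lo <= t.setpoint <= hi):
                diags.append(
                    f"variable {v.name!r}: setpoint {t.setpoint} of term {t.label!r} "
                    f"outside universe [{lo}, {hi}]"
                )
            else:
                peak = max(t.mf(x) for x in np.linspace(lo, hi, 201))
                if t.mf(t.setpoint) < peak - 1e-9:
                    diags.append(
                        f"variable {v.name!r}: setpoint {t.setpoint} of term {t.label!r} "
                        f"does not attain maximal membership"
                    )
        if not (v.universe[0] <= v.initial <= v.universe[1]):
            diags.append(f"variable {v.name!r}: initial state {v.initial} outside universe")
        if v.role == "input" and v.name in ruled:
            diags.append(f"input variable {v.name!r} appears as a rule consequent")
        if v.role not in ("input",) and not v.constant and v.name not in ruled:
            diags.append(f"variable {v.name!r} has no rule targeting it and is not constant")

    for r in model.rules:
        if r.variable not in by_name:
            diags.append(f"rule targets undeclared variable {r.variable!r}")
            continue
        for atom in r.atoms():
            if atom.variable not in by_name:
                diags.append(f"rule for {r.variable!r} references undeclared variable {atom.variable!r}")
            elif by_name[atom.variable].role == "output":
                diags.append(
                    f"output variable {atom.variable!r} appears in the antecedent of a rule for {r.variable!r}"
                )
        lo, hi = by_name[r.variable].universe
        if not (lo <= r.value <= hi):
            diags.append(f"rule consequent {r.value} outside universe of {r.variable!r}")

    for name in model.drivers:
        if name not in by_name:
            diags.append(f"driver for undeclared variable {name!r}")
        elif by_name[name].role != "input":
            diags.append(f"driver attached to non-input variable {name!r}")

    for src, dst, sign in model.graph_edges:
        for node in (src, dst):
            if node not in by_name:
                diags.append(f"graph edge references undeclared variable {node!r}")
        if sign not in ("positive", "negative"):
            diags.append(f"graph edge ({src!r}, {dst!r}) has unknown sign {sign!r}")
    return diags


def _validate_perturbation(model: DFModel, pi: GlobalPerturbation) -> None:
    by_var: dict[str, list[Perturbation]] = {}
    for p in pi:
        if p.variable not in model.variable_names:
            raise PerturbationError(f"perturbed variable {p.variable!r} not in model")
        if not (0 <= p.t_begin < p.t_end <= model.t_max):
            raise PerturbationError(
                f"perturbation of {p.variable!r}: need 0 <= t_begin < t_end <= t_max, "
                f"got [{p.t_begin}, {p.t_end}] with t_max={model.t_max}"
            )
        by_var.setdefault(p.variable, []).append(p)
    for var, ps in by_var.items():
        ps = sorted(ps, key=lambda p: p.t_begin)
        for a, b in zip(ps, ps[1:]):
            if b.t_begin <= a.t_end:
                raise PerturbationError(
                    f"overlapping perturbations of {var!r}: "
                    f"[{a.t_begin},{a.t_end}] and [{b.t_begin},{b.t_end}]"
                )


def _clamp(x: float, lo: float, hi: float) -> float:
    return lo if x < lo else hi if x > hi else x


def simulate(model: DFModel, pi: GlobalPerturbation | None = None,
             check: bool = True) -> Trajectory:
    """Run the DFM for t = 0..t_max under global perturbation ``pi``.

    Fully synchronous: every non-input variable's next state is the Sugeno
    inference of its rules evaluated on the complete state at the previous
    step. Deterministic: a pure function of (model, pi). Values produced by
    drivers and perturbation functions are clamped to each variable's
    universe. ``check=False`` skips re-validating a model already known to
    be valid (screening evaluates thousands of perturbations of one model).
    """
    if check:
        diags = validate(model)
        if diags:
            raise ModelValidationError(diags)
    pi = pi if pi is not None else GlobalPerturbation()
    _validate_perturbation(model, pi)

    symbols = model.symbols
    names = model.variable_names
    t_max = model.t_max
    variables = {v.name: v for v in model.variables}
    rules_by_var = {n: model.rules_for(n) for n in names}
    active: dict[str, list[Perturbation]] = {}
    for p in pi:
        active.setdefault(p.variable, []).append(p)

    def forcing(name: str, t: int) -> float | None:
        for p in active.get(name, ()):
            if p.t_begin <= t <= p.t_end:
                return float(p.function(t))
        return None

    out = {n: np.empty(t_max + 1, dtype=float) for n in names}
    state: dict[str, float] = {}
    zero_fire_logged = False
    for n in names:
        v = variables[n]
        x = v.initial
        if v.role == "input" and n in model.drivers:
            x = model.drivers[n].at(0, t_max)
        f = forcing(n, 0)
        if f is not None:
            x = f
        state[n] = _clamp(x, *v.universe)
        out[n][0] = state[n]

    for t in range(t_max):
        nxt: dict[str, float] = {}
        for n in names:
            v = variables[n]
            f = forcing(n, t + 1)
            if f is not None:
                x = f
            elif v.role == "input":
                x = model.drivers[n].at(t + 1, t_max) if n in model.drivers else state[n]
            elif v.constant or not rules_by_var[n]:
                x = state[n]
            else:
                try:
                    x = sugeno_infer(rules_by_var[n], state, symbols, current=state[n])
                except EvaluationError as exc:
                    raise EvaluationError(f"updating {n!r} at step {t + 1}: {exc}") from exc
                if x == state[n] and not zero_fire_logged:
                    # may be a genuine fixed point or the zero-firing hold;
                    # distinguishing is not worth a second inference pass
                    zero_fire_logged = True
                    logger.debug("variable %r held its state at step %d", n, t + 1)
            nxt[n] = _clamp(x, *v.universe)
        state = nxt
        for n in names:
            out[n][t + 1] = state[n]

    return Trajectory(times=np.arange(t_max + 1), states=out, model_name=model.name)


def state_change(traj: Trajectory, variable: str, delta: int) -> float:
    """Change of a variable over the evaluation window: x(Δ) − x(0)."""
    if variable not in traj.states:
        raise KeyError(f"trajectory has no variable {variable!r}")
    if not (0 <= delta <= traj.t_max):
        raise ValueError(f"delta must be in [0, {traj.t_max}], got {delta}")
    series = traj.states[variable]
    return float(series[delta] - series[0])
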