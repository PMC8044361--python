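"""Fuzzy primitives: membership functions, linguistic variables, rule
parsing and 0-order Sugeno inference.

Each model component is a *linguistic variable* whose crisp state lives on a
bounded universe (by default ``[0, 1]``) and is described qualitatively by
*linguistic terms* ("low", "high", ...), each with a piecewise-linear
membership function. Interactions are conditional rules of the form::

    IF (Glucose IS high) AND (NOT (ATP IS low)) THEN (Glycolysis IS 1.0)

Antecedents combine atoms with AND (minimum), OR (maximum) and NOT
(complement); consequents are crisp constants, so inference is 0-order
Sugeno: the next state of a variable is the firing-strength-weighted average
of the consequents of all rules that target it.

Rule grammar (EBNF)::

    rule       = "IF" expr "THEN" "(" NAME "IS" value ")" ;
    expr       = or_expr ;
    or_expr    = and_expr { "OR" and_expr } ;
    and_expr   = not_expr { "AND" not_expr } ;
    not_expr   = "NOT" not_expr | "(" expr ")" | atom ;
    atom       = "(" NAME "IS" NAME ")" | NAME "IS" NAME ;
    value      = NUMBER | NAME ;       (* a term label resolves to its setpoint *)

``NAME`` is any run of characters excluding whitespace and parentheses that
is not a keyword; identifiers like ``Ca2+`` and ``N-glycosylation`` are
legal. Keywords are case-sensitive upper-case.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

from .errors import EvaluationError, RuleParseError

__all__ = [
    "MembershipFunction",
    "LinguisticTerm",
    "LinguisticVariable",
    "Atom",
    "Not",
    "And",
    "Or",
    "FuzzyRule",
    "parse_rule",
    "firing_strength",
    "sugeno_infer",
]

_MF_KINDS = ("triangular", "trapezoidal", "crisp")
_N_POINTS = {"triangular": 3, "trapezoidal": 4, "crisp": 1}


@dataclass(frozen=True)
class MembershipFunction:
    """Piecewise-linear membership function on a bounded universe.

    ``triangular`` takes breakpoints (a, b, c): foot, peak, foot.
    ``trapezoidal`` takes (a, b, c, d): foot, shoulder, shoulder, foot.
    ``crisp`` takes a single point with degree 1 there and 0 elsewhere.
    Degenerate edges (equal adjacent breakpoints) are vertical: the peak
    side wins at the shared abscissa, so e.g. triangular(0, 0, 0.5) has
    degree 1 at x = 0.
    """

    kind: str
    points: tuple[float, ...]
    universe: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if self.kind not in _MF_KINDS:
            raise ValueError(f"unknown membership kind {self.kind!r}")
        pts = tuple(float(p) for p in self.points)
        if len(pts) != _N_POINTS[self.kind]:
            raise ValueError(
                f"{self.kind} membership needs {_N_POINTS[self.kind]} breakpoints, got {len(pts)}"
            )
        if any(b < a for a, b in zip(pts, pts[1:])):
            raise ValueError(f"breakpoints must be non-decreasing: {pts}")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "universe", (float(self.universe[0]), float(self.universe[1])))

    def __call__(self, x: float) -> float:
        """Membership degree of crisp value ``x`` (clamped to the universe)."""
        lo, hi = self.universe
        x = min(max(float(x), lo), hi)
        if self.kind == "crisp":
            return 1.0 if x == self.points[0] else 0.0
        if self.kind == "triangular":
            a, b, c = self.points
            lb, rb = b, b
        else:
            a, lb, rb, c = self.points
        if x < a or x > c:
            return 0.0
        if x < lb:
            return (x - a) / (lb - a) if lb > a else 1.0
        if x > rb:
            return (c - x) / (c - rb) if c > rb else 1.0
        return 1.0


@dataclass(frozen=True)
class LinguisticTerm:
    """A qualitative state of a variable ("low", "high", ...).

    ``setpoint`` is the crisp value a perturbation forces when this term is
    imposed on the variable; it should attain the term's maximal membership.
    """

    label: str
    mf: MembershipFunction
    setpoint: float

    def __post_init__(self):
        object.__setattr__(self, "setpoint", float(self.setpoint))


_ROLES = ("input", "inner", "output")


@dataclass(frozen=True)
class LinguisticVariable:
    """A model component: a named state on a universe with its terms.

    Roles: ``input`` variables are driven from outside and appear only in
    rule antecedents; ``output`` variables are read-outs and appear only in
    consequents; ``inner`` variables may appear on both sides. ``constant``
    marks a rule-less variable that simply holds its initial state.
    """

    name: str
    role: str
    terms: tuple[LinguisticTerm, ...] = ()
    universe: tuple[float, float] = (0.0, 1.0)
    initial: float = 0.0
    display_name: str | None = None
    pathway: str | None = None
    constant: bool = False

    def __post_init__(self):
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "universe", (float(self.universe[0]), float(self.universe[1])))
        object.__setattr__(self, "initial", float(self.initial))

    def term(self, label: str) -> LinguisticTerm:
        for t in self.terms:
            if t.label == label:
                return t
        raise KeyError(f"variable {self.name!r} has no term {label!r}")

    @property
    def term_labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.terms)


# --- antecedent expression tree -------------------------------------------

@dataclass(frozen=True)
class Atom:
    variable: str
    term: str

    def degree(self, state: Mapping[str, float], terms: Mapping[tuple[str, str], LinguisticTerm]) -> float:
        if self.variable not in state:
            raise EvaluationError(f"no state for variable {self.variable!r}")
        return terms[(self.variable, self.term)].mf(state[self.variable])

    def render(self) -> str:
        return f"({self.variable} IS {self.term})"


@dataclass(frozen=True)
class Not:
    operand: "Expr"

    def degree(self, state, terms) -> float:
        return 1.0 - self.operand.degree(state, terms)

    def render(self) -> str:
        return f"(NOT {self.operand.render()})"


@dataclass(frozen=True)
class And:
    operands: tuple["Expr", ...]

    def degree(self, state, terms) -> float:
        return min(op.degree(state, terms) for op in self.operands)

    def render(self) -> str:
        return "(" + " AND ".join(op.render() for op in self.operands) + ")"


@dataclass(frozen=True)
class Or:
    operands: tuple["Expr", ...]

    def degree(self, state, terms) -> float:
        return max(op.degree(state, terms) for op in self.operands)

    def render(self) -> str:
        return "(" + " OR ".join(op.render() for op in self.operands) + ")"


Expr = Union[Atom, Not, And, Or]


@dataclass(frozen=True)
class FuzzyRule:
    """IF <antecedent> THEN (<variable> IS <crisp value>)."""

    antecedent: Expr
    variable: str
    value: float

    def __post_init__(self):
        object.__setattr__(self, "value", float(self.value))

    def render(self) -> str:
        body = self.antecedent.render()
        # canonical form never double-wraps a single atom
        return f"IF {body} THEN ({self.variable} IS {self.value!r})"

    def atoms(self) -> list[Atom]:
        out: list[Atom] = []
        stack: list[Expr] = [self.antecedent]
        while stack:
            node = stack.pop()
            if isinstance(node, Atom):
                out.append(node)
            elif isinstance(node, Not):
                stack.append(node.operand)
            else:
                stack.extend(node.operands)
        return out


# --- parsing ---------------------------------------------------------------

_KEYWORDS = {"IF", "THEN", "IS", "AND", "OR", "NOT"}
_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


class _Tokens:
    def __init__(self, text: str):
        self.items = _TOKEN_RE.findall(text)
        self.pos = 0
        self.text = text

    def peek(self) -> str | None:
        return self.items[self.pos] if self.pos < len(self.items) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise RuleParseError(f"unexpected end of rule: {self.text!r}")
        self.pos += 1
        return tok

    def expect(self, tok: str) -> None:
        got = self.next()
        if got != tok:
            raise RuleParseError(f"expected {tok!r} but found {got!r} in {self.text!r}")


class SymbolTable:
    """Variable/term lookup used while parsing and evaluating rules."""

    def __init__(self, variables: Iterable[LinguisticVariable]):
        self.variables: dict[str, LinguisticVariable] = {v.name: v for v in variables}
        self.terms: dict[tuple[str, str], LinguisticTerm] = {
            (v.name, t.label): t for v in self.variables.values() for t in v.terms
        }

    def check_atom(self, var: str, term: str, text: str) -> None:
        if var not in self.variables:
            raise RuleParseError(f"unknown variable {var!r} in {text!r}")
        if (var, term) not in self.terms:
            raise RuleParseError(f"unknown term {term!r} for variable {var!r} in {text!r}")


def _parse_name(toks: _Tokens, what: str) -> str:
    tok = toks.next()
    if tok in _KEYWORDS or tok in ("(", ")"):
        raise RuleParseError(f"expected {what} but found {tok!r} in {toks.text!r}")
    return tok


def _parse_atom_body(toks: _Tokens, symbols: SymbolTable) -> Atom:
    var = _parse_name(toks, "a variable name")
    toks.expect("IS")
    term = _parse_name(toks, "a term label")
    symbols.check_atom(var, term, toks.text)
    return Atom(var, term)


def _parse_primary(toks: _Tokens, symbols: SymbolTable) -> Expr:
    tok = toks.peek()
    if tok == "NOT":
        toks.next()
        return Not(_parse_primary(toks, symbols))
    if tok == "(":
        toks.next()
        inner = _parse_or(toks, symbols)
        toks.expect(")")
        return inner
    return _parse_atom_body(toks, symbols)


def _parse_and(toks: _Tokens, symbols: SymbolTable) -> Expr:
    ops = [_parse_primary(toks, symbols)]
    while toks.peek() == "AND":
        toks.next()
        ops.append(_parse_primary(toks, symbols))
    return ops[0] if len(ops) == 1 else And(tuple(ops))


def _parse_or(toks: _Tokens, symbols: SymbolTable) -> Expr:
    ops = [_parse_and(toks, symbols)]
    while toks.peek() == "OR":
        toks.next()
        ops.append(_parse_and(toks, symbols))
    return ops[0] if len(ops) == 1 else Or(tuple(ops))


def parse_rule(text: str, symbols: SymbolTable) -> FuzzyRule:
    """Parse one rule string against a model symbol table.

    The consequent value may be a numeric literal or a term label of the
    consequent variable, which resolves to that term's setpoint. Raises
    :class:`RuleParseError` naming the offending token on any violation.
    """
    toks = _Tokens(text)
    toks.expect("IF")
    if toks.peek() == "THEN":
        raise RuleParseError(f"empty antecedent in {text!r}")
    antecedent = _parse_or(toks, symbols)
    toks.expect("THEN")
    paren = toks.peek() == "("
    if paren:
        toks.next()
    var = _parse_name(toks, "a consequent variable")
    if var not in symbols.variables:
        raise RuleParseError(f"unknown variable {var!r} in {text!r}")
    toks.expect("IS")
    value_tok = toks.next()
    if _NUMBER_RE.match(value_tok):
        value = float(value_tok)
    else:
        if (var, value_tok) not in symbols.terms:
            raise RuleParseError(
                f"consequent {value_tok!r} is neither a number nor a term of {var!r} in {text!r}"
            )
        value = symbols.terms[(var, value_tok)].setpoint
    if paren:
        toks.expect(")")
    if toks.peek() is not None:
        raise RuleParseError(f"trailing tokens after rule: {toks.peek()!r} in {text!r}")
    lo, hi = symbols.variables[var].universe
    if not (lo <= value <= hi):
        raise RuleParseError(
            f"consequent value {value} outside universe [{lo}, {hi}] of {var!r} in {text!r}"
        )
    return FuzzyRule(antecedent=antecedent, variable=var, value=value)


# --- inference -------------------------------------------------------------

def firing_strength(rule: FuzzyRule, state: Mapping[str, float], symbols: SymbolTable) -> float:
    """Degree to which the rule's antecedent holds in ``state``.

    AND is the minimum t-norm, OR the maximum s-norm, NOT the standard
    complement; atoms evaluate to term membership degrees, so the result is
    in [0, 1].
    """
    return rule.antecedent.degree(state, symbols.terms)


def sugeno_infer(
    rules: Sequence[FuzzyRule],
    state: Mapping[str, float],
    symbols: SymbolTable,
    current: float | None = None,
) -> float:
    """0-order Sugeno update for one variable.

    Returns the firing-strength-weighted average of the rules' crisp
    consequents, ``Σ w_i c_i / Σ w_i``. If no rule fires at all the weighted
    average is undefined; the variable's current state (``current``, falling
    back to the consequent variable's stored state) is returned unchanged so
    the dynamics stay well-defined.
    """
    if not rules:
        raise ValueError("sugeno_infer needs at least one rule")
    var = rules[0].variable
    if any(r.variable != var for r in rules):
        raise ValueError("all rules passed to sugeno_infer must share one consequent variable")
    num = 0.0
    den = 0.0
    for r in rules:
        w = firing_strength(r, state, symbols)
        num += w * r.value
        den += w
    if den == 0.0:
        if current is None:
            if var not in state:
                raise EvaluationError(f"no state for variable {var!r}")
            current = state[var]
        return float(current)
    return num / den
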