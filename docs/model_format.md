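# Model file format

Models and screening problems are single-document YAML files restricted to
a JSON-compatible subset (plain scalars, lists, maps), so any JSON document
with the same structure is also accepted. A required `format_version` key
(currently `1`) makes schema changes detectable; unknown top-level keys are
rejected. Three examples ship with the package under
`src/dfmscreen/examples/`.

## Model documents

```yaml
format_version: 1
name: toy-chain            # required
description: free text     # optional
t_max: 20                  # simulation steps (default 20)
variables:
- name: Glucose            # identifier: no whitespace/parentheses
  role: input              # input | inner | output
  universe: [0.0, 1.0]     # optional, default [0, 1]
  initial: 1.0             # optional, default 0.0
  display_name: "Ca^2+"    # optional pretty name for figures
  pathway: metabolism      # optional label, used by the pathway filter
  constant: false          # optional; a rule-less variable that holds state
  terms:
  - label: low
    mf: {kind: triangular, points: [0.0, 0.0, 0.5]}
    setpoint: 0.0          # optional; defaults: low -> universe min,
                           # high -> universe max, otherwise the mf peak
rules:
- IF (Glucose IS high) THEN (Glycolysis IS 1.0)
drivers:                   # one per input variable
  Glucose: {kind: constant, value: 1.0}
  # {kind: linear, start: 1.0, end: 0.0}             # ramp over 0..t_max
  # {kind: piecewise, points: [[0, 1.0], [13, 0.5], [26, 0.0]]}
edges:                     # signed interaction graph (used by filters/plots)
- [Glucose, Glycolysis, positive]
```

Membership kinds: `triangular` (3 breakpoints: foot, peak, foot),
`trapezoidal` (4: foot, shoulder, shoulder, foot), `crisp` (1 point).
Breakpoints must be non-decreasing; equal adjacent breakpoints give a
vertical edge with full membership at the shared abscissa.

Structural rules enforced at load time: input variables never appear in a
rule consequent, output variables never in an antecedent; every non-input,
non-constant variable has at least one rule targeting it; every input has a
driver; rule references and graph nodes must be declared variables; term
setpoints must attain their term's maximal membership.

`write_model` emits a canonical serialization (variables sorted by name,
rule strings normalized through the parser and sorted), so two structurally
equal models serialize to identical bytes.

## Rule grammar (EBNF)

```
rule     = "IF" expr "THEN" "(" NAME "IS" value ")" ;
expr     = or_expr ;
or_expr  = and_expr { "OR" and_expr } ;
and_expr = not_expr { "AND" not_expr } ;
not_expr = "NOT" not_expr | "(" expr ")" | atom ;
atom     = "(" NAME "IS" NAME ")" | NAME "IS" NAME ;
value    = NUMBER | NAME ;   (* term label -> that term's setpoint *)
```

Precedence is NOT > AND > OR; keywords are upper-case. `NAME` is any run of
characters without whitespace or parentheses that is not a keyword, so
identifiers like `Ca2+` and `N-glycosylation` are legal.

## Problem documents

```yaml
format_version: 1
kind: problem
model: model.yaml          # optional path, relative to this file
perturbable: [Target0, Target1, ...]   # genome order, position i = entry i
delta: 13                  # evaluation step for objective changes
objectives: 3obj           # 2obj | 3obj
condition: {PKA: high}     # optional input pinning for the whole run
apoptosis_variable: Apoptosis   # optional, defaults shown
necrosis_variable: Necrosis
```
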