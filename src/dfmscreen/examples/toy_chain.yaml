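format_version: 1
name: toy-chain
description: >
  Three-component chain: a constant glucose supply drives glycolysis, which
  produces ATP. Smallest useful example of the model format.
t_max: 20
variables:
- name: Glucose
  role: input
  initial: 1.0
  terms:
  - label: low
    mf: {kind: triangular, points: [0.0, 0.0, 0.5]}
  - label: high
    mf: {kind: triangular, points: [0.5, 1.0, 1.0]}
- name: Glycolysis
  role: inner
  initial: 0.0
  pathway: metabolism
  terms:
  - label: low
    mf: {kind: triangular, points: [0.0, 0.0, 0.5]}
  - label: high
    mf: {kind: triangular, points: [0.5, 1.0, 1.0]}
- name: ATP
  role: output
  initial: 0.0
  terms:
  - label: low
    mf: {kind: triangular, points: [0.0, 0.0, 0.5]}
  - label: high
    mf: {kind: triangular, points: [0.5, 1.0, 1.0]}
rules:
- IF (Glucose IS high) THEN (Glycolysis IS 1.0)
- IF (Glucose IS low) THEN (Glycolysis IS 0.0)
- IF (Glycolysis IS high) THEN (ATP IS 1.0)
- IF (Glycolysis IS low) THEN (ATP IS 0.0)
drivers:
  Glucose: {kind: constant, value: 1.0}
edges:
- [Glucose, Glycolysis, positive]
- [Glycolysis, ATP, positive]
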