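format_version: 1
name: feedback-loop
description: >
  Negative feedback between two inner components, driven by a constant
  signal. Demonstrates NOT/OR antecedents and oscillatory dynamics.
t_max: 20
variables:
- name: Signal
  role: input
  initial: 0.8
  terms:
  - label: low
    mf: {kind: triangular, points: [0.0, 0.0, 0.5]}
  - label: high
    mf: {kind: triangular, points: [0.5, 1.0, 1.0]}
- name: A
  role: inner
  initial: 0.0
  pathway: loop
  terms:
  - label: low
    mf: {kind: triangular, points: [0.0, 0.0, 0.5]}
  - label: high
    mf: {kind: triangular, points: [0.5, 1.0, 1.0]}
- name: B
  role: inner
  initial: 0.0
  pathway: loop
  terms:
  - label: low
    mf: {kind: triangular, points: [0.0, 0.0, 0.5]}
  - label: high
    mf: {kind: triangular, points: [0.5, 1.0, 1.0]}
- name: Out
  role: output
  initial: 0.0
  terms:
  - label: low
    mf: {kind: triangular, points: [0.0, 0.0, 0.5]}
  - label: high
    mf: {kind: triangular, points: [0.5, 1.0, 1.0]}
rules:
- IF (Signal IS high) AND (NOT (B IS high)) THEN (A IS 1.0)
- IF (Signal IS low) OR (B IS high) THEN (A IS 0.0)
- IF (A IS high) THEN (B IS 1.0)
- IF (A IS low) THEN (B IS 0.0)
- IF (B IS high) THEN (Out IS 1.0)
- IF (B IS low) THEN (Out IS 0.0)
drivers:
  Signal: {kind: constant, value: 0.8}
edges:
- [Signal, A, positive]
- [B, A, negative]
- [A, B, positive]
- [B, Out, positive]
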