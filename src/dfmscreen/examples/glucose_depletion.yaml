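format_version: 1
name: glucose-depletion
description: >
  Minimal starvation model: a piecewise-linear glucose driver is depleted
  over the run (half consumed by step 13), nutrient stress rises, and the
  apoptosis and necrosis read-outs respond. Demonstrates drivers, pathway
  labels and a two-output screening-style model.
t_max: 26
variables:
- name: Glucose
  role: input
  initial: 1.0
  terms:
  - label: low
    mf: {kind: triangular, points: [0.0, 0.0, 0.5]}
  - label: high
    mf: {kind: triangular, points: [0.5, 1.0, 1.0]}
- name: Stress
  role: inner
  initial: 0.0
  pathway: stress-response
  terms:
  - label: low
    mf: {kind: triangular, points: [0.0, 0.0, 0.5]}
  - label: high
    mf: {kind: triangular, points: [0.5, 1.0, 1.0]}
- name: Apoptosis
  role: output
  initial: 0.0
  terms:
  - label: low
    mf: {kind: triangular, points: [0.0, 0.0, 0.5]}
  - label: high
    mf: {kind: triangular, points: [0.5, 1.0, 1.0]}
- name: Necrosis
  role: output
  initial: 0.0
  terms:
  - label: low
    mf: {kind: triangular, points: [0.0, 0.0, 0.5]}
  - label: high
    mf: {kind: triangular, points: [0.5, 1.0, 1.0]}
rules:
- IF (Glucose IS low) THEN (Stress IS 1.0)
- IF (Glucose IS high) THEN (Stress IS 0.0)
- IF (Stress IS high) THEN (Apoptosis IS 0.8)
- IF (Stress IS low) THEN (Apoptosis IS 0.0)
- IF (Stress IS high) AND (Glucose IS low) THEN (Necrosis IS 0.4)
- IF (Stress IS low) OR (Glucose IS high) THEN (Necrosis IS 0.0)
drivers:
  Glucose:
    kind: piecewise
    points: [[0, 1.0], [13, 0.5], [26, 0.0]]
edges:
- [Glucose, Stress, negative]
- [Stress, Apoptosis, positive]
- [Stress, Necrosis, positive]
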