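# AdHOC trauma-bay score expressed in the generic score-definition schema.
# Four any-of indicator groups (aspects), one point each; an aspect is
# positive as soon as any one of its parameters crosses its threshold.
# Hemoglobin threshold below assumes g/dL; a g/L registry should use 70.
name: adhoc
missing_policy: zero_points
items:
  - kind: any_of
    name: age
    points: 1
    predicates:
      - {parameter: age, op: ">", value: 65}
  - kind: any_of
    name: head
    points: 1
    predicates:
      - {parameter: gcs, op: "<", value: 12}
      - {parameter: ecs_motor, op: in, value: [non_specific, none]}
      - {parameter: ecs_pupil_size, op: in, value: [not_normal]}
      - {parameter: ecs_pupil_reactivity, op: in, value: [not_normal]}
  - kind: any_of
    name: oxygenation
    points: 1
    predicates:
      - {parameter: hemothorax, op: is_true}
      - {parameter: base_excess, op: "<=", value: -6}
      - {parameter: pao2_fio2, op: "<=", value: 200, requires: intubated}
  - kind: any_of
    name: circulation
    points: 1
    predicates:
      - {parameter: sbp, op: "<=", value: 90}
      - {parameter: prbc_transfused, op: is_true}
      - {parameter: inr, op: ">", value: 1.4}
      - {parameter: hb, op: "<", value: 7}
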