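# GAP score (GCS, Age, systolic blood Pressure), point table transcribed
# from the original publication (Kondo et al., Crit Care 2011):
#   GCS contributes its own value (3-15 points),
#   age < 60 years contributes 3 points,
#   SBP > 120 mmHg contributes 6 points, 60-120 mmHg contributes 4 points.
# Published range: 3-24.
name: gap
missing_policy: zero_points
items:
  - kind: bins
    parameter: gcs
    bins:
      - {lower: 3, upper: 4, points: 3}
      - {lower: 4, upper: 5, points: 4}
      - {lower: 5, upper: 6, points: 5}
      - {lower: 6, upper: 7, points: 6}
      - {lower: 7, upper: 8, points: 7}
      - {lower: 8, upper: 9, points: 8}
      - {lower: 9, upper: 10, points: 9}
      - {lower: 10, upper: 11, points: 10}
      - {lower: 11, upper: 12, points: 11}
      - {lower: 12, upper: 13, points: 12}
      - {lower: 13, upper: 14, points: 13}
      - {lower: 14, upper: 15, points: 14}
      - {lower: 15, upper: 16, points: 15}
  - kind: bins
    parameter: age
    bins:
      - {lower: 0, upper: 60, points: 3}
      - {lower: 60, upper: .inf, points: 0}
  - kind: bins
    parameter: sbp
    bins:
      - {lower: 0, upper: 60, points: 0}
      - {lower: 60, upper: 120, points: 4, upper_closed: true}
      - {lower: 120, upper: .inf, points: 6, lower_closed: false}
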