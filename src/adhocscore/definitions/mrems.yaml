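# Modified Rapid Emergency Medicine Score (mREMS), point table transcribed
# from the original publication (Miller et al., 2017): the REMS point bins
# with systolic blood pressure substituted for mean arterial pressure.
# Parameters hr (heart rate, /min), rr (respiratory rate, /min) and spo2
# (oxygen saturation, %) are not canonical record fields and are read from
# the record's passthrough columns.  Published range: 0-26.
name: mrems
missing_policy: zero_points
items:
  - kind: bins
    parameter: age
    bins:
      - {lower: 0, upper: 45, points: 0}
      - {lower: 45, upper: 55, points: 2}
      - {lower: 55, upper: 65, points: 3}
      - {lower: 65, upper: 75, points: 5}
      - {lower: 75, upper: .inf, points: 6}
  - kind: bins
    parameter: sbp
    bins:
      - {lower: 0, upper: 50, points: 4}
      - {lower: 50, upper: 70, points: 2}
      - {lower: 70, upper: 110, points: 0}
      - {lower: 110, upper: 130, points: 2}
      - {lower: 130, upper: 160, points: 3}
      - {lower: 160, upper: .inf, points: 4}
  - kind: bins
    parameter: hr
    bins:
      - {lower: 0, upper: 40, points: 4}
      - {lower: 40, upper: 55, points: 3}
      - {lower: 55, upper: 70, points: 2}
      - {lower: 70, upper: 110, points: 0}
      - {lower: 110, upper: 140, points: 2}
      - {lower: 140, upper: 180, points: 3}
      - {lower: 180, upper: .inf, points: 4}
  - kind: bins
    parameter: rr
    bins:
      - {lower: 0, upper: 6, points: 4}
      - {lower: 6, upper: 10, points: 2}
      - {lower: 10, upper: 12, points: 1}
      - {lower: 12, upper: 25, points: 0}
      - {lower: 25, upper: 35, points: 1}
      - {lower: 35, upper: 50, points: 3}
      - {lower: 50, upper: .inf, points: 4}
  - kind: bins
    parameter: spo2
    bins:
      - {lower: 0, upper: 75, points: 4}
      - {lower: 75, upper: 86, points: 3}
      - {lower: 86, upper: 90, points: 1}
      - {lower: 90, upper: .inf, points: 0}
  - kind: bins
    parameter: gcs
    bins:
      - {lower: 3, upper: 5, points: 4}
      - {lower: 5, upper: 8, points: 3}
      - {lower: 8, upper: 11, points: 2}
      - {lower: 11, upper: 14, points: 1}
      - {lower: 14, upper: 16, points: 0}
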