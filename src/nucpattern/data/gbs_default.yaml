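sites:
- groove: minor
  shl: -6.5
  start: 5
  length: 4
- groove: major
  shl: -6.0
  start: 10
  length: 3
- groove: minor
  shl: -5.5
  start: 15
  length: 4
- groove: major
  shl: -5.0
  start: 20
  length: 4
- groove: minor
  shl: -4.5
  start: 26
  length: 4
- groove: major
  shl: -4.0
  start: 31
  length: 4
- groove: minor
  shl: -3.5
  start: 36
  length: 4
- groove: major
  shl: -3.0
  start: 41
  length: 3
- groove: minor
  shl: -2.5
  start: 46
  length: 4
- groove: major
  shl: -2.0
  start: 51
  length: 4
- groove: minor
  shl: -1.5
  start: 57
  length: 4
- groove: major
  shl: -1.0
  start: 62
  length: 4
- groove: major
  shl: 1.0
  start: 81
  length: 4
- groove: minor
  shl: 1.5
  start: 86
  length: 4
- groove: major
  shl: 2.0
  start: 92
  length: 4
- groove: minor
  shl: 2.5
  start: 97
  length: 4
- groove: major
  shl: 3.0
  start: 103
  length: 3
- groove: minor
  shl: 3.5
  start: 107
  length: 4
- groove: major
  shl: 4.0
  start: 112
  length: 4
- groove: minor
  shl: 4.5
  start: 117
  length: 4
- groove: major
  shl: 5.0
  start: 123
  length: 4
- groove: minor
  shl: 5.5
  start: 128
  length: 4
- groove: major
  shl: 6.0
  start: 134
  length: 3
- groove: minor
  shl: 6.5
  start: 138
  length: 4
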