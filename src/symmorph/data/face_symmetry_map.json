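{
  "pairs": [
    [
      4,
      5
    ],
    [
      6,
      7
    ],
    [
      8,
      9
    ],
    [
      10,
      11
    ],
    [
      12,
      13
    ],
    [
      14,
      15
    ],
    [
      16,
      17
    ],
    [
      18,
      19
    ],
    [
      20,
      21
    ],
    [
      22,
      23
    ],
    [
      24,
      25
    ],
    [
      26,
      27
    ],
    [
      28,
      29
    ],
    [
      30,
      31
    ],
    [
      32,
      33
    ]
  ],
  "midline": [
    0,
    1,
    2,
    3
  ],
  "reflection_axis": 0
}
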