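{
  "name": "midline",
  "modules": {
    "sagittal": [
      0,
      1,
      2,
      3
    ],
    "midsagittal": [
      4,
      5,
      6,
      7,
      8,
      9,
      10,
      11,
      12,
      13,
      14,
      15,
      16,
      17,
      18,
      19
    ],
    "lateral": [
      20,
      21,
      22,
      23,
      24,
      25,
      26,
      27,
      28,
      29,
      30,
      31,
      32,
      33
    ]
  }
}
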