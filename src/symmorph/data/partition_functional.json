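{
  "name": "functional",
  "modules": {
    "eyes": [
      0,
      4,
      5,
      6,
      7,
      8,
      9,
      10,
      11,
      30,
      31
    ],
    "mouth": [
      3,
      16,
      17,
      18,
      19,
      32,
      33
    ],
    "nose": [
      1,
      2,
      12,
      13,
      14,
      15
    ],
    "ears": [
      20,
      21,
      22,
      23,
      24,
      25,
      26,
      27,
      28,
      29
    ]
  }
}
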