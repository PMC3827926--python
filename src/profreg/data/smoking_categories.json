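[
  {
    "name": "intensity",
    "bins": [[0, 10, 1], [10, 20, 2], [20, 30, 3], [30, null, 4]],
    "specials": {"non-smoker": 0}
  },
  {
    "name": "duration",
    "bins": [[0, 20, 1], [20, 30, 2], [30, 40, 3], [40, null, 4]],
    "specials": {"non-smoker": 0}
  },
  {
    "name": "time_since_cessation",
    "bins": [[20, null, 1], [10, 20, 2], [0, 10, 3]],
    "specials": {"non-smoker": 0, "current smoker": 4}
  },
  {
    "name": "pack_years",
    "bins": [[0, 15, 1], [15, 30, 2], [30, 45, 3], [45, null, 4]],
    "specials": {"non-smoker": 0}
  }
]
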