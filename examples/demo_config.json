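{
  "window": [2004, 2005, 2006],
  "national_population": 48890000,
  "seed": 2006,
  "sampling_fraction": 0.15,
  "n_random_verify": 2000,
  "n_census": 3504,
  "ci_digits_mode": "round",
  "simulate": {
    "seed": 2006
  }
}
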