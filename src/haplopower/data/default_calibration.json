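{
  "bandwidth_selection": "leave-one-out CV over a log-spaced grid",
  "bandwidths": {
    "0.001": 0.7003871545638966,
    "0.005": 0.5111546081322234,
    "0.01": 0.5111546081322234,
    "0.05": 0.3547229689763406,
    "0.1": 0.3922718049406671
  },
  "estimator": "local_linear",
  "exponent": 0.37,
  "grid": {
    "deviations": [
      1.0,
      0.5,
      0.25
    ],
    "method": "asymptotic",
    "n_cases": [
      100,
      250,
      500,
      750,
      1000
    ],
    "n_haplogroups": [
      4,
      8,
      12,
      16,
      20
    ],
    "n_perm": 1000,
    "n_sim": 2000,
    "ratios": [
      1.0,
      2.0,
      3.0
    ],
    "risky_freqs": [
      0.3,
      0.15,
      0.05
    ]
  },
  "kernel": "gaussian",
  "seed": 2013
}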