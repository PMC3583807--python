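# Rate-asymmetry scenarios for the single-process power and recovery study.
# One process is asymmetric per row; the other two are symmetric at base
# values. reported_pct_state0 is the published mean percent of state-0 tips
# over 500 simulations of 500-tip trees (used for calibration checks only).
defaults:
  n_tips: 500
  n_reps: 500
scenarios:
  - {label: "speciation 1.25x", process: speciation, lambda0: 0.1, lambda1: 0.125, mu0: 0.03, mu1: 0.03, q01: 0.01, q10: 0.01, tip_ratio: "3:1", reported_pct_state0: 29.23}
  - {label: "speciation 1.5x",  process: speciation, lambda0: 0.1, lambda1: 0.15,  mu0: 0.03, mu1: 0.03, q01: 0.01, q10: 0.01, tip_ratio: "5:1", reported_pct_state0: 19.33}
  - {label: "speciation 2x",    process: speciation, lambda0: 0.1, lambda1: 0.2,   mu0: 0.03, mu1: 0.03, q01: 0.01, q10: 0.01, tip_ratio: "10:1", reported_pct_state0: 9.90}
  - {label: "speciation 3x",    process: speciation, lambda0: 0.1, lambda1: 0.3,   mu0: 0.03, mu1: 0.03, q01: 0.01, q10: 0.01, tip_ratio: "20:1", reported_pct_state0: 4.94}
  - {label: "speciation 4x",    process: speciation, lambda0: 0.1, lambda1: 0.4,   mu0: 0.03, mu1: 0.03, q01: 0.01, q10: 0.01, tip_ratio: "30:1", reported_pct_state0: 3.19}
  - {label: "speciation 5x",    process: speciation, lambda0: 0.1, lambda1: 0.5,   mu0: 0.03, mu1: 0.03, q01: 0.01, q10: 0.01, tip_ratio: "40:1", reported_pct_state0: 2.50}
  - {label: "speciation 10x",   process: speciation, lambda0: 0.1, lambda1: 1.0,   mu0: 0.03, mu1: 0.03, q01: 0.01, q10: 0.01, tip_ratio: "90:1", reported_pct_state0: 1.13}
  - {label: "speciation 20x",   process: speciation, lambda0: 0.1, lambda1: 2.0,   mu0: 0.03, mu1: 0.03, q01: 0.01, q10: 0.01, tip_ratio: "180:1", reported_pct_state0: 0.51}
  - {label: "character 2x",  process: character_change, lambda0: 0.1, lambda1: 0.1, mu0: 0.03, mu1: 0.03, q01: 0.01,  q10: 0.005, tip_ratio: "2:1", reported_pct_state0: 33.96}
  - {label: "character 3x",  process: character_change, lambda0: 0.1, lambda1: 0.1, mu0: 0.03, mu1: 0.03, q01: 0.015, q10: 0.005, tip_ratio: "3:1", reported_pct_state0: 24.01}
  - {label: "character 4x",  process: character_change, lambda0: 0.1, lambda1: 0.1, mu0: 0.03, mu1: 0.03, q01: 0.02,  q10: 0.005, tip_ratio: "4:1", reported_pct_state0: 20.57}
  - {label: "character 5x",  process: character_change, lambda0: 0.1, lambda1: 0.1, mu0: 0.03, mu1: 0.03, q01: 0.025, q10: 0.005, tip_ratio: "5:1", reported_pct_state0: 16.69}
  - {label: "character 10x", process: character_change, lambda0: 0.1, lambda1: 0.1, mu0: 0.03, mu1: 0.03, q01: 0.05,  q10: 0.005, tip_ratio: "10:1", reported_pct_state0: 9.14}
  - {label: "character 20x", process: character_change, lambda0: 0.1, lambda1: 0.1, mu0: 0.03, mu1: 0.03, q01: 0.1,   q10: 0.005, tip_ratio: "20:1", reported_pct_state0: 4.69}
  - {label: "character 40x", process: character_change, lambda0: 0.1, lambda1: 0.1, mu0: 0.03, mu1: 0.03, q01: 0.2,   q10: 0.005, tip_ratio: "40:1", reported_pct_state0: 2.39}
  - {label: "extinction 2x",  process: extinction, lambda0: 0.1, lambda1: 0.1, mu0: 0.06, mu1: 0.03, q01: 0.01, q10: 0.01, tip_ratio: "3:1", reported_pct_state0: 23.85}
  - {label: "extinction 3x",  process: extinction, lambda0: 0.1, lambda1: 0.1, mu0: 0.09, mu1: 0.03, q01: 0.01, q10: 0.01, tip_ratio: "6:1", reported_pct_state0: 13.21}
  - {label: "extinction 4x",  process: extinction, lambda0: 0.1, lambda1: 0.1, mu0: 0.12, mu1: 0.03, q01: 0.01, q10: 0.01, tip_ratio: "9:1", reported_pct_state0: 9.29}
  - {label: "extinction 5x",  process: extinction, lambda0: 0.1, lambda1: 0.1, mu0: 0.15, mu1: 0.03, q01: 0.01, q10: 0.01, tip_ratio: "12:1", reported_pct_state0: 7.12}
  - {label: "extinction 10x", process: extinction, lambda0: 0.1, lambda1: 0.1, mu0: 0.3,  mu1: 0.03, q01: 0.01, q10: 0.01, tip_ratio: "27:1", reported_pct_state0: 3.40}
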