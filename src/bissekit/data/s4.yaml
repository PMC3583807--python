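# Single-process asymmetry scenarios with matched stationary tip bias, used
# for the reduced-model (4-vs-3 parameter) power comparison. The asymmetric
# process's two rates are placed geometrically around the base value so that
# the stationary state-0 frequency hits target_x_hat (3:1 bias -> 0.25,
# 7:1 bias -> 0.125); exact rates are derived at load time from these
# targets. reported_ratio is the published rate ratio for cross-checking.
defaults:
  base_lambda: 0.1
  base_mu: 0.05
  base_q: 0.005
  n_tips: 500
  n_reps: 500
scenarios:
  - {label: "S4 speciation low bias",  process: speciation,       target_x_hat: 0.25,  tip_ratio: "3:1", reported_ratio: 1.1425}
  - {label: "S4 extinction low bias",  process: extinction,       target_x_hat: 0.25,  tip_ratio: "3:1", reported_ratio: 1.3046}
  - {label: "S4 character low bias",   process: character_change, target_x_hat: 0.25,  tip_ratio: "3:1", reported_ratio: 3.0}
  - {label: "S4 speciation high bias", process: speciation,       target_x_hat: 0.125, tip_ratio: "7:1", reported_ratio: 1.407}
  - {label: "S4 extinction high bias", process: extinction,       target_x_hat: 0.125, tip_ratio: "7:1", reported_ratio: 1.960}
  - {label: "S4 character high bias",  process: character_change, target_x_hat: 0.125, tip_ratio: "7:1", reported_ratio: 7.000}
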