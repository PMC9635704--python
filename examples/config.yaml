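# Reference-study configuration for the fractcm CLI.
# All values shown are the package defaults; edit and pass with `-c`.
model: fractional
seed: 0
output_dir: results

growth:
  lambda0: 0.25
  lambda1: 0.4603
  phi: 20.0
  w0: 0.0121

pk:
  k01: 1.6
  k21: 0.2353
  k12: 0.1699
  V: 1028.0

dosing:
  dose_amount: 4.5e7
  n_doses: 10
  dose_start_day: 13.0

fractional:
  alpha: 0.945
  tau: 3.6852
  eta_fractional: 0.24657

erlang:
  n: 4
  k1: 0.54379
  eta_erlang: 0.37847

solver:
  t_start: 0.0
  t_end: 60.0
  step: 0.00390625   # 2^-8
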