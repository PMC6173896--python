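# Experiment 1, discontinuously fed reactor: identical to the continuous
# case except that 83 % of each daily ration is delivered in one 20-min
# pulse (the remainder continuously).  The pulse fraction and the inoculum
# acetoclastic split are jointly fitted to the reported day-64 community
# compositions (docs/methods.md).
scenario:
  name: exp1_disco
reactor:
  V_liq: 6.0
  HRT: 5.5
  T: 310.15
  S_cat_in: 0.0783
  S_an_in: 0.0198
influent:
  total_cod: 37.2
  cod_fractions: {acetic: 0.45, propionic: 0.10, butyric: 0.45}
  inorganic_carbon: 0.005
  inorganic_nitrogen: 0.055
parameters:
  preset: this_study
feed:
  mode: discontinuous
  pulse_fraction: 0.83
  period: 1.0
  pulse_duration: 0.013888888888888888   # 20 min in days
  disturbance: {day: 64.0, extra_cod_g: 45.0}
initial:
  inoculum_vs: 0.87
  partition: {X_su: 0.05, X_aa: 0.05, X_fa: 0.05, X_c4: 0.22,
              X_pro: 0.07, X_ac1: 0.041, X_ac2: 0.369, X_h2: 0.15}
simulation:
  t_end: 80.0
  training_end: 64.0
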