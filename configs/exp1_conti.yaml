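# Experiment 1, continuously fed reactor: 6 L working volume, HRT 5.5 d,
# 37.2 gCOD/L VFA medium (45/10/45 % acetic/propionic/butyric on COD
# basis), 64-day training phase, organic-overloading pulse on day 64.
# Influent inorganic N is anchored to the reported continuous-reactor
# charge balance; the disturbance load is calibrated (docs/methods.md).
scenario:
  name: exp1_conti
reactor:
  V_liq: 6.0        # L
  HRT: 5.5          # d
  T: 310.15         # K
  S_cat_in: 0.0783  # M
  S_an_in: 0.0198   # M
influent:
  total_cod: 37.2   # gCOD/L
  cod_fractions: {acetic: 0.45, propionic: 0.10, butyric: 0.45}
  inorganic_carbon: 0.005    # M
  inorganic_nitrogen: 0.055  # M
parameters:
  preset: this_study
feed:
  mode: continuous
  disturbance: {day: 64.0, extra_cod_g: 45.0}
initial:
  inoculum_vs: 0.87          # g/L, measured inoculum volatile solids
  partition: {X_su: 0.05, X_aa: 0.05, X_fa: 0.05, X_c4: 0.22,
              X_pro: 0.07, X_ac1: 0.041, X_ac2: 0.369, X_h2: 0.15}
simulation:
  t_end: 80.0
  training_end: 64.0
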