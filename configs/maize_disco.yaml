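# Maize-silage digester, every-second-day feeding at HRT 20 d.  The
# influent is the literature-style whole-silage characterisation bundled
# with the package (see src/admsplit/data/maize_silage.yaml).  The regime
# switch experiment in the test suite first runs the continuous variant to
# steady state and re-seeds Methanosarcina at 0.2 gCOD/L before switching.
scenario:
  name: maize_disco
reactor:
  V_liq: 6.0
  HRT: 20.0
  T: 310.15
  S_cat_in: 0.0783
  S_an_in: 0.0198
influent:
  total_cod: 350.0
  cod_fractions: {carbohydrate: 0.72, protein: 0.08, lipid: 0.05,
                  inert_particulate: 0.12, inert_soluble: 0.03}
  inorganic_carbon: 0.010
  inorganic_nitrogen: 0.150
parameters:
  preset: this_study
feed:
  mode: discontinuous
  pulse_fraction: 1.0
  period: 2.0
  pulse_duration: 0.013888888888888888
initial:
  inoculum_vs: 10.0
  S_IN0: 0.15
simulation:
  t_end: 365.0
  training_end: 0.0
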