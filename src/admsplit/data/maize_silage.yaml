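# Maize-silage influent characterisation for the agricultural-digester scenario.
#
# These are external-literature values (standard ADM1-style substrate
# characterisation of ensiled maize fed as fresh matter, ~30 % total
# solids, ~1.1 gCOD/gVS), not measurements made by this package: COD is
# dominated by carbohydrates (starch + fibre), with small protein and lipid
# shares and a degradation-resistant remainder.  The inorganic nitrogen
# level reflects the ammonium a silage-fed digester holds with digestate
# recirculation.  Edit freely; fractions must sum to 1.
total_cod: 350.0           # gCOD/L of feed (fresh-matter silage)
cod_fractions:
  carbohydrate: 0.72
  protein: 0.08
  lipid: 0.05
  inert_particulate: 0.12
  inert_soluble: 0.03
inorganic_carbon: 0.010    # M
inorganic_nitrogen: 0.150  # M
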