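# admsplit

Anaerobic digesters fed on demand risk organic overloading: volatile fatty
acids (VFAs) accumulate faster than acetogens and methanogens consume
them, pH drops, and methane production collapses.  Whether a digester
survives such an overload depends less on bulk biomass than on *which*
acetoclastic methanogens dominate.  `admsplit` is a simulation package for
studying exactly that: it implements the Anaerobic Digestion Model No. 1
(ADM1) with the acetoclastic guild split into two competing populations —

* ***Methanosarcina*** (`X_ac1`): fast (k_m = 20 gCOD gCOD⁻¹ d⁻¹),
  low-affinity (K = 0.32 gCOD L⁻¹), acid-tolerant (pH inhibition only
  below 5.5);
* ***Methanosaeta*** (`X_ac2`): slower (k_m = 14.5), high-affinity
  (K = 0.09), acid-sensitive (inhibited below pH 7) —

so that feeding regime, not just loading, selects the community.  Under
continuous feeding the residual acetate is low and steady:
*Methanosaeta* excludes its competitor.  Under pulsed feeding, acetate
spikes to ~2 gCOD/L and pH dips to ~6.5 once a day, opening a niche in
which *Methanosarcina* grows and both coexist — and a
*Methanosarcina*-rich community shrugs off an acetate overload that
acidifies the continuously fed reactor permanently.

The package is aimed at bioprocess modellers and microbial-ecology
researchers who want to design feeding regimes as a microbial-resources-
management tool.  It provides:

* `admsplit.model` — the modified ADM1: two acetoclastic guilds,
  charge-balance pH at every step, overpressure-driven biogas outflow,
  and inorganic C/N source terms constructed so every process row closes
  COD, carbon and nitrogen exactly (machine precision, asserted at model
  build);
* `admsplit.feeding` / `admsplit.scenarios` — continuous, daily-pulse and
  every-second-day schedules, overloading disturbances, and presets for
  three laboratory VFA-fed experiments plus a maize-silage digester;
* `admsplit.calibration` — run summaries, a weighted fitting objective,
  least-squares parameter recovery from observation tables, and the
  closed-form chemostat washout boundary;
* `admsplit.metrics` — Hill diversity/evenness, 16S copy-number and
  *mrtA* duplicate corrections, ¹³C labelling-ratio interpretation, and
  stoichiometric COD/mass/mol conversion of VFA mixtures;
* `admsplit.synthetic` — seeded generators of noisy observation tables
  and community profiles, so the calibration machinery is testable
  without any measurement data.

## Worked example

Simulate the two Experiment-1 feeding regimes (6 L, HRT 5.5 d,
37.2 gCOD/L VFA medium) through their 64-day training phase and compare
the acetoclastic community:

```python
from admsplit import simulate
from admsplit.scenarios import preset

for name in ("exp1_conti", "exp1_disco"):
    sc = preset(name, disturbed=False)
    traj = simulate(sc.config, sc.params, sc.schedule, 64.0, sc.y0)
    end = traj.df.iloc[-1]
    train = traj.window(47.5, 64.0)
    print(f"{name}: f_sarcina={end['f_sarcina']:.3f} "
          f"pH_max={train['pH'].max():.2f} DIC={end['S_IC']:.3f} M "
          f"VFA={end['vfa_total']:.2f} gCOD/L")
```

prints

```
exp1_conti: f_sarcina=0.012 pH_max=7.29 DIC=0.103 M VFA=1.33 gCOD/L
exp1_disco: f_sarcina=0.557 pH_max=7.59 DIC=0.105 M VFA=0.40 gCOD/L
```

Read: after ~11.6 retention times, *Methanosarcina* is nearly washed out
of the continuously fed reactor (1.2 % of acetoclastic biomass) but holds
56 % of it under daily pulse feeding; the pulsed reactor also runs
~0.3 pH units higher, because each acid excursion shifts bicarbonate to
CO₂ and strips it, permanently lowering dissolved inorganic carbon.  The
same mechanism in reverse explains the resilience contrast after a day-64
acetate overload, which `preset(name, disturbed=True)` includes.

The same runs from the shell:

```bash
admsplit simulate --preset exp1_disco --t-end 64 --out disco.csv
admsplit metrics convert --total-cod 37.2   # VFA medium unit conversions
admsplit washout --kinetics literature --guild X_ac2
```

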