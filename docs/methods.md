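# Methods

## Model

The package implements a continuous stirred-tank (CSTR) formulation of the
IWA Anaerobic Digestion Model No. 1 (ADM1; Batstone et al. 2002) in the
mesophilic benchmark parameterisation of Rosen & Jeppsson (2006), with one
structural change that is the point of the package: acetoclastic
methanogenesis is carried by **two competing guilds** instead of one.

* `X_ac1` — *Methanosarcina*: high maximum uptake rate
  (k_m = 20 gCOD/gCOD/d), high half-saturation constant (K = 0.32 gCOD/L),
  pH inhibition only below pH 5.5 (complete at pH 4).
* `X_ac2` — *Methanosaeta*: lower uptake rate (k_m = 14.5), strong
  affinity (K = 0.09 gCOD/L), but pH inhibition already below pH 7
  (complete at pH 6.3).

Both draw on the same acetate pool with their own Monod kinetics and
inhibition products, so the acetate balance carries two uptake terms.  At
low, steady acetate the high-affinity, pH-sensitive guild wins
(competitive exclusion at the lower residual substrate); when feeding
pulses drive acetate up to ~2 gCOD/L and pH down to ~6.5, the
pH-insensitive, high-rate guild out-consumes it.  Pulsed feeding therefore
opens a temporal niche in which both coexist.  All other guilds
(sugar/amino-acid/LCFA degraders, butyrate+valerate and propionate
oxidisers, hydrogenotrophic methanogens) follow the standard ADM1 process
structure.  Propionate and butyrate oxidisers carry no pH-inhibition
window in the fitted parameter set (their table entries are "not
applicable"); hydrogen inhibition of the acetogens and free-ammonia
inhibition of both acetoclastic guilds stay at ADM1 defaults.

Further deviations from the benchmark formulation:

* **Exact elemental closure.** The inorganic-carbon and inorganic-nitrogen
  stoichiometric coefficients of every process are not tabulated but
  computed as the negative C- (resp. N-) content-weighted sum of all other
  coefficients of that process.  Every process row then closes COD, C and
  N to machine precision by construction (asserted at model build time);
  the benchmark tables leave small gaps, e.g. in biomass decay.
* **Decay recycling.** Decay of every guild feeds the composite pool
  `X_c`, which re-enters disintegration/hydrolysis with standard
  parameters, so decayed biomass is slowly re-digested.
* **Overpressure-driven gas outflow.** Biogas leaves the headspace at
  q_gas = k_p·(P−P_atm)·P/P_atm; reported flows are normalised to 273.15 K
  and 101 325 Pa.  k_p = 5·10⁴ L/(d·bar) keeps the steady overpressure
  below 1 mbar (a few mbar at the peak of a feeding pulse), mimicking a
  drum-type gas meter.
* **Algebraic pH.** Acid–base reactions are treated as instantaneous
  equilibrium: at every right-hand-side evaluation the proton
  concentration solves the charge balance
  S_cat + NH4⁺ + H⁺ − HCO3⁻ − ΣVFA⁻ − OH⁻ − S_an = 0,
  which is strictly monotone in [H⁺] (unique root).  A warm-started Newton
  iteration (bisection fallback) converges to |residual| < 1e−12 eq/L.
  This removes the fast ion ODEs — the dominant stiffness source in the
  original formulation — at the cost of one scalar root solve per RHS
  call.  Carbonate (CO3²⁻) is neglected as in the benchmark
  implementation; below pH 8 its contribution is < 1 %.

Temperature enters through van-'t-Hoff-corrected equilibrium and Henry
constants and the water vapour pressure (0.062 bar at 310.15 K).

## Integration

`simulate` uses scipy's BDF with rtol 1e−8 / atol 1e−12 and restarts the
integrator at every feed edge, so pulse discontinuities are never stepped
across.  Output is sampled at ≤ 0.01 d during pulses and ≤ 0.1 d
otherwise; implicit-solver trial excursions below zero are clipped only
for rate evaluation and reporting.  Two cumulative audit states integrate
the COD fed and exported alongside the model, so the global COD balance
(`cod_balance`) is computed to integrator accuracy rather than by
quadrature of saved samples; valid runs close to ~1e−8 relative (the
acceptance threshold is 1e−3).

## Laboratory scenarios and their unreported inputs

The lab presets feed a synthetic VFA medium — 45/10/45 % acetic/propionic/
butyric acid on COD basis, 37.2 gCOD/L (Experiments 1–2) or 12.4 gCOD/L
(Experiment 3) — into a 6 L (8 L for Experiment 3) reactor at 37 °C,
either continuously (V/HRT = 1.09 L/d at HRT 5.5 d) or with a daily
20-min pulse carrying 83 % of the ration (the remainder continuous).  The
influent strong-ion lumps are 78.3 mM cations and 19.8 mM anions, as
determined from the medium recipe.  Training runs for 64 days
(≈ 11.6 HRTs); day 64 applies an organic-overloading pulse of the same
mixture at four-fold concentration.

Four scenario inputs the experiment description does not pin down
numerically are fixed as follows (all overridable in config):

* **Influent inorganic nitrogen, 55 mM.**  The medium's ammonium is not
  given in the main experiment description, but the continuous reactor's
  reported state (DIC 0.113 M at pH ≈ 7.3 with the cation surplus
  cat−an = 58.5 meq/L) fixes it through the charge balance: bicarbonate
  ≈ 0.10 M requires NH4⁺ ≈ 45 mM beyond the strong-ion surplus, i.e.
  S_IN,in ≈ 0.05–0.06 M.  The preset uses 0.055 M, the value whose
  simulated continuous reactor reproduces the reported pH maximum and
  DIC simultaneously.  Influent inorganic carbon is set to a trace
  5 mM.
* **Pulse fraction, 0.83.**  The protocol delivered 75–100 % of the daily
  ration in the pulse, the exact per-experiment value being figure-level
  information.  Within that range the day-64 community composition of the
  pulsed reactor is steeply increasing in the pulse fraction while the
  continuous reactor is unaffected, so the fraction was fitted jointly
  with the inoculum split (below) to the two reported day-64 compositions.
  The fitted value also reproduces the reported pulsed-reactor pH maximum
  (7.59 simulated vs 7.56 reported) and gives post-pulse acetic-acid
  accumulations of ≈ 2.3 gCOD/L against the ≈ 2.1 gCOD/L reported.
* **Inoculum guild partition.**  The measured inoculum is a single VS
  concentration (0.87 g/L for Experiment 1), converted at 1.42 gCOD/gVS
  and split over the eight guilds by a configurable vector.  The
  acetoclastic split (Methanosarcina share f₀ of acetoclastic COD) is the
  one genuinely sensitive entry: the continuous reactor's day-64
  composition is a monotone image of f₀ (Methanosarcina only decays
  there), while the pulsed reactor's day-64 composition lies on a slow
  drift towards Methanosarcina dominance.  f₀ and the pulse fraction were
  fitted jointly to the two reported day-64 compositions (99.8 %
  Methanosaeta continuous, 56 % Methanosarcina pulsed), reproducing the
  study's own manual calibration step.  The frozen values (f₀ = 0.10 of
  acetoclastic COD, i.e. X_ac1 4.1 % and X_ac2 36.9 % of inoculum
  biomass) yield 98.8 % / 55.7 % at day 64.
* **Disturbance load, 45 gCOD.**  Not reported; calibrated so that the
  continuous reactor's pH immediately after the day-64 overload matches
  the reported 5.93 (simulated 5.97).  The reported values are the
  immediately-post-disturbance pH (the failing continuous reactor keeps
  falling afterwards).  In the pulsed reactor the disturbance coincides
  with — and merges into — the daily feeding pulse, so its immediate dip
  is deeper in simulation (5.36) than the reported 5.99; the package
  delivers the disturbance together with the ration rather than inventing
  an unreported delay.

Because the pulsed reactor's day-64 composition sits mid-transient on a
sharp regime boundary (insufficient Methanosarcina lets a daily pulse
acidify the reactor outright — the same bistability that underlies the
resilience result), the fitted value of the pulse fraction is a genuine
calibration, not a prediction.  Everything downstream of it (pH dynamics,
DIC stripping, resilience contrast, washout behaviour) is prediction.

## A residual-VFA discrepancy

In a chemostat at HRT 5.5 d, each guild's steady residual substrate is
pinned by Y·k_m·S*/(K+S*)·I = 1/HRT + k_dec.  With the fitted kinetics
this gives S* of roughly 0.07–0.25 gCOD/L (acetate, depending on ammonia
inhibition), ~0.13–0.45 (propionate) and ~0.4–0.7 (butyrate) — a total
residual VFA of ~0.5–1.4 gCOD/L in the continuously fed simulation,
corresponding to 96–99 % substrate conversion.  Residuals in the few
mgCOD/L range are mathematically unreachable with these kinetics at this
HRT, whatever the initial state or buffering.  The package reports the
computed residuals as they are; the two checks tied to few-mg residuals
and >99 % simulated conversion document this discrepancy and are expected
to fail under the published kinetics.

## Maize-silage scenario

The agricultural preset keeps all fitted kinetics and changes only HRT
(20 d) and the influent: a literature-style maize-silage characterisation
(bundled as an editable data file) fed directly as carbohydrate/protein/
lipid particulates plus inerts, with standard disintegration/hydrolysis/
acidogenesis parameters.  Characterising fresh substrate at the
hydrolysis level (rather than routing it through the composite pool,
which exists here to recycle decayed biomass) is standard ADM1
application practice and preserves the pulse structure of every-second-day
feeding.  The switch experiment runs continuous feeding to steady state,
re-seeds Methanosarcina at 0.2 gCOD/L (≈ replacing 5 % of the working
volume with effluent from a Methanosarcina-rich digester) and follows
365 days of every-second-day feeding.  At a dilute influent (e.g. a
95 gCOD/L slurry) the every-second-day acetate spikes stay below
Methanosaeta's inhibition threshold and no niche opens; the regime-switch
effect requires the undiluted substrate the protocol implies (each pulse
then raises acetate by several gCOD/L and dips pH to ≈ 6.9).

## Synthetic observations

`synthetic.generate_observations` samples a simulated trajectory the way
the reactors were sampled: daily pre-feeding measurements (VFA, pH,
volatile-solids biomass, acetoclastic composition) plus an optional dense
24-h series across one feeding interval (30-min spacing).  Noise is
multiplicative lognormal on concentrations and rates (CV 10 %), additive
Gaussian on pH (sd 0.05) and on composition fractions (sd 0.02), plus an
additive Gaussian detection floor (sd 0.01 gCOD/L) on concentrations so
that trace-level readings do not pretend unlimited precision (VFA
chromatography cannot resolve µg/L) — all chosen once to resemble the
scatter of the published process-monitoring box plots; they are defaults,
not measured values.  The generator is
deterministic given a seed.  What it does *not* emulate: sensor drift,
autocorrelated error, sampling dead volume, or the compositional bias of
marker-gene quantification; recovery results bound estimation error under
idealised iid noise only.

## Parameter recovery

The recovery experiment generates observations (as above) from two
12-day acetate-only companion reactors at the fitted kinetics — one
pulse-fed (with two dense 24-h series), one continuous (daily samples) —
and re-estimates (k_m, K) of both acetoclastic guilds by weighted least
squares over both tables jointly (trust-region reflective in
log-parameter space, residuals scaled by each observation's noise sd,
full simulator as forward model, output grid refined to 0.02 d so
interpolation error stays below the noise floor).  The two-regime design
mirrors the study's own fitting, and it is what makes the problem well
posed: fitted to the pulsed reactor alone the likelihood has a flat
k_m–K ridge for Methanosarcina (its uptake is saturated during the brief
acid excursions), and single-regime estimates of K wander 20–40 % at
this noise level.  The continuous reactor's residual acetate pins
Methanosaeta's K, and its slow Methanosarcina washout rate fixes
k_m/K at low substrate, breaking the ridge; the joint fit recovers all
four parameters within 15 %.  The acetate-only medium isolates the
two-guild acetate balance — with the mixed-acid medium the upstream
oxidisers' kinetics would confound the estimate.  Yields and decay rates
are held at truth: the study itself notes yields are not identifiable
from this data type.

## Numerical choices and degenerate inputs

* Charge-balance solve: Newton from the previous time step's root,
  |f| < 1e−12 eq/L, bisection fallback on [pH 0, 14]; an empty system
  (pure water) returns pH 7 at 25 °C by construction.
* Monod terms evaluate concentrations clipped at zero; the
  butyrate/valerate oxidiser splits its capacity by relative substrate
  abundance with an 1e−12 guard against 0/0.
* Feeding events are square pulses; overlapping disturbance events merge
  with mass-weighted composition.
* `find_steady_state` declares continuous runs stationary at
  max|dy/dt| < 1e−6 and pulsed runs cyclostationary when the relative
  state change over one whole period falls below tolerance.
* Integrator failures raise with the failure time and the stiffest state
  component; NaN derivatives raise immediately with a state dump.

## Problem sizes

Default test and acceptance runs use: 64–80-day Experiment-1 simulations
(the full training + disturbance horizon), a 40-day literature-kinetics
washout run, a 250-day maize spin-up plus 365-day switch simulation, and
a 12-day recovery fit — all chosen as the shortest horizons that contain
the quantities being measured (11.6 HRTs of training, ≥ 3 HRTs of
post-disturbance observation, one year of regime switch).

## Known limitations

* Methanosarcina is modelled as strictly acetoclastic; its facultative
  hydrogenotrophy is outside the model, as is syntrophic acetate
  oxidation (the labelling-ratio analytics in `metrics` exist precisely
  to check that assumption against data).
* No thermodynamic rate corrections, no biofilm/spatial structure, no
  start-up phase: simulations begin at the training phase.
* The pH-inhibition switch offers the lower-limit exponential (default)
  and Hill forms only.
* Gas-phase dynamics assume ideal gas and a fixed headspace volume
  (V_gas = V_liq/10 unless configured).
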