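# sharkstress

A tested, reusable implementation of the full computational chain of a
2x2 temperature x pCO2 multistressor exposure experiment on neonatal
blacktip reef sharks — for experimental biologists running (or planning)
factorial climate-stressor studies on hard-to-replicate species, and for
anyone who wants the analysis machinery of such a study as a library
rather than a pile of one-off scripts.

The chain covers:

* **Seawater carbonate chemistry** — pCO2 from (pH_NBS, A_T, T, S) with
  Mehrbach constants refit by Dickson & Millero, and total alkalinity
  from open-cell Gran titrations;
* **Respirometry** — six oxygen-uptake metrics from a 24-h
  intermittent-flow trace: MO2min (mean of the lowest normal
  distribution), MO2max (steepest 30-s window of hour one), absolute and
  factorial aerobic scope, EPOC and recovery time, all mass-corrected as
  mg O2 kg^-0.89 h^-1;
* **Behaviour** — relative/absolute lateralisation indices
  (L_R = (R - L)/(R + L) x 100, L_A = |L_R|), overall dynamic body
  acceleration (ODBA) from 25-Hz accelerometry, and the hypoxia-tolerance
  endpoint;
* **Haematology** — Drabkin [Hb], haematocrit, MCHC;
* **Inference** — per-trait linear mixed models (temperature x pCO2
  fixed, replicate tank random), 95% CIs from 1000 posterior simulations,
  CV / correlation / KS / Bartlett variability screens;
* **Power** — Monte-Carlo power analysis over replicate-group counts,
  with meta-analytic effect ratios (1.67 temperature, 1.06 pCO2, 1.60
  interaction) translated into model effects;
* **Synthetic data** — generators for every raw input with stored ground
  truth, so each stage above is validated by parameter recovery.

## The model

Every trait y for shark j in replicate group (tank) g is modelled as

    y_gj = beta0 + bT xT + bC xC + bI xT xC + u_g + e_gj,
    u_g ~ N(0, sigma_g^2),   e_gj ~ N(0, sigma_e^2),

where xT, xC indicate the high temperature / high pCO2 levels.  A
treatment/control ratio r enters as an additive effect (r - 1) * beta0.
Significance of a fixed effect is judged by whether the 2.5–97.5
percentile band of 1000 simulated coefficient draws excludes zero; power
for an effect is the rejection rate of a between-within t test over
simulate–refit replicates.  See `docs/methods.md` for the full account.

## Worked example

```python
from sharkstress.carbonate import SeawaterSample, solve_pco2
from sharkstress.respirometry import analyse_trace
from sharkstress.synthetic import (MO2Truth, RespirometerConfig, Shark,
                                   generate_o2_trace)

# treatment water: what pCO2 did the ambient tanks actually hold?
sample = solve_pco2(SeawaterSample(temperature=28.1, salinity=37.0,
                                   ph_nbs=8.01, alkalinity=2354.0))
print(f"pCO2 = {sample.pco2:.1f} uatm")         # pCO2 = 651.8 uatm

# a synthetic 24-h respirometry trial with known kinetics...
shark = Shark("demo", mass=1.0, total_length=569.0,
              temperature=28.0, pco2=650.0, group_id="T28_C650_g1")
truth = MO2Truth()                               # min 133.69, max 360.15
trace = generate_o2_trace(shark, truth, RespirometerConfig(), seed=1)

# ...and the pipeline recovering its ground truth
metrics, dets = analyse_trace(trace)
print(f"MO2min = {metrics.mo2_min:.2f}")         # MO2min = 133.70
print(f"MO2max = {metrics.mo2_max:.2f}")         # MO2max = 359.68
print(f"FAS    = {metrics.fas:.2f}")             # FAS    = 2.69
print(f"EPOC   = {metrics.epoc:.1f}")            # EPOC   = 426.2
```

The first number is the solved partial pressure of CO2 in the ambient
treatment water (the tanks targeted 650 uatm).  The remaining lines show
the uptake-metric pipeline recovering the generator's programmed
minimum/maximum uptake rates — 133.69 and 360.15 mg O2 kg^-0.89 h^-1 —
to within a fraction of a percent from the raw O2 trace alone.

A thin CLI wraps the same functions:

```bash
sharkstress carbchem --ph 8.01 --temp 28.1 --sal 37 --ta 2354
sharkstress respo --trace trace.csv --mass 1.0
sharkstress power --ratios 1.67,1.06,1.60 --groups 3:8 --nsim 200 --seed 7
```

## Data formats

All interchange is plain CSV (`sharkstress.io`): rosters
(`shark_id, mass_kg, ...`), O2 traces (`time_s, o2_mg_l, phase`),
acceleration traces (`time_s, x_g, y_g, z_g`), turn records
(`shark_id, trial_side, turn_direction`), titrations (`acid_ml, ph`) and
the shark x traits table.  The original study's deposited dataset uses
compatible tabular layouts and can be loaded with the same readers.
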