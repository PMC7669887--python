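# Methods

This package re-implements, end to end, the computational chain of a 2x2
temperature x pCO2 multistressor exposure experiment on neonatal sharks:
treatment-water carbonate chemistry, derivation of 15 behavioural and
physiological traits from raw instrument records, linear mixed-model
effect estimation with simulation-based confidence intervals, Monte-Carlo
power analysis over replicate-group counts, and inter-individual
variability screens.  Every stage is driven by a synthetic-data generator
with stored ground truth, so the whole chain is testable by parameter
recovery without access to the field data.

## Study design and generative model

The design fully crosses two temperatures (28, 31 degC — dry- and
wet-season lagoon conditions) with two pCO2 levels (650, 1050 uatm —
present-day high and a +400 uatm acidification scenario).  Each of the
four cells holds three replicate groups (tanks) of 3–4 sharks; the tank
is the unit that shares treatment water, hence the random-intercept unit.
Body mass is drawn from a truncated normal, 1.0 ± 0.2 kg on [0.7, 1.4] kg,
matching the sampled population.

Each trait y for shark j in group g follows

    y_gj = beta0 + bT x_T + bC x_C + bI x_T x_C + u_g + e_gj,
    u_g ~ N(0, sigma_g^2),  e_gj ~ N(0, sigma_e^2),

with x_T, x_C indicators of the high factor levels.  Treatment effects are
specified as treatment/control *ratios* (the scale on which meta-analytic
effect sizes are reported) and enter additively as b = (r - 1) * beta0.
This keeps the generative model linear — matching the analysis model —
while accepting ratio-scale effect specifications; it also makes shifts
exactly additive, which the tests exploit (doubling r - 1 doubles the
shift).

Seeding fans a single global seed out through `numpy.random.SeedSequence`
keyed on structural indices (cell, group, shark) and stable string hashes,
never on stream position.  Consequences: identical seeds give bit-identical
outputs, and enlarging a design (more groups) reuses the identical draws
for the entities it shares with the smaller design.  The power module's
group-count search depends on this common-random-numbers property to make
its power curves monotone up to test noise.

### What the generator does not emulate

Real traces contain sensor drift and spikes, tidal/circadian activity
rhythms, spontaneous-activity bursts during respirometry, tag slippage,
and non-Gaussian trait distributions.  Passing parameter-recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to every field artefact.  The screens (R^2 filter,
negative-determination exclusion, singularity flags) are exercised by the
noise the generator does produce.

## Carbonate chemistry

`carbonate` solves the seawater CO2 system from the measured pair
(pH_NBS, A_T) at in-situ T and S.  Constants: Mehrbach K1/K2 as refit by
Dickson & Millero (1987) on the seawater pH scale, Dickson (1990) KB and
KS, Millero (1995) KW, Weiss (1974) K0, Uppstrom boron.  pH_NBS is mapped
to a concentration scale by dividing the activity by the Takahashi/GEOSECS
fH factor.  Fluoride is excluded from the alkalinity balance by default
(the convention under which total and seawater scales coincide); a flag
enables it.  Alkalinity components are carbonate, borate, water, free H+
and bisulfate — nutrients are assumed zero, as none are reported for the
treatment water.

Total alkalinity comes from an open-cell Gran titration: 50 mL of sample
dosed with 0.1 M HCl in 0.1 mL steps; in the acid region (pH 3.0–3.5,
where CO2 has degassed and carbonate species no longer buffer) the Gran
function F = (V0 + V) 10^(-pH) is linear in V and its x-intercept is the
equivalence volume.  A_T = Ve C_acid / (V0 rho_sw), with surface seawater
density from the EOS-80 (Millero–Poisson) formula.  Because the meter pH
is an NBS-style activity, the 10^(-pH) in F is proportional to the
seawater-scale [H+], which *includes* HSO4-; this is what keeps F linear
despite sulfate taking up part of the added acid.  The titration
generator solves the full proton condition (including DIC and dilution)
at every dose, so recovery of the programmed A_T (within 0.25% noiseless)
is a genuine round trip through an independent forward model.

A caution from validation: the published treatment-water table prints
mean pCO2 values that cannot all be reproduced from the printed mean
inputs — two of its rows share pH 8.01 and nearly equal A_T yet print
pCO2 *decreasing* with temperature, which contradicts the strict
monotonicity of pCO2 in T at fixed (pH, S, A_T).  Such tables are
evidently means of per-sample solver outputs whose inputs are averaged
and rounded separately; solver agreement should be judged against rows
that are internally consistent.

## Respirometry

A 24-h intermittent-flow trial alternates 10-min sealed measure phases
with 5-min flushes — 96 determinations in 24 h; the cadence is implied by
the count, since 96 x 15 min = 24 h.  Empty-chamber background phases
bracket the trial.  Per measure phase, the O2 uptake determination is the
least-squares slope of the concentration decline, kept when R^2 > 0.95,
converted as

    MO2 = |slope| * (V_chamber - V_animal) * 3600 / mass^0.89

(mg O2 kg^-0.89 h^-1; the intraspecific scaling exponent 0.89 corrects to
a 1-kg animal; animal volume defaults to mass at 1 kg/L displacement).
Background correction interpolates the empty-chamber decline rate
linearly between the pre and post measurements and subtracts it on the
per-litre-rate scale before unit conversion — the generator's background
truth is linear in time, so this correction is exact in round trips.
Determinations that go negative after correction indicate drift and are
excluded, not clipped (clipping would bias the minimum-uptake estimate
downward).

* **Minimum uptake (MO2min)** — mean of the lowest normal distribution
  (MLND): Gaussian mixtures with 1–4 components are fit to the retained
  determinations, the count chosen by BIC, and the lowest component mean
  returned.  Resting metabolism forms the lowest mode; spontaneous
  activity populates the higher ones.
* **Maximum uptake (MO2max)** — steepest 30-s regression window during
  the first hour, windows advancing sample-by-sample strictly inside
  measure phases (a window spanning a flush is physically meaningless);
  ties go to the earliest window.
* **Scopes** — AAS = MO2max - MO2min, FAS = MO2max / MO2min.
* **EPOC and recovery** — a 3-parameter decay y(t) = a e^(-kt) + c is fit
  to the determination series (t from trial start).  Recovery is the
  earliest t with y(t) <= MO2min, closed-form when the asymptote c
  undercuts MO2min; EPOC is the analytic integral of y - MO2min over
  [0, recovery].  When c does not undercut MO2min by at least 1%
  (relative), the strict crossing is absent or pushed to an arbitrarily
  late, noise-dominated time, so recovery falls back to the time the
  fitted excess a e^(-kt) drops within 10% of MO2min, flagged
  approximate.  The 1% guard is a numerical tie-break: without it, a
  fitted asymptote a hair below MO2min yields crossings many hours late
  with negligible area contribution.  EPOC/recovery ground truth in the
  generator is defined under the same convention — the metric is defined
  *by* the convention, like recovery itself.

## Behaviour and blood

Lateralisation: L_R = (right - left)/total x 100 over 20 T-maze turns
(10 initiated per maze side), L_A = |L_R|.  ODBA: per axis, the static
component is a centred 2-s running mean (window shrinking symmetrically at
the edges); dynamic = raw - static; ODBA sums |dynamic| over axes.
Activity level is the mean ODBA over the half-open clock window
[11:00, 15:00) — half-open so adjacent windows never double-count.  The
closed form for a pure sine (mean |dynamic| = 2A/pi) holds when the
smoothing window spans an integer number of beat cycles; otherwise the
running mean leaks a sinc(fT) fraction of the beat into the static
estimate, which is why the generator's default tail-beat is 1.5 Hz
(3 cycles per 2-s window at 25 Hz).  Hypoxia tolerance is the % air
saturation, linearly interpolated, at the onset of muscle spasms.

Drabkin haemoglobin: [Hb] = mean(A540)/(11 x path) x dilution, with the
cyanmethemoglobin heme-basis extinction coefficient 11 mmol^-1 L cm^-1,
dilution 201 (5 uL blood + 1000 uL reagent read as addition) and a
0.56 cm default path (200 uL in a flat-bottom 96-well; configurable).
Hct is the mean of duplicate spins; MCHC = [Hb]/Hct.  Electrode pH
temperature correction is a pluggable affine map defaulting to identity,
since the species-specific equations are instrument-calibration details.

## Inference

Each trait is fit with `statsmodels` MixedLM: interacting two-level fixed
effects, replicate-group random intercept, REML for reporting, complete-
case rows per trait (no imputation).  A random-intercept variance below
1e-4 of the residual variance is flagged singular, lme4-style.

95% CIs come from posterior simulation: draw an overall scale from
df/chi2_df, then a coefficient vector from N(estimates, cov x scale^2);
the CI is the 2.5/97.5 percentile band of 1000 draws and a term is
significant when its band excludes zero.  Degrees of freedom follow the
between-within convention — treatments are randomised to groups, so
treatment contrasts carry df = n_groups - p (n - p when the random
intercept is absent or collapsed).  Validation at the study design
(500 simulated datasets) puts coverage at ~95%; with df = n - p the same
intervals undercover (~92%) because twelve groups, not forty sharks, are
the effective replicates.  Random-effect variances are held at their
point estimates during simulation — a stated limitation shared with the
R-ecosystem tooling this mirrors.  No multiplicity correction is applied
across the 15 trait models; the Bonferroni correction (alpha = 0.0005 for
105 pairs) applies only to the correlation screen, and a "strong"
correlation additionally requires r > 0.80 at p < 0.001.  Lateralisation
distributions are compared across cells by two-sample Kolmogorov–Smirnov
tests (all pairs by default; an each-vs-ambient mode is provided, since
either reading is defensible) and variances by Bartlett tests.

## Power

Power for a fixed effect is the rejection fraction over simulate–refit–
test replicates, with a Wilson binomial CI.  The default in-loop test is
the hybrid between-within t: REML fit, t = beta/se with df = n_groups - p;
when the group variance collapses to the boundary the mixed model *is*
OLS and the exact OLS t (df = n - p) is used instead.  Measured size at
the study design is 5.0% (2000 null replicates).  The likelihood-ratio
chi2 test of nested ML fits — the R-ecosystem convention — is available
as `test_rule="lrt"` but is anticonservative with this few groups
(measured size ~9%), which is why it is not the default.  In the
degenerate no-random-effect case the refits are OLS and the nested F test
is exact, coinciding with the two-sample t test for a single coefficient;
a closed-form noncentral-t oracle validates this path to within
Monte-Carlo error.

`required_groups` evaluates the power curve on an increasing grid of
groups per cell with common random numbers and reports both the strict
answer (smallest count with power > 80%) and a plateau answer (power >
80% and < 2-point gain to the next grid point), since "grown until power
plateaued above 80%" admits both readings.  `ratios_to_effects` converts
meta-analytic treatment/control ratios (defaults 1.67 temperature, 1.06
pCO2, 1.60 interaction) to additive effects via (r - 1) x intercept.

Reproducing the original study's observed powers (54/62/98%) is out of
scope: they depend on variance components of field-data fits that were
never published.  The machinery that would compute them is what is
tested, against calibration targets that have known answers.  Post-hoc
("observed") power needs no special mode: fit a trait model, then feed
its own estimates — intercept, effects, group and residual SDs — into a
`PowerSpec`.

## Numerical choices and problem sizes

Default synthetic problem sizes keep the full validation suite fast while
leaving estimator behaviour asymptotically visible: O2 traces at 2-s
sampling (43k samples/trial), 500-dataset coverage runs, 1000-replicate
power estimates, 100-replicate noisy-titration runs.  Root-finding for
carbonate speciation brackets [H+] in [1e-12, 1] with Brent's method at
1e-14 relative tolerance; the decay fit bounds a, k positive and retries
are unnecessary on generator data.  GaussianMixture uses three
initialisations with a 1e-10 covariance floor so that near-degenerate
(noiseless) determination sets remain fittable.

## Known limitations

* The CO2 solver covers exactly the study's use case: NBS-scale pH input,
  Mehrbach-refit constants, no pressure correction, no nutrient
  alkalinity, no alternative constant sets.
* MLND component count is capped at 4; multimodal activity patterns
  beyond that are absorbed into the highest component.
* Posterior-simulation CIs ignore variance-component uncertainty; with
  very few groups they can still undercover for extreme
  intraclass correlations.
* The between-within df rule is exact for balanced designs and an
  approximation under the mild group-size imbalance (3 vs 4) used here.
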