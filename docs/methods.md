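# Methods

## Structural model

Gadofosveset distributes between blood and the extravascular-
extracellular space and is cleared only by the kidneys; no metabolism is
modelled. The minimal-PBPK topology — blood pool, liver/portal vein, and
one single adjusted compartment (V_sac) — carries zero hepatic
extraction, which makes the liver loop kinetically silent, so the model
is implemented as its exact two-compartment reduction: central volume V1
(blood pool) with renal elimination clearance CL, peripheral volume V2
(V_sac) exchanging with the centre via the distribution clearance Q.

For an IV bolus the solution is bi-exponential with rate constants α > β
(the roots of x² − (k10+k12+k21)x + k10·k21, k10 = CL/V1, k12 = Q/V1,
k21 = Q/V2) and amplitudes A = (α−k21)/(V1(α−β)),
B = (k21−β)/(V1(α−β)). Concentration, cumulative urinary excretion and
the compartment amounts are all evaluated in closed form; a Runge-Kutta
integration of the same ODEs exists only as an independent oracle in the
test suite. Mass balance (central + peripheral + urine = dose) is exact
to numerical round-off, and AUC(0–∞) = dose/CL identically.

## Parameterisation of the reference subject

The compound's printed inputs (dose 30 mg/kg, CL, Vss 0.148 L/kg, both
half-lives, and the observed peak) over-determine a two-compartment
model, so a choice of anchors is required. The defaults prioritise the
peak concentration and the distribution half-life:

| parameter | default | unit | role |
|---|---|---|---|
| dose | 30 | mg/kg | IV bolus at t = 0 |
| V1 | 0.0545 | L/kg | calibrated so C(0) = dose/V1 ≈ 550 mg/L |
| Vss | 0.148 | L/kg | V2 = Vss − V1 |
| CL_ref | 0.5 | L/h | renal CL of the 74-kg, GFR-96 reference male |
| t½ dist | 0.48 | h | pins Q via the fast-root equation |
| t½ elim | 16.3 | h | stored input; the model's terminal phase *emerges* at ≈ 16.1 h |
| K_d | 85 | µM | albumin binding; fu = K_d/(K_d+[Alb]) |
| albumin | 45 | g/L | ≈ 677 µM at MW 66,500 → fu ≈ 0.11 |

With V1, V2 and CL fixed, Q = 3.473 L/h is the unique positive solution
making α = ln2/0.48; the emergent elimination half-life is 16.08 h,
within 1.5 % of the labelled 16.3 ± 2.6 h. The alternative
parameterisation from (CL, Vss, both half-lives) is available as
`solve_subject_pk`, which has the closed-form inverse
V1 = CL/(α + β − αβ·Vss/CL) and reports infeasibility (no positive
volumes) by naming the violated constraint. The labelled elimination
half-life appears in two variants (16.3 h and 18.5 h) in different
sources; the default stores 16.3 h and 18.5 h is reachable by config
override.

Binding is single-site and non-saturating (ligand ≪ albumin), so fu is
a pure function of cohort albumin. fu deliberately does **not** rescale
renal clearance: the observed CL (~0.5 L/h) sits far below the
theoretical filtration clearance fu×GFR (~0.86 L/h for a young male at
GFR 130 mL/min), and a single linear GFR–CL relation holds across all
cohorts including low-albumin cirrhosis, so clearance is treated as an
empirical input scaled by GFR alone. `theoretical_filtration_clearance`
exposes the fu×GFR bound with the textbook young-male GFR of 130 mL/min
as its default.

## Virtual cohorts (the synthetic-data generator)

The generator emulates cohort-level physiology — weight by sex, age,
GFR, plasma albumin — with truncated normal distributions; no organ-level
demography, no creatinine-based GFR equations, no age-dependent
physiology (age is recorded but drives nothing). The published study
reports only cohort summary tables, so the distribution parameters are
this package's own calibration against those tables and are fixed as
defaults:

* **weight means** (kg, pooled sexes; SD 12, sex offset ±6): mean
  administered dose ÷ 30 mg/kg per cohort — healthy 73.8, renal 70.2,
  obese 99.9, cirrhosis 76.1, oncology 74.3;
* **GFR means** (mL/min; SD 12 % unless noted): back-calculated from the
  cohort mean clearances via CL = 0.5·GFR/96 — healthy 108, obese 145,
  cirrhosis A/B/C 77/79/88, oncology 96; moderate renal impairment uses
  mean 56, SD 4, truncated to its defining 30–60 band (a 12 % SD would
  let the truncation drag the effective mean and overshoot the AUC
  fold); severe renal impairment uses the effective value 46 that
  reproduces the published CL of 0.24 L/h, although that exceeds the
  cohort's nominal "GFR < 30" label — the published CL and AUC values
  are internally inconsistent with a strictly sub-30 GFR under any
  linear GFR–CL law that also fits the healthy cohort, and the printed
  values are prioritised;
* **albumin** (g/L; SD 3): 45 for healthy/renal/obese, 38/31/25 for
  cirrhosis A/B/C, 39 for oncology — affects only the reported fu;
* **volume expansion**: cirrhosis A/B/C multiply both V1 and V2 by
  1.25/1.55/1.95, modelling ascites/edema. For a bolus, C(0) = dose/V1
  is independent of V2, so an expansion confined to the peripheral
  compartment cannot lower the peak; the multipliers are therefore
  applied to the whole distribution volume, which reproduces the
  declining cirrhosis Cmax gradient while leaving AUC = dose/CL
  untouched;
* **central-volume variability**: a lognormal factor on V1 per subject
  (mean 1, CV 15 %, matching the ~15 % spread of the published healthy
  Cmax). Without it the model's Cmax would be the constant
  30 mg/kg ÷ 0.0545 L/kg for every subject and Cmax comparisons would
  be degenerate. The deterministic reference subject uses scale 1.

Sampling is counter-based: each subject's stream is seeded by
(global seed, cohort label, trial, subject), so results are independent
of draw order and any subject is reproducible in isolation.

What passing tests show — and do not show — about real data: the
generator reproduces the *between-subject variability structure assumed
here* (independent truncated normals, exact linear GFR–CL coupling), not
real covariance between weight, renal function and albumin, nor
measurement error, dropout or sampling-time jitter. Cohort-level
agreement with published tables validates the calibration, not the
underlying proprietary physiology it emulates.

## Trial engine and NCA

The design is 10 trials × 10 subjects, first ⌈0.5·n⌉ slots of each trial
female (making the 0.5 female fraction exact rather than Bernoulli),
dose = 30 mg/kg × weight, horizon 72 h. Pooled statistics are computed
over all 100 subjects (the published SDs are subject-level magnitudes);
per-trial means are also reported. Profile envelopes are empirical
point-wise 5th/95th percentiles by default.

NCA conventions (the study does not state its own): linear trapezoid on
the sampling grid (0.05-h steps to 2 h, then 0.25-h steps — dense enough
that the linear/log-trapezoid difference is < 0.1 %); λ_z from an OLS
log-linear fit over the final 24 h (safely past the 0.48-h distribution
phase); AUC(0–∞) = AUC(0–last) + C_last/λ_z; CL = dose/AUC(0–∞); the
reported "AUC" is AUC(0–∞), because the published healthy AUC matches
mean dose / mean CL and exceeds any 0–72 h reading, and both values are
exported. The bi-exponential fit is nonlinear least squares on the log
scale (log-sum-exp form), initialised by curve stripping, and flags
mono-exponential (non-separable) profiles as degenerate rather than
returning arbitrary phases.

## Statistics

Comparisons are log-scale: one-way ANOVA with Dunnett many-to-one
adjusted p-values (scipy's multivariate-t implementation), significance
stars at 0.05/0.01/0.001, GMR with pooled-variance two-sample t
confidence intervals, and a fixed equivalence band of 0.8–1.2 on the GMR
("GMR ± 0.2", matching the published forest plot's dashed bounds, not a
CI half-width). AUC fold changes are ratios of arithmetic means (the
published folds 1.8/2.2 are reproduced by arithmetic, not geometric,
means); both are reported. Subject-level values (n = 100 per cohort) are
the default analysis unit; trial-level means remain available in the
results.

## Numerical choices and degenerate inputs

* α/β are computed with the stable companion-root form β = k10·k21/α;
  the discriminant is strictly positive for all positive parameters.
* Feasibility of the macro→micro inversion is checked analytically, not
  by optimiser failure.
* `fraction_excreted` and C(1 h) interpolate linearly between grid
  points; queries outside the grid are errors, not extrapolations.
* Quantile envelopes require ≥ 2 profiles on a common grid.
* Dunnett p-values use a fixed internal random state, so comparison
  tables are byte-reproducible.

## Problem sizes

The canonical study simulates 8 cohorts × 100 subjects on a 321-point
grid with a full NCA (including a nonlinear fit) per subject, and
completes in a few seconds on one CPU. Validation of the sampling
distributions uses 10,000 draws per cohort; the Dunnett type-I-error
simulation uses 500–1,000 null replicates of three 100-subject groups.

## Known limitations

* Cirrhosis urinary fractions: the published fe values (0.74/0.60/0.51)
  are not reachable in a renal-only two-compartment model at the
  published clearances; the model reproduces the monotone decline but
  at higher absolute values. Likewise renal-cohort fe values are
  directionally, not absolutely, reproduced.
* The oncology cohort is calibrated directionally (AUC ≈ 1.1× healthy)
  only; the physiology source it emulates is not fully specified.
* No infusion or multiple dosing, no saturable binding, no transporter
  kinetics, no blood/plasma partitioning, no assay error model, no
  crossover designs or dropout.
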