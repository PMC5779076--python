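# Methods

`eadpredict` measures, for a drug characterised only by ion-channel pIC50s
and a therapeutic plasma concentration, how much of a disease-mimicking
perturbation a human ventricular myocyte model tolerates before early
afterdepolarisations (EADs) appear.  The resulting thresholds are used as
ordinal pro-arrhythmic (Torsades de Pointes, TdP) risk markers and fed into
simple classifiers and linkage analyses.

## Cell model

The ionic model is the O'Hara–Rudy (2011) endocardial human ventricular
myocyte model, transcribed from the original equation supplement with no
CiPA-era or dynamic hERG-binding modifications: 41 state variables
(membrane potential, 6 ion concentrations, 2 SR calcium pools, the CaMK
trap fraction and 31 Hodgkin–Huxley-type gates).  Two families of hooks
parameterise it:

* multiplicative scale factors on the maximal conductances/permeabilities of
  I_Na, I_CaL, I_Kr, I_Ks, I_NaL (the late/persistent sodium current —
  "I_pNa" in the drug table maps onto G_NaL), I_to and I_K1;
* an additive depolarising shift (mV) of the fast-sodium inactivation
  dynamics.

**Inactivation shift semantics.**  The shift replaces the voltage argument
of the *entire* fast-Na inactivation process — the steady-state curves of
h (fast and slow components) and j, their time constants, and the
CaMK-phosphorylated steady states — by `V - shift`.  Activation (m) is
untouched.  This reading was fixed by behaviour, not taste: shifting only
the steady-state curves (in any combination of h/j/phosphorylated variants)
either abolishes shift-induced EADs entirely on [0, 20] mV or displaces the
control threshold by ~0.4 mV, while shifting the full dynamics reproduces
the known control threshold for this protocol (17.41 mV) to 0.03%.

Drug block is conductance-only pore block with Hill coefficient 1:
`g = ḡ / (1 + [D]/IC50)`, with `IC50(nM) = 10^(9 - pIC50)` converted in a
single place.  Concentrations default to each drug's EFTPC_max.  Hill
slopes are deliberately not fitted per drug (experimental slopes are too
variable to help); the coefficient can be overridden in configuration but
the override is logged.

## Numerics

The stiff system is advanced by a hybrid adaptive scheme written for this
package: all 31 gate-like states (including the relaxation-form SR-release
fluxes and the L-type calcium `nca` mode fraction) are updated exactly over
each step with the Rush–Larsen exponential formula, while the 10 remaining
states take explicit steps.  Every step is error-controlled by step
doubling with Richardson extrapolation (locally second order); the
mixed error norm uses relative tolerance 1e-5 and absolute tolerance 1e-7
(defaults), the internal step is capped at 1 ms, and steps never straddle a
stimulus on/off edge, so the discontinuous forcing is handled exactly.
Tolerance halving moves the end-of-pace potential by well under 0.1 mV, and
an independent stiff solver (LSODA at rtol 1e-7) run on the same
right-hand side agrees with the integrator to ~1e-4 mV over
multi-second windows, including the delicate depolarised-plateau regimes.
Exponential-ratio singularities in the GHK-type flux expressions are
series-expanded near V = 0.

Pacing applies −25.5 µA/µF for 3 ms every 3 s (bradycardic, EAD-permissive;
the stimulus charge is booked against K+ as in the source model).  *Steady
state* means the Euclidean norm of the change in the full, unnormalised
state vector between consecutive end-of-pace states falls below 1e-6, up to
10 000 paces (the drug-free model needs ~780 paces from the published
initial conditions).  The 2-norm was chosen where the stopping rule's norm
was underdetermined; the threshold is configurable so a max-norm reading
can be emulated.  Drugs whose baseline dynamics alternate (the three
baseline-EAD compounds) never satisfy any norm criterion; the pace cap
applies and the final state is used, flagged.

## EAD detection and the third morphology

A trace sampled at 0.1 ms contains an EAD when the slope between adjacent
samples strictly exceeds +1 mV/ms at a time outside [−50, +100] ms around
every stimulus (slope assigned to the left sample; at 0.1 ms sampling the
choice is immaterial).  The detector is purely slope-based and therefore
invariant to constant voltage offsets.

Afterdepolarisation pathology has a third face: beats that never repolarise
at all.  In this transcription, severe repolarisation impairment (very
strong hERG block, large inactivation shifts) produces a *smooth* sustained
plateau near −10 mV — verified against the independent solver, so it is the
true trajectory and not numerical damping — with no discrete
supra-threshold upstroke for the slope rule to find.  A separate predicate
flags a beat as failed when the voltage minimum over the last 500 ms of a
diastolic interval stays above −40 mV.  The −40 mV line separates two
regimes observed in practice: failure plateaus sit near −10 mV, while the
benign slow creep seen at inactivation shifts just above the EAD window
settles at −41…−46 mV and still counts as repolarised.

## Threshold search

Per drug: apply block at EFTPC_max, pace to steady state once, save the
state, then for each intervention bisect on its standard interval
(I_CaL × on [1, 80], I_Na shift on [0, 20] mV, I_Kr × on [0, 1] with
severity toward 0), re-simulating 12 s from the saved state at each iterate
and stopping when the bracket is below 1e-4.  Interventions act on top of
drug block.  I_Kr thresholds are reported as the conductance fraction
remaining.  The reported threshold is the final bracket midpoint.

The slope-detectable EAD region is not always a half-line.  For the
inactivation shift it is typically an interior window (e.g. [17.41, ~19] mV
drug-free; [15.45, ~15.9] mV under cisapride): beyond the window the cell
slides into the sub-take-off creep described above.  Plain bisection
converges onto the window's *lower edge* — the minimal provoking
intervention — whenever a midpoint lands inside the window; when every
midpoint misses (narrow windows), a uniform bracket-recovery sweep from
mild to severe finds the first EAD-positive level and the bisection
restarts on that bracket.  When no slope EAD exists at any level, the
search runs again with the repolarisation-failure criterion and reports the
failure onset, marked `mode="repolarisation_failure"` (this is how most
I_Kr thresholds arise).  Only if both searches come up empty is the drug
`not_provokable`.  The baseline (no-intervention) run is checked first with
the combined criterion; drugs already pathological get
`ead_at_baseline`.  Bisection assumes the region above the reported onset
is the relevant one; possible multi-window structure below the sweep
resolution would be missed — the resolutions used (0.25 mV on the shift
axis at defaults) are finer than the narrowest window observed (~0.45 mV).

## Comparator biomarkers

APD at any repolarisation fraction is measured on the final pace of a
trace: upstroke = first sample with dV/dt > +10 mV/ms, amplitude = peak
minus pre-upstroke diastolic potential, duration to the first downward
crossing of `peak − fraction × amplitude` (linear interpolation at the
crossing; NaN for repolarisation failure).  Diastolic Ca is the minimum
intracellular calcium over the final pace.  The hERG safety factor is
log10(hERG IC50 / EFTPC_max).  All biomarkers here are computed on the same
endocardial model as the thresholds; the comparator literature computed
APD90 on a different ventricular model, so absolute APDs are not
comparable across studies — the classifiers consume them ordinally, which
softens the difference.  Externally computed metric columns can be supplied
to the classification layer directly.

## Classification and linkage

Metrics (any subset/combination) feed two classifiers over TdP risk
categories 2–5 (Redfern-style, categories 1 and 2 pooled): linear
discriminant analysis (per-category Gaussians, pooled covariance, empirical
priors) and a linear-kernel SVM (one-vs-one, margin penalty C = 1 — the
minimal reading of a maximum-margin hyperplane classifier; no kernel was
specified by the comparator methodology).  Evaluation is the mean absolute
category error E = (1/N) Σ|a_i − c_i| under leave-one-out or seeded
five-group cross-validation (uniform random partition; the original
partition seed is unknowable, so real-data accuracy claims are
property-based rather than value-based).  Degenerate folds fall back
deliberately: a single-category training fold predicts that category; an
LDA fold with as few samples as categories degrades to nearest class
centroid.  Drugs missing a metric or label are dropped from that run, with
the roster logged.

For linkage analysis, metric columns are normalised (control shifted to 0,
scaled into [−1, 1]), drugs are clustered agglomeratively on Euclidean
distance (average linkage by default; single/complete/ward selectable — the
comparator analysis named only the metric, not the linkage), and leaves are
reordered by subtree rotations to best match ascending category order
(2,2,…,3,3,…) — "descending risk".  The rotation optimum is exact (dynamic
programme over subtree placements, equivalent to enumerating all
2^(internal nodes) rotations).  The ranking error is reported as the mean
of squared deviations from the sorted ideal (the 1/N normalisation is
stated with the metric; the raw sum is also available).

## Synthetic data

Two generators back the test suite.  Piecewise-linear AP-like traces with
triangular depolarising bumps of chosen slope/timing provide detector and
biomarker inputs whose ground truth is known by construction (bump and AP
breakpoints are aligned to the sample grid so per-sample slopes are exact);
they emulate the geometry of simulated traces, not the electrophysiology —
passing detector tests says nothing about the ionic model.  Gaussian metric
tables with strictly ordered per-category means (categories round-robin,
default noise SD 0.25 at unit separation) provide classifier/linkage inputs
where separability is a dial: zero noise must give zero cross-validated
error, shuffled labels must fall to the label-frequency null (1.25 mean
absolute error for uniform categories 2–5).

## Problem sizes used in the automated checks

The threshold tests in `tests/test_acceptance.py` and the
`scripts/acceptance.py` pipeline run the full protocol (tolerances 1e-5 /
1e-7, steady state to 1e-6, bisection to 1e-4, 12 s test windows).  The
whole-table scan backing the ordinal lowest-threshold check uses reduced
sizes chosen as a deliberate compromise — 60 pre-pacing paces, 6 s test
windows, bisection gaps 0.1 (I_CaL), 0.05 (shift, I_Kr) and sweep
resolutions 12/50/20 points: spot checks against fully paced runs showed
individual thresholds move by ~1–2% while the cross-drug ordering is
stable, and the zero-intervention trio is identified identically at 60,
100 and 500 paces.

## Known limitations

* The pore-block model ignores state-/use-dependent binding and active
  metabolites (amiodarone is the canonical caveat) and any hERG binding
  kinetics.
* Only the endocardial parameterisation is implemented; no epicardial or
  mid-myocardial variants, no tissue-level simulation.
* The oscillatory-vs-smooth character of failed-repolarisation plateaus is
  solver- and formulation-sensitive in the literature; this package pins
  the behaviour with an independent-solver cross-check and treats sustained
  failure as its own EAD morphology rather than relying on fragile plateau
  oscillations.  A consequence: drugs whose entire pathology is the smooth
  plateau (single-channel strong hERG blockers such as terodiline or
  clozapine) receive failure-onset rather than slope-onset thresholds, which
  shifts their position in cross-drug rankings under the I_Na-shift and
  I_Kr interventions relative to analyses whose plateaus oscillate; the
  I_CaL ranking is unaffected.
* Risk categories for 29 of the 41 bundled drugs are defaults under the
  stated Redfern/Mirams rule (flagged per row in `risk_labels.csv`), not
  values confirmed by the source text; classification numbers on the
  bundled labels should be read accordingly.
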