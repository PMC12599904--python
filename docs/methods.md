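# Methods

## Problem

Vancomycin dosing in critically ill patients is steered by therapeutic
drug monitoring (TDM): trough concentrations (the level just before the
next dose) are kept inside the 15–20 μg/mL window — below it the
antibiotic may fail, above it nephrotoxicity risk climbs. Troughs are
measured sparsely, while doses are given every 8–48 hours, so the
clinical question is a *sequential prediction* problem: given a patient's
covariates and dosing history, what will the trough be at each upcoming
administration, and which dose–interval combination will keep it in
range?

## Feature engineering

Each dosing event is summarised by 16 covariates: sex, age, height,
weight, dosing interval, injection-to-draw time, loading-dose flag,
dialysis status, serum creatinine (forward-filled from the most recent
measurement), average volume of distribution, elimination rate constant,
infusion duration, dose per infusion, cumulative dose, MDRD eGFR and
vancomycin clearance. The derived quantities are recomputed at every
dose from the latest creatinine:

- Creatinine clearance (Cockcroft–Gault):
  CrCl = (140 − age)·weight·K / (72·Scr), K = 1.0 (male) / 0.85 (female).
- Vancomycin clearance, linear in CrCl:
  CL = (0.695·CrCl/weight + 0.05)·weight·0.06 L/h — the 0.06 converts
  mL/min to L/h; the intercept is non-renal clearance.
- eGFR: 4-variable re-expressed MDRD, 175·Scr^−1.154·age^−0.203·(0.742
  if female). No race coefficient (race is not a model covariate); the
  leading coefficient is configurable.
- Vd = 0.7 L/kg · weight and ke = CL/Vd. These are the standard
  one-compartment adult values; both coefficients are configurable
  (`PkCoefficients`).

Conventions worth knowing: the first dose of a course has `interval_h
= 0` (kept, not dropped); "administration time" is interpreted as
infusion duration in hours; the injection-to-draw feature uses the
actual delay when a trough was drawn after that dose and the gap to the
next dose otherwise; records with no creatinine to carry forward are
excluded.

## Preprocessing

Continuous covariates are min–max scaled to [−1, 1] with bounds fitted
on the training split only; the loading and dialysis flags stay {0, 1}.
Troughs are additionally bucketed into three ordered ranges —
sub-therapeutic (< 15), therapeutic (15–20, endpoints inclusive), toxic
(> 20 μg/mL) — and encoded as two cumulative binaries ("above 15?",
"above 20?"). A trough of exactly 15 or 20 is therapeutic (the toxic
range is strictly > 20; the printed therapeutic range "15–20" assigns 15
upward). Training sequences are truncated to a configurable maximum
length (default 25; a tuned setting of 20 is also reported for the
reference model, so the knob is exposed), keeping the **most recent**
events; evaluation sequences are never truncated. Each trough is
attached to the latest dose preceding the draw; the mask M marks exactly
those dose events. Padded steps carry zeros and M = 0, so they
contribute nothing to loss or metrics. Gaps of ≥ 14 days between doses
split a patient's history into independent courses when the latest MDRD
eGFR is ≥ 60 mL/min/1.73 m² ("normal renal function"; the threshold is
configurable because the source of the rule does not define "normal").

## Model

The network (GointMLP) has three stages, run per time step:

1. **Sequential module** — L stacked GRU layers of H units. Gates are
   z = σ(W_z·[h_{t−1}, x_t]) and r = σ(W_r·[h_{t−1}, x_t]), candidate
   h̃ = tanh(W·[r⊙h_{t−1}, x_t]), update h_t = (1−z)⊙h_{t−1} + z⊙h̃_t.
   The gates carry no bias terms, matching the printed formulation. A
   variant update h_t = (1−z)⊙x_t + z⊙h_{t−1} — which never uses the
   candidate state — exists behind `printed_update=True` for comparison;
   the standard update is the default because the variant leaves the
   candidate equation dead.
2. **Joint module** — N parallel MLPs over the top GRU state. Each MLP's
   first layer is an attention layer: LeakyReLU affine map, elementwise
   product with a learnable prior vector p (initialised to ones), then
   **sparsemax** (the Euclidean projection onto the probability simplex,
   which unlike softmax produces exact zeros). The attended activation
   feeds D−1 further LeakyReLU affine layers (negative slope 0.01) of U
   units.
3. **Decision module** — the N MLP outputs are concatenated. A linear
   head emits the trough regression ŷ (μg/mL); a CORAL-style ordinal
   head emits K−1 = 2 logits from a **shared** weight vector with one
   bias per threshold, the second bias clamped to min(b₁, b₂) so
   P(y > 15) ≥ P(y > 20) holds for every input by construction.
   Independent per-threshold classifiers are available via
   `shared_ordinal=False`.

The training objective is masked and multi-task:

L = mean_{M=1}[(ŷ − y)²] + λ · mean_{M=1}[Σ_{k=1}^{K−1} BCE(ŷ_k, y_k)]

Steps without a measured trough (M = 0) contribute exactly zero to the
value and to every parameter gradient (verified by finite differences in
the tests). λ defaults to 0.29.

Class decoding counts thresholds cleared cumulatively (rank repair: the
count stops at the first probability ≤ 0.5). A prediction is flagged
*consensus* when the regression output, re-bucketed through the 15/20
thresholds, agrees with the classifier's range — disagreement marks the
prediction as lower-confidence for the clinician.

The reference architecture is L = 3, H = 15, N = 15, D = 5, U = 64.
Weights are initialised uniform ±1/√fan-in from a recorded seed. The
whole network, its reverse-mode gradients and the Adam optimiser are
implemented in numpy (float64), which makes seeded runs bit-reproducible
on a single machine.

## Training

Adam (β = 0.9/0.999), constant learning rate, optional global-norm
gradient clipping (default max norm 0.5), minibatches over courses.
Early stopping watches masked validation RMSE with a warm-up: stopping
cannot trigger before `warmup_epochs`, and the returned weights are
those of the best post-warm-up validation epoch. The full-scale protocol
is 1000 epochs, batch 512, lr 5e-4, patience 50, warm-up 300; the
package's reference desk-scale protocol (used by the shipped experiments)
is 350 epochs, batch 128, lr 1e-3, warm-up 100, patience 60, which
trains the full architecture on a 500-patient synthetic cohort in a few
minutes on one CPU. Hyperparameter search is seeded random sampling over
the documented ranges with k-fold cross-validation scored by mean masked
validation RMSE (a Bayesian sampler can replace the random one by
pre-sampling candidates).

**Fine-tuning** continues optimisation from trained weights on a
patient-level fraction (default 10%) of a new cohort, at a reduced
learning rate (default 1e-4) with early stopping on a validation split
carved from the fine-tuning subset itself. The lower rate and
self-contained early stopping matter: with only tens of trough
observations, full-rate fine-tuning overfits within tens of epochs.

## Dose recommendation

Two functions sit on the trained predictor. *Regimen simulation* appends
hypothetical future (dose, interval) events to a patient's history —
covariates carried forward, cumulative dose updated — and reads the
predicted trough at each appended event; dose and interval may change at
every future step. *Recommendation* scores a fixed clinical menu —
general ICU: intervals {8, 12, 18, 24, 48} h × doses 15–20 mg/kg in
1 mg/kg steps (30 candidates); dialysis: 12 h × 7.5–10 mg/kg in
0.5 mg/kg steps (6 candidates) — by simulating 4 repeated cycles of each
regimen (configurable; the caller asserts near-steady-state) and keeps
candidates whose predicted trough lies in [15, 20] μg/mL, endpoints
inclusive. Doses are interpreted as mg per kg body weight.

## Synthetic cohort generator

No patient data ships with the package; the generator defines the study
conditions. Kinetics are one-compartment with zero-order infusion
superposition: during an infusion of rate R₀ the contribution is
(R₀/CL)(1 − e^(−ke·τ)); afterwards it decays with ke = CL/Vd; a zero
infusion duration is a bolus. The steady-state trough of repeated
bolus dosing matches (D/Vd)·e^(−ke·τ)/(1 − e^(−ke·τ)) within 1% in the
tests.

Per patient: covariates are drawn from an elderly medical-ICU profile
(age 65 ± 13 y, weight 62 ± 11 kg, 60% male, creatinine log-normal
around 0.9 mg/dL, 15% dialysis); true clearance is the covariate formula
times a log-normal inter-individual deviate (σ = 0.3, ≈ 30% CV, the
typical vancomycin figure), times 0.3 for dialysis patients (a crude
between-session reduction — deliberately not covariate-explained, since
the prediction model receives only the dialysis flag); true Vd is
0.7 L/kg × a log-normal deviate (σ = 0.15). Dosing starts near 15 mg/kg
(rounded to 250 mg) at an interval chosen nomogram-style from CrCl;
30% of patients get a 25 mg/kg loading dose. Troughs are drawn 0.5 h
before a random 35% of doses (≈ 2.1 troughs per course, matching
TDM-per-case ratios reported for ICU cohorts) with additive Gaussian
assay noise (σ = 1.0 μg/mL, truncated at zero). Creatinine drifts as a
daily log-normal random walk.

**Titration.** After each observed trough the maintenance dose is
adjusted the way clinicians respond to TDM: +25% if the trough was below
10 μg/mL, −25% if above 20, rounded to 250 mg. Without this the
simulated regimens would be static and consecutive troughs nearly
identical — unrealistically easy for naive carry-forward prediction and
unrepresentative of practice, where regimens change with patient status.
Titration also means the dose trajectory itself carries information
about earlier troughs, which the sequence model can exploit.

**Population shift.** The shifted cohort is 10 years younger, 20 kg
heavier, dosed 2.5 mg/kg higher, and — crucially — every patient's true
clearance is scaled by 0.8 relative to the covariate formula. That last
factor is a population-level miscalibration no covariate explains
(clearance formulas fitted on one population transfer imperfectly to
another); it gives the shifted cohort systematically higher troughs and
gives a base-trained model a systematic bias that only adaptation can
remove. Fine-tuning on 10% of the shifted patients corrects most of that
bias in the shipped experiment.

What the generator does *not* emulate: two-compartment distribution
phases, dialysis-session-resolved kinetics, covariate time-variation
beyond creatinine drift, informative TDM sampling (draws are random, not
triggered by clinical concern), and measurement-error structure beyond
additive Gaussian noise. Passing tests therefore demonstrate that the
pipeline learns and adapts under controlled PK-consistent conditions,
not that it attains any particular accuracy on real EMR data.

## Numerical choices and degenerate inputs

- float64 throughout; no threading; seeded `numpy.random.Generator`
  everywhere — two runs with the same seed produce byte-identical
  artifacts.
- Sparsemax support selection uses the exact sort-based rule; its
  Jacobian distributes gradient uniformly over the support.
- Binary cross-entropy is computed in the stable
  max(l,0) − l·t + log(1+e^(−|l|)) form; NaN targets (masked-out steps)
  contribute zero value and gradient.
- An all-zero mask yields loss 0 (no update) rather than an error during
  a minibatch; a batch with no masked-in target at all refuses to train.
- A constant continuous variable raises a degenerate-scale error naming
  the variable; binaries are exempt.
- Ties: a trough exactly at 15 or 20 is therapeutic; `minimum` routes
  gradient to its first argument on ties; titration rounding goes to the
  nearest 250 mg.
- Metrics are pooled over observations (not per-patient means) and each
  report carries its n. R² requires ≥ 2 observations and nonzero target
  variance; the paired t-test requires ≥ 2 pairs and nonzero difference
  variance — degenerate cases raise rather than return NaN.

## Problem sizes

Shipped experiment sizes were chosen so the whole suite runs on one CPU
in minutes: baseline comparison on 500 patients (≈ 1,050 troughs, 25%
of patients held out), shift experiment with 400 base + 300 shifted
patients and 10% fine-tuning, unit tests on 30–150-patient cohorts with
a topology-identical scaled-down network. The scaled-down network
measurably underfits the titration signal (held-out RMSE ≈ 6.5 vs ≈ 5.7–6.6
for the full architecture at 500 patients), which is why the reference
experiments use the full architecture.

## Known limitations

- The simulator's titration rule is deterministic and dose-only;
  clinicians also stretch intervals.
- The dialysis clearance multiplier is constant rather than
  session-resolved, so dialysis patients are the hardest subgroup for
  the model (as they are in practice).
- Regression and classification heads can disagree; the consensus flag
  surfaces this rather than hiding it, but no calibration of the
  disagreement rate is attempted.
- The recommendation engine trusts the regression head; if the model is
  biased for a patient subgroup, recommended regimens inherit that bias.
- Hyperparameter search is random; with small budgets its result is
  noisy, and the reference architecture was fixed from the documented
  tuned values rather than re-searched.
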