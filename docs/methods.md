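# Methods

## The model

`lqrg` models loco-regional tumor control after fractionated radiotherapy.
The quantity being predicted is the loco-regional progression-free survival
curve LPFS(t), with t the time from the end of radiotherapy; deaths and
distant-only failures are censoring events, not failures.

### Cell survival

The extended linear-quadratic model (LQRG) writes the log surviving
fraction of clonogenic cells after a course delivering total dose D over
treatment time T as

```
ln SF(t) = -alpha*D - beta*G(tau_R)*D^2 + (sigma^2/2)*G(tau_S)*D^2
           + ln2 * max(0, T - T_k)/tau_P + (ln2 * t/tau_P)^delta
```

Term by term: one-track killing (`alpha`); two-track killing attenuated by
the dose-protraction factor at the repair time (`beta`, `tau_R`);
resensitization — the common outcome of redistribution and reoxygenation,
modelled as a variance `sigma^2` of the radiosensitivity distribution that
regenerates with time constant `tau_S` (this term *reduces* net kill
heterogeneity-wise, hence its positive sign); in-treatment repopulation
with doubling time `tau_P` after a lag `T_k`; and Gompertzian post-treatment
regrowth with exponent `delta` (sub-exponential: regrowth decelerates).

The classical LQ baseline keeps `-alpha*D - beta*D*d` (complete
inter-fraction repair, G = 1/n) and pure exponential repopulation
`ln2 * max(0,T-T_k)/tau_P + ln2 * t/tau_P`. The post-treatment part of the
classical model is a reconstruction: only its parameter count (5) and the
fitted repopulation constants pin it down, and the natural choice —
the LQRG formula with `sigma^2 -> 0`, `delta = 1`, `tau_R -> 0` — is what
is implemented. The equivalence in exactly that limit is tested.

**Regrowth clamp.** The repopulation term is clamped at `T = T_k`: a course
shorter than the lag earns no repopulation credit. The unclamped form would
*reward* short courses with negative repopulation, which is biologically
meaningless. The clamp is a deliberate choice and is applied identically in
SF and BED so the identity `-ln SF(0) = alpha * BED` holds exactly.

### Dose protraction

The generalized Lea-Catcheside factor

```
G(tau) = (2/D^2) * int_0^T R(u) du int_0^u R(w) exp(-(u-w)/tau) dw
```

is evaluated exactly (pairwise exponential sum) for schedules of
instantaneous fractions — the delta-function limit where quadrature is
singular — and by adaptive quadrature (absolute tolerance 1e-8) of a
closed-form inner integral for finite fraction durations. Closed forms for
n equally spaced acute fractions and for a single constant-rate exposure
serve as oracles; results are cached per (schedule, tau).

### TCP

With K_0 = rho*V initial clonogens, the LQRG TCP is Gaussian-threshold:
`TCP = 1 - Phi((K_0*SF - K_cr)/sigma_k)` — the tumor is controlled when the
surviving number falls below a critical count K_cr with population spread
sigma_k. The classical baseline uses the Poisson zero-survivor form
`exp(-K_0*SF)` (exact binomial `(1-SF)^K_0` is selectable; the two agree to
1e-6 whenever `K_0*SF^2 < 1e-6`). Whether the original baseline used the
exact binomial or its Poisson limit is not documented; at `K_0 ~ 1e11` and
the SF values involved the difference is far below every tolerance used
here, so the Poisson form is the default. The Gaussian argument is used as
printed, without truncating negative mean counts.

TCP(t) evaluated on a follow-up grid is the model's LPFS prediction; it is
non-increasing because SF grows with t.

## Schedules and units

Schedule arithmetic is in hours; repopulation/Gompertz terms are evaluated
in days (`tau_P` is a doubling time in days, `T_k` hours -> days at the
boundary); follow-up times are months (30.4375 days). Default delivery is
instantaneous fractions, once daily, weekdays only (five fractions per
seven-day week), which reproduces the cohort's overall-treatment-time
medians from the fraction counts to within the trailing partial week.

A group known only by summary statistics gets a representative schedule:
n = round(mean total dose / median fraction size) fractions. The dose per
fraction is set to `mean_total_dose/n` rather than the median fraction size,
so the schedule delivers the group's mean dose exactly (the median is kept
as the nominal fraction size). With nominal `n*d` doses instead, the
2.4 Gy and 2.8 Gy groups' TCP curves nearly coincide and can swap order;
using the delivered mean dose keeps the model's group ordering consistent
with the clinical one (C > B > A). The true per-patient schedules are
unknowable from summaries, so this convention is a documented choice, not
a claim about the source analysis.

## Fitting

The cost is the pooled mean absolute error between TCP(t_i) and the KM
value at each sample time, one sample per patient record (so the sample
count equals the cohort size). MAE minimization is read as maximum
likelihood under Laplace residuals, giving the surrogate log-likelihood
`LL = -m(ln(2*MAE) + 1)` and `AIC = 2k - 2LL` with k the number of free
parameters actually fitted.

The optimizer is gradient descent with central finite differences
(relative step 1e-5) and Armijo backtracking, in log-parameter space within
wide positivity boxes, from 16 deterministic starts by default (first at
the init, the rest log-normal perturbations, spread 0.5). Convergence:
best-cost improvement below 1e-7 for 50 consecutive iterations, or 5000
iterations. MAE is non-smooth at zero residuals, so late convergence is
slow; the line search keeps the iteration stable there.

**Identifiability.** The full 11-parameter LQRG vector is not identifiable
from ~100 KM samples of three groups: several parameters enter only through
products (e.g. `beta*G(tau_R)`), and the clonogen-count constants trade off
against `rho`. The pipeline therefore defaults to freeing the
dose-response/shape subset (`alpha, beta, sigma2, tau_P, T_k, delta`) for
LQRG and all five LQ parameters, with AIC computed at the honest free
counts; recovery tests free `alpha` alone, as the cleanest identifiable
probe. Any mask can be requested explicitly.

Confidence intervals: curvature (numeric Hessian) of the surrogate
log-likelihood at the optimum in log-space, transformed back; singular
curvature falls back to percentile bootstrap over >= 200 seeded case
resamples of the fitting samples, refit warm-started from the point
estimate. Leave-one-out cross-validation refits with each sample withheld
(warm-started, single start) and reports
`100*(1 - mean relative absolute prediction error)`; folds with a zero
observed value are skipped and flagged.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any real
dataset: three groups with the packaged dose summaries (62.92/64.07/62.89
Gy mean dose; 2.1/2.4/2.8 Gy median fraction size; 105.83/102.21/108.51
cm^3 mean GTV), log-normal tumor volumes (CV 0.5 — a typical spread for
locally advanced lung tumors; the source summaries give means only),
failure times drawn from the group-level LQRG TCP(t) curve by
inverse-transform sampling, and administrative censoring with uniform
entry over a 41-month accrual and a 70-month horizon (the fitting window).
Default group sizes are 34/34/35.

What it does not emulate: per-patient delivered schedules, competing risks
(death, distant failure) beyond their role as censoring, volume-dependent
failure by default (group-mean volume is used for event sampling unless
per-patient mode is on), and the point mass of immediate failures implied
by TCP(0) < 1 — a model artifact accepted for consistency between
generator and fitted model. Passing recovery tests therefore show the
pipeline is self-consistent at realistic cohort sizes, not that the model
is correct for real patients.

Determinism: one master seed fans out to per-(group, patient) substreams,
so resizing one group never changes another group's records.

## Problem sizes used in the checks

Simulation-based checks run at sizes chosen to make their statistical
assertions stable on a single CPU: parameter recovery at 500 patients/group
over 10 seeds (alpha within 20% in >= 8/10); model-selection asymmetry on
103-patient cohorts over 10 seeds (LQRG beats LQ on AIC and LOO accuracy
in >= 9/10); KM convergence at 2000 patients (sup-difference < 0.05);
oracle agreement for G on 100 randomized schedules at 1e-8.

## Known limitations

* The protraction factors this package computes for the fitted repair time
  (0.0346/0.0384/0.0471 for the three groups) do not exactly match the
  values the source analysis reports for its LQRG fit
  (0.036/0.040/0.049): the exact dose-rate functions behind those numbers
  are unspecified. The complete-repair limits (1/n) do match. BED values
  differ correspondingly; only their ordering across groups is asserted.
* The classical-LQ post-treatment term and the fitting-error/likelihood
  conventions are reconstructions from the constraints stated above.
* Group-level fitting uses one representative tumor per group (mean GTV
  volume); per-patient heterogeneity enters only through the KM data.
* Gradient descent on a non-smooth MAE surface can stall near the optimum;
  multi-start and the patience-based stop mitigate but do not eliminate
  flagged non-convergence on hard masks.
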