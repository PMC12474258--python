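# Methods

This note documents the models, defaults and design choices behind
`zfscreen`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Assay and endpoint layer

The light–dark transition test records distance moved (cm) per larva in
2-min bins across a 20-min dark acclimation, 40-min light and 40-min dark
phase. `bin_track` reproduces the tracker-side semantics that matter for
analysis: per-sample displacements below the 0.02 cm noise floor are zeroed
*before* summation, and bins are half-open `[start, start + width)`. With the
standard protocol there are 20 light and 20 dark bins; acclimation bins are
never used by any endpoint.

The 13 endpoints are exact arithmetic on the light bins `l_1..l_m` and dark
bins `d_1..d_n`:

- `avgSL = mean(l)`, `avgSD = mean(d)`, `avgST = mean(l ∪ d)`;
- `hbt1 = (last − first)/(#bins − 1)` per phase — the slope is expressed per
  bin index (cm/bin per bin); any other time unit would rescale the endpoint
  uniformly and be absorbed by the Box–Cox standardization;
- `hbt2 = [(last − 2nd) − (2nd-to-last − first)]/(#bins − 2)` per phase;
- `RoA = max/(min + 1)` per phase (the “+1” is part of the definition, so
  `RoA` is deliberately not scale-invariant);
- `strtlA = d_1 − l_m`, `strtlAavg = d_1 − avgSL`, `strtlF = d_1/l_m`;
- `AUC_r = AUC(dark)/AUC(light)`, trapezoidal over bin index.

Two denominators can vanish on inactive larvae (`strtlF`, `AUC_r`); both are
floored at ε = 0.02 cm, the same tracking noise floor, so an all-zero profile
maps to all-zero endpoints rather than NaN. These conventions (slope unit,
trapezoid AUC, ε-floor) were genuinely open choices; they are fixed here and
covered by an independent-transcription oracle test at 1e-12.

## Vehicle-referenced Box–Cox standardization

Activity endpoints are strongly right-skewed. Each endpoint is transformed
with a two-parameter Box–Cox: a data-driven shift
`max(0, 1e-6 − min(controls))` guarantees positive support (startle
differences and habituation slopes can be ≤ 0), then λ maximizes the profile
log-likelihood over the grid [−3, 3] step 0.01, ties broken toward λ = 1.
The profile log-likelihood is evaluated vectorized over the grid and is
asserted against `scipy.stats.boxcox_llf` in the tests. Transformed controls
are centered at their mean and — a declared extension beyond plain
centering — scaled by their SD, so every endpoint's null distribution is
(approximately) zero-mean unit-variance and a *single* cutoff definition
applies across endpoints. The reference is fit once on a vehicle-control
pool (the assay tradition uses a large historical pool, ~640 larvae; the
pipeline accepts either a pooled pre-fit reference JSON or the study's own
pooled controls, minimum 20) and then frozen. Treated values below the
shifted support are floored at 1e-6 and flagged.

The response **cutoff** separating assay noise from signal defaults to 1.0
control SD (configurable). λ is only well identified when the data's
coefficient of variation is appreciable; the recovery tests generate data
accordingly.

## Concentration–response suite, hitcall, BMC

Responses are signed displacements in control-SD units; activity is judged
on |response|, so bidirectional effects are handled. Concentration is
handled on the log10 scale with vehicle mapped to a pseudo-concentration
half a log-step (10^0.25) below the lowest tested level. The suite contains
ten shapes — constant, linear and quadratic in log10(conc) anchored at the
vehicle pseudo-concentration, power, Hill, gain–loss (Hill gain × Hill
loss), and four exponential forms — fit by maximum likelihood with
Student-t(4) residuals (scale estimated), a robust likelihood that
down-weights occasional wild larvae in lieu of outlier removal. Fits use
L-BFGS-B from several data-driven starts inside explicit parameter boxes; a
model that fails to converge is excluded and logged, never fatal.

The continuous hitcall is the product of three weights, each in [0, 1]:

- **w1** = 1 − Akaike weight of the constant model among all converged fits
  (AIC = 2k − 2·loglik, k counting the residual scale);
- **w2** = probability that at least one concentration group's true median
  response exceeds the cutoff: each observed group median is treated as
  normal about the truth with SE = σ̂/(2·f(0)·√n) where f(0) = 0.375/σ̂ is the
  central t(4) density, and groups combine as 1 − Π(1 − p_g);
- **w3** = probability that the winning (lowest-AIC non-constant) model's
  |top| — the maximal |predicted response| over the tested range — exceeds
  the cutoff, using a delta-method SE from the numeric Hessian (fallback: a
  group-mean-scale SE when the Hessian is degenerate).

The three-factor structure is the assay community's convention; the precise
operationalizations of w2 and w3 above are this package's declared choices.
An endpoint is **active** at hitcall ≥ 0.9 (threshold configurable, the
boundary inclusive).

For active endpoints the **BMC** is the smallest tested-range concentration
where |fitted response| = BMR, located by a log-grid scan for the first
crossing followed by bisection (robust to the non-monotone suite members).
BMR defaults to 1.349 control SDs — the conventional continuous
benchmark-response multiplier (the two-sided 10% tail shift of a standard
normal) — and is configurable. BMDL/BMDU are the 5th/95th percentiles of
the BMC over seeded within-group nonparametric bootstrap refits of the
winning model (default 1,000 resamples; tests and the acceptance script use
fewer, see below). A curve that never reaches the BMR in range reports an
absent BMC with an explicit reason. No multiplicity correction is applied
across the 13 endpoints — the screen is deliberately the liberal arm of the
two analyses.

## Traditional analysis

The split-plot ANOVA treats phase (light/dark, within-subject, two levels —
so no sphericity correction is needed or offered) and concentration
(between-subject): concentration is tested against subjects-within-groups,
phase and the interaction against the phase × subject residual. The
implementation is the explicit textbook sums-of-squares decomposition and is
cross-checked in the tests against an independent mixed-ANOVA implementation
(pingouin) to 1e-6 on random balanced designs. Fisher's LSD is gated on the
omnibus concentration or interaction effect (p ≤ 0.05) and compares each
treatment with vehicle on each larva's *total average activity* (mean of its
two phase means), using the pooled subjects-within-groups error (variance of
a subject mean = MS_error/2) with the ANOVA's error df — i.e. unadjusted
pooled-variance t tests, which the tests verify definitionally to 1e-12.

## Developmental-toxicity layer

Observer calls per well (alive, hatched, malformation set, severity) map to
one status with precedence **dead > not-hatched > severely-abnormal >
abnormal > normal**: morphology cannot be fully scored inside the chorion,
and stacked-bar reporting needs exclusive categories. Severity is the
observer's call, not re-derived from malformation counts. Plate QC fails
when *strictly more* than 15% of vehicle controls are non-normal (any status
other than normal — unhatched and dead controls count). Behavior inclusion
requires alive ∧ hatched ∧ no malformations (swim-bladder non-inflation is a
malformation), which provably implies status "normal".

Dosing arithmetic: a semi-log series is `top × 10^(−0.5k)`; the exposure
plate is a 250× dilution of the stock plate (25 mM top stock → 100 µM top
well). Display labels round to one significant figure, the pharmacology
half-log convention ({1, 3} × 10^k), which renders the canonical
100…0.03 µM series; exact values are kept internally and the adjacent-point
ratio is exactly 10^0.5. Rinse-out residual is `100 × retained^rinses`
(five 50% rinses → 3.125%, "approximately 3%").

## Synthetic plate generator

The generator emulates the screen's design: 96-well plates, 5 semi-log
concentrations × 16 larvae + 16 vehicle wells in a seeded random layout,
2-min bins over the 20/40/40-min protocol. Per-bin distances are Gamma
distributed (shape 4, so CV = 0.5 and right skew — the transforms have real
work to do) around deterministic phase means, scaled by a per-larva
lognormal frailty (σ_log = 0.3, mean 1) that induces realistic within-larva
correlation. Vehicle phase means: light 3.0 cm/bin with a −0.02 cm/bin
drift, dark plateau 5.0 cm/bin plus a 7.0 cm/bin startle envelope decaying
at 0.25/bin — i.e. a ~12 cm first dark bin relaxing toward ~5, dark > light
on average, the canonical profile shape. These magnitudes were chosen once
as representative of control larvae in this assay family and are not tuned.

Chemical effects act multiplicatively on four interpretable drivers via Hill
functions of concentration — light level, dark level (plateau *and* startle
envelope together, so a 60% Emax at the AC50 cuts the dark-phase mean by
30%), startle amplitude alone, and habituation rate — so correlated
multi-endpoint responses emerge naturally rather than being injected
per-endpoint. Developmental-toxicity observations come from per-status
logistic dose–response curves (vehicle baselines: 1% dead, 1% unhatched, 2%
mildly abnormal, so QC failures are rare but possible). `true_bmc` computes
ground truth by noiseless forward evaluation: the endpoint's deterministic
concentration curve is pushed through the frozen vehicle transform and the
standardized shift from vehicle is bisected against the BMR to 1e-6.

What the generator does *not* emulate: per-frame kinematics, well-edge and
plate-position effects, time-of-day drift, inter-observer disagreement, and
chemical-specific effect shapes beyond Hill-on-drivers. Passing recovery
tests therefore demonstrates the pipeline's correctness and calibration
under a faithful statistical caricature of the assay, not performance on any
specific laboratory's data.

## Problem sizes and numerical choices

Simulation-based checks are sized to run comfortably on one CPU as part of a
default test run: the test suite uses 8–16 seeded plates per property
(recovery, null rate, detection), while `scripts/acceptance.py` re-runs them
larger (100 recovery plates, 40 null plates, 10 two-plate detection
replicates, 500 ANOVA null simulations). Bootstrap CIs default to 1,000
resamples in the API; tests use 20–200. Tolerances follow the property being
checked: exact arithmetic at 1e-9–1e-12, λ recovery ±0.15 at n = 641,
analytic Hill BMC inversion 1%, simulated BMC recovery ±0.3 log10 (median),
null per-endpoint active rate ≤ 10%, ANOVA type-I in [0.03, 0.07] at
α = 0.05.

Known limitations: the optimizer can rarely settle in a local optimum for
the 5-parameter gain–loss model (it is then simply out-weighed by AIC); the
w2/w3 probability approximations are asymptotic normal; the split-plot
decomposition assumes near-balanced groups (empty cells are an error);
display rounding of dose labels is cosmetic and never feeds computation.
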