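# Methods

This note documents the models implemented in `enzymix`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Initial-rate extraction

A kinetic trace is a short absorbance time series (three or more reads; the
default simulated design reads every minute for 3 min). The initial rate is
the OLS slope of absorbance against time over the full trace (a
configurable window is available). OLS is preferred to a two-point
difference because it uses every read and has a closed-form standard error;
on an exactly linear trace it returns the slope to machine precision, and a
flat trace returns exactly zero. Traces whose fit r² falls below a
threshold (default 0.90) are flagged `qc_pass=False` but never dropped —
quality filtering is left to the caller. LOX activity conversion is exact
by definition: one unit per 0.001 ΔAU/min at 234 nm; the conversion refuses
traces recorded at any other wavelength.

## Kinetics and mechanism classification

Michaelis–Menten parameters are estimated by Levenberg–Marquardt nonlinear
least squares on untransformed rates, with parameters log-transformed to
enforce positivity. Initialisation: Vmax₀ = maximum observed rate, Km₀ =
substrate concentration nearest half-max; up to five jittered restarts on
failure. The double-reciprocal (Lineweaver–Burk) line is computed for
display and diagnostics only, since reciprocal transformation inflates the
influence of low-rate points.

Mechanism classification fits six global candidate models to the complete
substrate × dose grid (shared control Km, Vmax plus a mechanism-specific
dose law): no effect, competitive, uncompetitive, noncompetitive, mixed,
and hyperbolic activation. Mixed inhibition is included even where a study
expects a pure mechanism, so the classifier is falsifiable. Selection is by
small-sample corrected AIC (AICc, with the residual variance counted as a
parameter); candidates within 2 AICc units of the best are treated as tied
and the tie goes to the model with fewer parameters.

Two guards precede selection:

* **Identifiability screen.** A candidate is admissible only if each of its
  effector components changes predicted rates at the largest tested dose by
  more than twice the residual coefficient of variation of the best fit.
  Without this, the four-parameter mixed model occasionally wins AICc on
  data from a pure mechanism by absorbing noise into a second inhibition
  constant whose maximal effect over the tested dose range is smaller than
  single-measurement noise — a mechanism claim the data cannot support. The
  threshold is expressed in units of the fit's own noise level, so the
  screen vanishes on noise-free data and is invariant to rate rescaling.
* **Activation direction check.** The activation label additionally
  requires fitted rates above the control at every nonzero dose, matching
  the visual criterion that the control double-reciprocal line lies above
  the effector lines.

On noise-free data the true mechanism is recovered exactly (Ki to 1e-6
relative), and the uncompetitive conservation law — apparent Km and Vmax
rescaled by the same 1/(1 + I/Ki) — holds on the fitted model by
construction. RSS values are floored at 1e-18 × total sum of squares so
AICc stays finite on exact fits without breaking scale invariance.

## Dose–response

Effect fractions: inhibition and scavenging use `fa = 1 − v/v₀` (for ABTS
endpoint reads, v is the endpoint absorbance and v₀ the blank); activation
uses `activation% = 100·(v/v₀ − 1)`. Activation percent can exceed 100
(plateau Vmax more than double the control), so the fraction used in
median-effect work is activation% normalised by the fitted plateau of the
hyperbolic curve `100·Emax·A/(Ka + A)`, which keeps fa in (0, 1). Both
conventions are reported: the AC50 is defined operationally as the dose at
which the *un-normalised* fitted curve predicts 50% activation, i.e.
`AC50 = Ka/(2·Emax − 1)`, which exists only when the plateau exceeds 50%;
the normalised fraction feeds Dx and combination work.

The median-effect law `fa/(1−fa) = (D/Dm)^m` is fitted by OLS on
`log₁₀(fa/(1−fa))` versus `log₁₀ D` on per-replicate points (not dose
means). Base-10 logarithms are used throughout. fa values at exactly 0 or 1
are excluded with a warning; the remainder are clipped to [0.01, 0.99]
before the transform (clipping is a no-op when all points are already
interior). At least three usable doses are required. A non-positive fitted
slope marks the fit invalid rather than raising, so callers can distinguish
"no dose dependence" from bad input. The covariance of (log₁₀ Dm, m) is
propagated from the OLS covariance by the delta method.

EC50s: IC50 coincides with Dm under the fa definition; AC50 as above.
Uncertainty is a nonparametric bootstrap (default B = 1000, seeded):
replicates are resampled with replacement within each dose and the full fit
is repeated. Because resampling n points of a group underestimates the
group variance by (n−1)/n, the reported SD is rescaled by
√(n̄/(n̄−1)) with n̄ the mean replicates per dose; with triplicates this
correction is ≈ 1.22 and brings the bootstrap SD within ~15% of the
across-simulation SD of the estimator in Monte-Carlo checks.

## Fixed-ratio combination analysis

Mixtures are prepared at fixed volume ratios. Ratios are converted to
component dose fractions assuming equal molar stock concentrations by
default (3:2 → d1 = 0.6 of the total dose); because studies rarely state
whether stocks are equimolar, per-component stock concentrations are a
config option and change the split to `f1 = p·c1/(p·c1 + q·c2)`.

The mixture's dose–effect curve is fitted on *total* dose with the same
median-effect model (standard fixed-ratio practice). At effect level x
(default 0.5, configurable), the fitted mixture curve gives the total dose
achieving x, the ratio convention splits it into (d1, d2), and

CI = d1/Dx1 + d2/Dx2,  DRI_i = Dx_i/d_i,

so CI = 1/DRI1 + 1/DRI2 holds as an identity of the emitted result (tested
to 1e-12). Isobologram coordinates are the normalised pair
(d1/Dx1, d2/Dx2); points below the unit anti-diagonal correspond exactly to
CI < 1. Verbal interaction classes use the refined bands
(<0.1 very strong synergism; 0.1–0.3 strong synergism; 0.3–0.7 synergism;
0.7–0.85 moderate; 0.85–0.90 slight; 0.90–1.10 nearly additive; 1.10–1.20
slight antagonism; 1.20–1.45 moderate; 1.45–3.3 antagonism; 3.3–10 strong;
>10 very strong antagonism). Since a study typically reports one CI per
pair, the report includes per-ratio CIs plus their mean. CI uncertainty is
the same within-dose bootstrap (all three curves refitted per resample)
with the small-group rescaling above.

## Synthetic-data generator

The generator is the package's ground-truth instrument:

* **Kinetic grids.** Default design: 8 log-spaced substrate concentrations
  spanning 0.2–20 × Km, triplicate wells, a dose-0 control block always
  present. Rates are exact model values times (1 + ε), ε ~ N(0, noise_cv)
  truncated at −0.99 — multiplicative noise matches the roughly
  proportional error of plate readers and keeps rates positive.
* **Plate traces.** Exactly linear absorbance ramps of a given slope with
  optional additive Gaussian read noise.
* **Mixtures.** Single agents are placed at the equipotent doses of a
  target effect grid (default 0.1–0.9 in steps of 0.1). For each ratio and
  effect x the total mixture dose solves d1/Dx1(x) + d2/Dx2(x) = ψ, where ψ
  is the built-in Loewe interaction index; the construction is verified
  pointwise to 1e-9 in tests. A noise-free pipeline therefore recovers
  CI = ψ at every ratio and effect level. Noise enters through the residual
  activity 1 − fa, mirroring how effects are measured from rates.
* Everything is driven by `numpy.random.default_rng(seed)`; identical
  truths and seeds give bit-identical data.

What the generator does **not** emulate: enzyme inactivation over time,
substrate depletion (trace curvature), inner-filter and path-length optical
effects, plate edge/position effects, or correlated (batch) noise. Passing
recovery tests therefore demonstrates the correctness of the estimators
under the stated error model, not robustness to every artefact of real
plates.

Two structural caveats. First, when the two agents have unequal
sigmoidicities (m1 ≠ m2), the fixed-ratio mixture constructed from a
constant ψ is not exactly a median-effect curve, so the fitted-mixture
route recovers CI = ψ only approximately; exact-recovery checks use equal
m. Second, with very high noise the logit transform near fa = 0 or 1
saturates at the clipping bounds and biases m downward; the default effect
grid keeps points well interior.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| substrate grid | 8 points, 0.2–20 × Km | mM | brackets Km symmetrically in log space |
| replicates | 3 | — | typical plate design |
| trace design | 4 reads over 3 min | min | short linear window |
| fa clipping | [0.01, 0.99] | — | standard median-effect practice |
| effect level x | 0.5 | — | AC50/IC50-centric reporting |
| bootstrap B | 1000 | — | SD stable to a few % |
| QC r² threshold | 0.90 | — | flags curved/noisy traces, drops nothing |
| interaction ratios | 1:4, 4:1, 3:2, 2:3, 1:1 | v/v | standard fixed-ratio design |

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at
desk scale: classifier validation uses 500 simulated series per mechanism
(8 × 4 × 3 = 96 rates each), interaction-index recovery uses 200 seeds per
ψ, and bootstrap calibration uses 200 simulations against B = 300–1000
resamples. These sizes give Monte-Carlo error comfortably below the
tolerances they are checked against.

## Known limitations

* Progress-curve (integrated rate law) analysis is out of scope; rates are
  assumed to come from the linear regime.
* The median-effect and hyperbolic-plateau models are the only
  dose–response families; no 4PL/5PL logistic alternatives.
* Two-agent combinations only; no Bliss/ZIP/HSA scores or response-surface
  models.
* The mixed-mechanism model reports one Ki per binding mode but no
  cooperativity; partial (hyperbolic) inhibition is not modelled.
* Bootstrap SDs assume exchangeable replicates within dose; day/batch
  effects would require a hierarchical resampling scheme.
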