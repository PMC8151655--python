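# enzymix

Analysis pipeline for plate-reader studies of small-molecule enzyme
effectors and their mixtures: initial-rate extraction from absorbance
traces, Michaelis–Menten kinetics with mechanism classification, median-
effect dose–response modelling (AC50/IC50), and fixed-ratio isobolographic
combination-index analysis with synergy/antagonism calls.

It is written for the kind of study in which dietary phenolic acids are
screened as enzyme effectors — e.g. thyroid peroxidase (TPO) activation
followed by guaiacol oxidation at 470 nm, lipoxygenase (LOX) inhibition
followed by linoleate conjugated-diene formation at 234 nm, and ABTS
radical-scavenging endpoint reads — and in which two-agent mixtures at
fixed volume ratios (1:4, 4:1, 3:2, 2:3, 1:1) are assessed for interaction.
Because raw measurements for such studies are rarely deposited, the package
ships a synthetic-data generator with known ground truth, so every stage is
verifiable by parameter recovery.

## The models

**Initial rates.** Absorbance traces `A(t)` are reduced to rates
`v = dA/dt` (ΔAU/min) by ordinary least squares over the recorded window.
One LOX unit is an increase of 0.001 AU/min at 234 nm, so
`units = v / 0.001`.

**Mechanism classification.** Rates on a substrate × effector-dose grid are
fitted globally by nonlinear least squares under six candidate
rapid-equilibrium laws for `v = Vmax·S/(Km + S)` with dose-dependent
apparent parameters:

| mechanism      | apparent Km           | apparent Vmax          |
|----------------|-----------------------|------------------------|
| none           | Km                    | Vmax                   |
| competitive    | Km·(1 + I/Ki)         | Vmax                   |
| uncompetitive  | Km/(1 + I/Ki)         | Vmax/(1 + I/Ki)        |
| noncompetitive | Km                    | Vmax/(1 + I/Ki)        |
| mixed          | Km·(1+I/Kic)/(1+I/Kiu)| Vmax/(1 + I/Kiu)       |
| activation     | Km                    | Vmax·(1 + Emax·A/(Ka+A)) |

Candidates are screened for parameter identifiability and compared by
AICc, ties going to the simpler model. Lineweaver–Burk (1/v vs 1/S)
coordinates are produced for display; parameters are never estimated from
the double-reciprocal line.

**Median-effect dose–response.** Effect fractions
(`fa = 1 − v/v₀` for inhibition and scavenging; plateau-normalised
activation otherwise) follow `fa/(1−fa) = (D/Dm)^m`, fitted by OLS on
`log₁₀(fa/(1−fa))` vs `log₁₀ D`. The equipotent dose at effect `x` is
`Dx = Dm·(x/(1−x))^(1/m)`; IC50 ≡ Dm, while AC50 is the dose at which the
fitted hyperbolic activation curve `100·Emax·A/(Ka+A)` reaches 50%
activation.

**Combination index.** A fixed-ratio mixture fitted on total dose gives,
at effect level `x`, component doses `(d1, d2)`; with single-agent
equipotent doses `Dx1, Dx2`:

```
CI = d1/Dx1 + d2/Dx2 = 1/DRI1 + 1/DRI2
```

CI < 1 is synergy, CI = 1 Loewe additivity, CI > 1 antagonism; refined
verbal bands (e.g. CI < 0.3 "strong synergism", CI in [0.9, 1.1] "nearly
additive") and dose-normalised isobologram coordinates `(d1/Dx1, d2/Dx2)`
are reported, with bootstrap SDs over within-dose replicate resamples.

## Worked example

```python
import enzymix as ez
from enzymix import fit_median_effect, combination_index

# LOX-style uncompetitive inhibitor: Km 0.007 mM, Vmax 1111 dAU/min, Ki 0.009 mM
truth = ez.KineticTruth(km=0.007, vmax=1111.0, mechanism="uncompetitive",
                        k_effector=0.009, noise_cv=0.05, seed=42)
series = ez.generate_kinetic_series(truth, effector_doses=[0.0045, 0.009, 0.018])
call = ez.classify_mechanism(series)
print(f"mechanism: {call.label}")
print(f"Km = {call.km:.4f} mM, Vmax = {call.vmax:.1f} dAU/min, Ki = {call.ki:.4f} mM")

mix_truth = ez.MixtureTruth(dm1=0.10, dm2=0.69, m1=1.0, m2=1.0, psi=0.24,
                            ratios=((1, 1),), noise_cv=0.05, seed=7)
s1, s2, (mix,) = ez.generate_mixture_series(mix_truth)
res = combination_index(fit_median_effect(s1), fit_median_effect(s2), mix, x=0.5)
print(f"CI at 50% effect = {res.ci:.3f} ({res.label})")
print(f"DRI1 = {res.dri1:.2f}, DRI2 = {res.dri2:.2f}")
```

prints

```
mechanism: uncompetitive
Km = 0.0068 mM, Vmax = 1107.1 dAU/min, Ki = 0.0089 mM
CI at 50% effect = 0.254 (strong synergism)
DRI1 = 4.51, DRI2 = 31.36
```

At 5% multiplicative rate noise the classifier recovers the uncompetitive
label and Ki ≈ 0.009 mM, and the combination analysis recovers the built-in
interaction index ψ = 0.24 ("strong synergism"): the mixture reaches 50%
effect with agent 1 at 1/4.5 and agent 2 at 1/31 of their single-agent
equipotent doses.

The same analyses are available from the shell via the `enzymix` console
script (`simulate`, `rates`, `kinetics`, `dose`, `ci`, `report`); see
`enzymix --help`.

## Layout

- `enzymix.datagen` — ground-truth generators (kinetic grids, fixed-ratio
  mixtures with controllable interaction index, linear plate traces)
- `enzymix.plate_io` — trace/rate CSV I/O, initial rates, LOX units
- `enzymix.kinetics` — Michaelis–Menten fits, Lineweaver–Burk, mechanism calls
- `enzymix.dose_response` — effect fractions, median-effect model, EC50s
- `enzymix.combination` — CI, DRI, isobolograms, interaction bands, bootstrap
- `enzymix.cli` — console entry points and the `report` pipeline

See `docs/methods.md` for the statistical details and design choices.
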