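# Methods

This note documents the models implemented in `bodycomp`, the defaults and
why they were chosen, what the synthetic cohort does and does not emulate,
and the numerical decisions that were genuinely open.

## Cole model and fitting

Tissue impedance over the beta dispersion is modelled as
Z(ω) = R∞ + (R0 − R∞)/(1 + (jωτ)^α), with R0 and R∞ the zero- and
infinite-frequency resistances (Ω), τ the characteristic time constant (s;
fc = 1/2πτ), and α ∈ (0, 1] the dispersion breadth. Spectra store reactance
as a positive magnitude Xc; the model's imaginary part is −Xc.

`fit_cole` minimises the summed squared complex residual (real and
imaginary misfits stacked, unweighted — whether instrument software weights
by frequency is generally undocumented, so the simplest convention is the
default) over a configurable window, 3–500 kHz by default: the low end
avoids electrode polarisation, the high end the capacitive-leakage
artifacts common above a few hundred kHz. Initialisation is deterministic,
from an algebraic (Kasa) circle fit to the (R, Xc) locus — intersections
with the real axis seed R0 and R∞, the centre depth seeds α, the
reactance-peak frequency seeds τ — so the fit is a pure function of the
data and the returned objective never exceeds the initialiser's. Parameters
are bounded (R0 > R∞ > 0 via a positive-ΔR parametrisation, α ≤ 1, τ in
log-space). A spectrum whose |Xc| never exceeds 0.01 Ω carries no usable
dispersion and is rejected rather than fitted. Duplicate instrument
readings are fitted separately and the fitted parameters averaged,
mirroring the averaging of repeated anthropometry. No cable time-delay
(Td) correction term is included.

## Mixture theory

Extracellular water follows the Hanai dilute-suspension result,

    V_ECW = k_ecw · (H² √W / R0)^(2/3),
    k_ecw = 10⁻³ (k_B² ρ_ECW² / D_b)^(1/3),

with ρ_ECW the apparent extracellular resistivity (Ω·cm), D_b body density
(kg/L, default 1.05) and k_B the dimensionless body proportion factor. The
BMI-adjusted variant replaces the constant with k_ecw = a/BMI + b
(a = 0.188, b = 0.2883 for ECW). Intracellular water solves

    (1 + v)^(5/2) = ((R_E + R_I)/R_I) (1 + k_ρ v),   v = V_ICW/V_ECW,

with R_E = R0, R_I = R0·R∞/(R0 − R∞) and k_ρ = ρ_ICW/ρ_ECW, by Brent
bracketing on v ∈ [0, 10] verified to |f| < 10⁻⁹.

**The k_ρ < 5/2 constraint.** The implicit relation behaves physically
(V_ICW → 0 as R∞ → R0; V_ICW monotone in R∞) only when k_ρ ≤ 5/2: for
larger ratios the root tends to the strictly positive limit v* solving
(1+v)^{5/2} = 1 + k_ρ v as R_I → ∞, i.e. a vanishing intracellular
conduction path would still be assigned nonzero intracellular water. Some
published adult resistivity pairs imply k_ρ ≈ 3–4 and sit in that regime.
The shipped coefficient registry therefore keeps ρ_ICW/ρ_ECW below 5/2
(ward 650/273.9, moon 560/235.5); the registry is user-editable and every
entry carries a citation note. Because child resistivities have not been
established empirically, the defaults are adult-style values paired with a
k_B correction: `kb_from_anthropometry` models the wrist-to-ankle path as
cylinders in series, K_B = Σ(λᵢ/γᵢ²)·Σ(λᵢγᵢ²) over segments with relative
lengths λᵢ and circumferences γᵢ (scale-invariant), returning the published
adult 4.3 when no child proportions are configured.

A consequence of pairing adult resistivities with child geometry is that
the synthetic spectra sit lower in ohms (R0 ≈ 150–250 Ω) than typical
pediatric wrist-to-ankle measurements; all internal relationships are
self-consistent, which is what the recovery tests exercise.

## Dilution reference

The plateau method gives the deuterium dilution space
V_D = dose·purity·10³/(plateau − baseline), with enrichments in ppm by
mass and dose in grams (purity default 0.999). Deuterium exchanges with
non-aqueous hydrogen, so TBW = V_D/1.04. Water litres and kilograms are
treated 1:1 (a density override is available). FFM = TBW/HF with hydration
fractions looked up by sex and integer age band; the default table spans
ages 6–10 with values declining from ~0.77 toward the adult 0.732, girls
slightly above boys, consistent with reference-child values; an
alternative table in the style of the older literature constants sits
behind `HydrationTable.lohman()`. FM = weight − FFM is flagged as an error
(never clipped) if an equation predicts FFM above body weight.

## Synthetic cohort

The generator emulates the study design: n = 158 (75 boys), ages uniform
on 6.5–9.6 y, sex-specific %BF as truncated Gaussians (means 38.7/35.1,
SD 8.5, clipped to 14.2–57.5 — the SD places the printed range at about
±2.5σ so truncation shifts the means by < 0.3 %BF). Height is age- and
sex-linear with Gaussian scatter (127 cm at age 8, 5.8 cm/y, SD 5.5); FFM
comes from a fat-free mass index ~N(13, 1.2²) kg/m², and weight =
FFM/(1 − %BF/100), which makes FM + FFM = weight exact and lets BMI span
normal to obese through adiposity alone. TBW = FFM·HF(age, sex) exactly.

Skinfolds invert the planted log-linear model
SSF = 10^((%BF − b0 − b2·sex − e)/b1) with (b0, b1, b2) = (−40, 50, −1.5)
and e ~ N(0, 3.5²) %BF. The truth %BF is constructed as latent + e with
the *same* e, so the planted model holds exactly with a regression error
independent of log₁₀SSF — the construction that makes unbiased coefficient
recovery possible. The four sites partition SSF as 0.35/0.15/0.30/0.20
(only the sum is ever analysed). Impedance spectra are exact forward
images of the mixture equations — R0 from the ECW power law, R∞ from the
closed-form inverse of the intracellular relation — at a per-subject
ECW/TBW fraction ~N(0.45, 0.013²), α ~ U(0.65, 0.78) and fc ~ U(25, 60)
kHz, plus N(0, 0.5² Ω) instrument noise per frequency. Dilution assays
invert the reference chain from truth TBW (dose 0.5 g/kg) with
multiplicative lognormal enrichment noise, CV 0.02.

The noise levels were set by an error budget targeting a cross-validated
FFM difference SD near 0.8 kg (dilution ~0.3 kg plus mixture-vs-linear
scatter ~0.5 kg), the regime in which the impedance equation shows
sub-1 % bias with limits of agreement around ±1.6 kg. All randomness flows
from one seed through per-subject substreams, so cohorts are reproducible
and prefixes are stable under resizing.

What the generator does **not** emulate: growth or pubertal change,
measurement-protocol artifacts (electrode placement, caliper technique),
segmental body-shape variation beyond the single ECW-fraction scatter,
non-Gaussian anthropometry, or any particular real population's covariance
structure. Passing tests therefore demonstrate correctness and calibration
of the *procedures*, not field accuracy of any coefficient set.

Because the impedance forward model is mixture-theoretic, the linear
single-frequency TBW model has no planted coefficients; the generator's
implied coefficients are defined as the large-n least-squares projection
of reference TBW on (RI, weight, sex) (`implied_bia_coefficients`,
n = 10000–20000) and recovery at n = 158 is judged against those.

## Equation development and validation

Diagnostics are computed from first principles so they can be audited:
PRESS by the hat-matrix identity Σ(eᵢ/(1−hᵢᵢ))², VIF from auxiliary R²,
Mallows' Cp against a supplied full-model σ² (p+1 against the model's
own), AIC in the Gaussian-likelihood form including constants (comparable
only across models of one response). Stepwise selection uses forward entry
at α = 0.05 and backward removal at α = 0.10 (logged per run as a
selection trace). The 50:50 split is stratified by sex; an odd stratum
sends its extra member to either group by one seeded coin flip.

The homogeneity check between the two split-sample equations is an ANCOVA:
the two development regressions are pooled with a group indicator and its
interactions with every predictor, and the extra terms are F-tested
jointly. (Comparing the two *reference-vs-predicted* lines instead is
badly anti-conservative — the crossed slopes are reciprocal functions of
the same coefficient estimates — with a measured type-I rate near 40 %;
the ANCOVA form is exact at level α, measured 5.5 % over 600 null
replicates.) When the test is not significant the pooled equation is
fitted and reported with the leave-one-out RMSE √(PRESS/n) and the
PRESS-based R²_pred — for linear models these are the exact LOO
quantities, so both of the two common conventions are available.

Normality screening uses the Kolmogorov–Smirnov test with fitted mean and
SD; the asymptotic p-value is conservative because the parameters are
estimated, and a Lilliefors-corrected variant is available by flag.
Outlier screening is Rosner's generalized ESD (default α = 0.05, up to
k = 5).

## Agreement battery and ranking

Differences are **reference − predicted** throughout. Limits of agreement
use exactly 1.96·SD. Proportional bias is the slope of differences on pair
means with its t-test p-value. Lin's concordance uses population (1/n)
moments. Passing–Bablok uses the original shifted-median-of-pairwise-
slopes estimator (slopes of −1 discarded, offset by the count below −1);
the reported residual SD uses vertical residuals y − (a + bx), the
convention flagged as ambiguous in parts of the literature. The TOST bound
is the smallest symmetric δ, as % of the grand mean, at which both
one-sided paired t-tests reject at α = 0.05, found by bisection to 0.01 %
(the closed form is |d̄| + t·SE; the bisection is kept as the documented
search semantics). The Gower index normalises the mean absolute difference
by the pooled range of both series. Equations are ranked by mean rank over
MAPE (ascending), TOST bound (ascending) and Gower (descending), ties
broken by MAPE then identifier.

## Known limitations

- Registry coefficient sets for published comparison equations that could
  not be transcribed from their original sources carry synthetic
  placeholder values (flagged `coefficients_verified: false`); they
  exercise the dispatch and comparison machinery and must be replaced
  before real-data use.
- The Weststrate–Deurenberg-style age/sex density transform and the
  hydration tables are parameterised approximations of the cited families
  of values, editable as data.
- Single wrist-to-ankle path only; no segmental or vector impedance
  analytics, no multi-point back-extrapolation dilution, no regularised or
  robust regression variants.
- The acceptance analyses run at the design point n = 158 (with 100-seed
  repetition for calibration rates and n = 10000 for implied-coefficient
  targets), sizes chosen to characterise the procedures precisely while
  keeping any run interactive.
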