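# Methods

## The model

`axilen` decomposes a measured axial length into two additive components
using the Morgan estimation formula. For an eye with anterior corneal
radius CR (mm, mean of flat and steep keratometry) and spherical
equivalent refractive error SER (D, corneal plane, post-mydriasis):

    AL_Morgan      = 1 / (a/CR + b·SER + c)        a = 0.22273
    AL_emmetropia  = 1 / (a/CR + c)                b = 0.00070 mm⁻¹·D⁻¹
    ΔAL            = AL − AL_emmetropia            c = 0.01368 mm⁻¹

`AL_emmetropia` is the axial length at which this cornea would be
emmetropic; `ΔAL` is the myopia-attributable axial increment. The three
constants are stored exactly as published and never re-fit. CR is in mm
throughout; keratometric diopters are converted explicitly via
`keratometry_to_radius` (k → 337.5/k with the standard index 1.3375),
never inferred from magnitude. SER is taken at the corneal plane with no
vertex-distance correction; no lens/aqueous/vitreous refraction or
accommodation is modelled.

Two exact algebraic identities follow and are enforced by property
tests: `AL_Morgan − AL_emm = −b·SER·AL_Morgan·AL_emm`, and the inverse
map `implied_ser(AL, CR) = (1/AL − a/CR − c)/b` round-trips to ≤ 1e−9.
The model-implied elongation per diopter, `b·AL_Morgan·AL_emm`, lies in
0.30–0.55 mm/D over the clinically observed range (CR 7.0–8.6 mm, SER
−9 to +2 D); outside that range — corneal radii no adult cornea
exhibits — the band does not hold, so the property is asserted on the
clinical range only.

## The statistical pipeline

Given a per-eye cohort table the pipeline computes, in order:

1. **Derived variables** per record from (CR, SER, AL).
2. **Agreement of AL with AL_Morgan**: Pearson r with its exact
   t statistic (`t = r√(n−2)/√(1−r²)`; the reported t always follows
   this identity rather than any externally rounded value) and
   Bland–Altman analysis with the difference defined as
   *measured − estimate*, bias = mean difference, limits of agreement
   bias ± 1.96·SD (sample SD, n−1). The direction convention is recorded
   in every output.
3. **Group means** of AL_emmetropia and ΔAL in four clinical groups:
   axial split at 26 mm (AL = 26 joins the long-eye group) and
   refractive split at −6.00 D (SER = −6.00 joins the high-myopia
   group). Empty groups are reported with n = 0, not raised.
4. **Simple regressions** of AL, AL_emmetropia and ΔAL on SSI.
5. **Adjusted models** 1–3: the same three outcomes on
   SSI + age + male gender (coded 1) + CCT, sharing one design matrix.
   Because AL = AL_emmetropia + ΔAL and least squares is linear in the
   outcome, Model 1 equals Model 2 + Model 3 termwise to machine
   precision — an exact structural invariant the tests assert at 1e−10.
6. **Subgroup model**: Model 3 refitted on AL ≥ 26 mm (inclusive).
7. **Diagnostics** on each adjusted fit, pass/fail at α = 0.05:
   D'Agostino–Pearson residual normality; Breusch–Pagan of squared
   residuals on fitted values; Ljung–Box at lag 1 (Durbin–Watson
   reported alongside); and an F-test on a fitted-value-squared
   augmentation of the design (RESET-type linearity check). The source
   study names no specific tests; these four are this package's
   choices and are labelled as such in output. Checks that cannot run
   (n too small, degenerate residuals) are reported as not-computed.

CIs are estimate ± t₀.₉₇₅(n−p)·SE; p-values are two-sided, displayed to
three decimals with a `<0.001` floor and starred at 0.05/0.01/0.001. No
multiple-testing correction is applied (none was used in the source
analysis). OLS fitting and the diagnostic statistics delegate to
statsmodels/scipy; the test suite cross-checks coefficients and SEs
against hand-rolled normal equations.

## The synthetic cohort generator

No individual-level data accompany the study the package reproduces, so
the generator is the test substrate. Its defaults encode the published
cohort (n = 267, right-eye summary statistics): age ~ truncated normal
(22, 8, bounds 6–60 y), P(male) = 0.46, CCT ~ N(544, 34) µm, SSI mean
0.82, SD 0.15. The structural equations are the published adjusted
models with coefficients printed as 0.00 fixed at zero:

    AL_emm = i₂ + 0.27·male + 0.48·SSI + ε₂
    ΔAL    = i₃ + 0.07·age + 0.23·male − 2.49·SSI + ε₃

The printed intercepts cannot reproduce the published means (the CCT
coefficient is rounded to 0.00), so intercepts are re-calibrated to the
target means (23.64, 2.38 mm) and residual SDs to the target SDs (0.50,
1.35 mm) after subtracting explained variance — a calibration error is
raised if a residual variance would go negative.

Confounding is the minimal structure reconciling the adjusted
coefficients with the published *marginal* slopes (0.561 for
AL_emm ~ SSI, −2.6 for ΔAL ~ SSI, and −2.04 for AL ~ SSI, which follows
automatically by additivity). Writing δ_x = cov(x, SSI)/var(SSI),
omitted-variable-bias algebra gives marginal = adjusted + Σ β_x·δ_x, so

    δ_male = (0.561 − 0.48)/0.27 = 0.30
    δ_age  = (−2.6 + 2.49 − 0.23·0.30)/0.07 ≈ −2.557   (corr ≈ −0.05)

solved analytically, never tuned. SSI is then generated linearly in age
and gender with a residual making its total SD 0.15. CR is obtained by
inverting the emmetropia formula (its mean 7.78 mm and SD 0.24 mm
emerge without being targeted), AL = AL_emm + ΔAL, and SER is the
Morgan-implied refraction plus independent N(0, 1.4 D) optometric
noise.

The 1.4 D default is a compromise: it puts corr(AL, AL_Morgan) near
0.91 and corr(SER, ΔAL) near −0.89 simultaneously, but no single noise
SD also reproduces the published Bland–Altman SD of 0.61 mm, and the
generator produces a near-zero agreement bias where the clinical data
showed −0.31 mm — the real error structure (device error, accommodation
residue, non-corneal optics) is richer than one additive term. Those
agreement point values are therefore checked as printed-value
arithmetic, not as generator recovery, and the correlation strengths are
asserted as bounds (≥ 0.85 in magnitude), not point targets.

Records violating the physiological guards (CR 5–12 mm, AL 15–40 mm,
SSI 0.2–2.5, CCT 300–800 µm) are redrawn, up to 100 rounds. One eye per
subject (OD) is generated by default — the source reports both eyes but
fits models at n = 267, leaving the pooling rule unstated — and an
optional paired mode duplicates each subject's structural draw with
small between-eye noise (0.10 mm on AL_emm, 0.20 mm on ΔAL; chosen to
be of the order of clinical inter-eye differences). Generation is
bit-reproducible for a fixed seed.

## What passing tests do and do not show

Parameter-recovery tests (n = 5,000, fixed seed, within 2 Monte-Carlo
SEs) demonstrate that the pipeline correctly estimates the quantities
the generator encodes — they validate the *software*, and the
calibration shows the published marginal and adjusted coefficients are
mutually consistent under a plausible confounding structure. They do not
re-establish the clinical findings: the published correlation and t
values, the subgroup coefficient −1.36, and the adjusted-model p-values
depend on the unreleased clinical data and are treated as qualitative
references only. (The published t values are in fact inconsistent with
the t/r identity at n = 267 — r = 0.91 implies t = 35.7, not 33.8 — so
the pipeline reports the identity-consistent t.)

## Numerical and design choices

* Exclusion screening (astigmatism ≥ 3 D — inclusive, contact-lens
  wear, corneal disease, prior surgery, failed quality flag) is
  re-expressed as data validation; missing flag columns warn and
  retain. Guard violations always exclude. The filter is idempotent.
* Degenerate inputs: zero-noise configs are legal (every record sits at
  the structural means); constant series raise a correlation error;
  perfect fits report diagnostics as not-computed rather than crashing.
* Derived columns are recomputed on model construction, so they are
  always consistent with the measured values (idempotent).
* `reproduce` writes a deterministic JSON/text bundle; every file
  embeds the config hash, seed and package version, and a stage failure
  removes partial outputs.
* Problem sizes: recovery checks use n = 5,000 (regression SEs ≈ 0.05
  for the 0.561 slope, ≈ 0.11 for the −2.49 coefficient); moment checks
  use n = 50,000 where a 0.05 mm tolerance needs SE ≲ 0.01.
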