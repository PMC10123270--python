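# axilen

Axial-length decomposition and corneal-stiffness regression analysis for
myopia cohorts.

Myopia usually reflects an eyeball that has grown too long for its own
optics. `axilen` separates a measured axial length (AL, mm) into the
part explained by the cornea's focal power and the part attributable to
myopic elongation, using the Morgan estimation formula

```
AL_Morgan     = 1 / (0.22273/CR + 0.00070·SER + 0.01368)
AL_emmetropia = 1 / (0.22273/CR + 0.01368)          # SER = 0
ΔAL           = AL − AL_emmetropia
```

where CR is the anterior corneal radius (mm) and SER the spherical
equivalent refractive error (D, corneal plane). It then quantifies how
AL and its two components relate to the corneal material stiffness
parameter SSI (stress-strain index, from dynamic corneal response
tonometry): Pearson correlation with exact t statistics, Bland–Altman
agreement of AL with AL_Morgan, simple regressions on SSI, the three
covariate-adjusted models (SSI + age + gender + CCT), and a long-eye
(AL ≥ 26 mm) subgroup model, with OLS-assumption diagnostics throughout.

Because the clinical cohort this analysis was developed on is not
publicly deposited, the package ships a calibrated synthetic-cohort
generator whose moments, structural coefficients and marginal
regression slopes match the published summary statistics — every stage
of the pipeline is testable without external data. See
[docs/methods.md](docs/methods.md) for the model, the calibration
algebra, and what the synthetic cohort does and does not emulate.

Intended users: ophthalmic-epidemiology and biostatistics researchers
working with per-eye biometry tables (age, gender, SER, SSI, CCT, CR,
AL).

## Worked example

```python
from axilen import GeneratorConfig, StiffnessElongationModel

cfg = GeneratorConfig(n=267, seed=20230410)          # one synthetic cohort
results = StiffnessElongationModel.from_config(cfg).fit()
print(results.summary())
```

Output (abridged):

```
Corneal stiffness & axial elongation analysis (n = 267 eyes)
================================================================

Agreement of measured AL with the Morgan estimate
  Pearson r = 0.90, t = 33.9, p = <0.001
  Bland-Altman (measured - estimate): bias -0.05 mm, SD 0.69 mm, 95% LoA [-1.41, 1.31] mm

Correlation of SER with the axial increment dAL
  Pearson r = -0.89, t = -31.1, p = <0.001

Simple regressions on SSI
  al_mm = 28.2 - 2.41 x SSI
  delta_al_mm = 4.73 - 2.69 x SSI
...
Model 3: delta_al_mm (n = 267, R^2 = 0.358)
  ssi              -2.437   0.472      [-3.37, -1.51]   <0.001 ***
```

Reading it: measured AL agrees closely with the Morgan estimate
(r = 0.90), more negative refractive error goes with a larger axial
increment (r = −0.89), and a one-unit drop in corneal stiffness is
associated with ~2.4 mm more myopia-attributable elongation after
adjusting for age, gender and corneal thickness — a softer cornea
accompanies a longer eye. The same analysis runs on real data via
`StiffnessElongationModel.from_csv("cohort.csv")` (columns
`subject_id, eye, age, gender, ser_d, ssi, cct_um, cr_mm, al_mm`).

A command-line interface wraps the library:

```
axilen generate --n 267 --seed 7 --out cohort.csv
axilen analyze cohort.csv --out report.json
axilen reproduce --seed 7 --out bundle/        # full deterministic report bundle
```

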