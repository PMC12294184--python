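# enamelmetrics

Radiographic morphometry of developmental enamel defects for amelogenesis
imperfecta (AI) cohorts.

AI is a family of inherited disorders of enamel quantity (hypoplasia) and
enamel quality (hypomineralization). Clinical inspection alone often cannot
separate the two, and erupted teeth accumulate environmental damage that
confounds any measurement. This package implements a quantitative
radiographic method that works on ordinary panoramic radiographs (OPTs) of
*unerupted* lower second permanent molar buds — crowns that are fully
formed but untouched by the oral environment — and links the resulting
phenotype to molecular findings. It is aimed at researchers in dental
genetics and at anyone building or validating morphometric pipelines on
radiographic data.

## The measurements

For each annotated tooth bud:

- **W, H** — crown width and height, straight-line distances between the
  annotated extremity points (pixels, optionally mm).
- **EA (enamel angle)** — an imaginary rectangle is placed on the bud,
  parallel to its longitudinal axis, with vertical sides through the mesial
  and distal cementum–enamel junctions (CEJ). EA is the acute angle between
  the outer enamel surface segment and the rectangle side (degrees).
- **DA (dentine angle)** — the same construction applied to the
  dentine–enamel junction (DEJ).
- **EDMR (enamel–dentine mineralization ratio)** — at half crown height a
  line of length twice the local enamel thickness is drawn from the dentine
  across the DEJ to the enamel surface; EDMR is the mean grey value of the
  middle third of the enamel half divided by that of the dentine half.
  Radiopacity increases with grey value, so healthy enamel gives EDMR > 1.

Per patient, values are pooled over the mesial and distal sides of both
lower second molars (mean ± sample SD). Patients are classified against
control-derived cut-offs (median with IQR over a healthy control group;
published values EA 14.63°, DA 7.22°, EDMR 1.06): `EDMR < cut` flags
hypomineralization, `EA < cut` / `DA < cut` flag hypoplasia, with strict
inequalities.

The statistics layer provides ICC reliability (ANOVA mean squares),
DBSCAN dispersion screening, PERMANOVA (Euclidean distances on z-scored
features, exact enumeration for small cohorts), exact mid-rank
Mann–Whitney tests with Benjamini–Hochberg correction, and a
bootstrap-validated random-forest / logistic-regression harness (repeated
class-balanced 70/30 splits scored by held-out ROC AUC) for predicting
disease-causing-variant (DCV) status from the radiographic parameters.
A variant-table module reproduces the cohort's diagnostic-yield arithmetic
from the packaged genotype table.

Because patient radiographs cannot be redistributed, the package ships a
phantom generator: stylized trapezoidal crowns with exactly known geometry
and grey levels, on which every operator is validated against ground truth.

## Worked example

```sh
python examples/01_phantom_and_measurement.py
```

```
image: 209 x 169 px, uint8
parameter      truth      measured (mesial/distal)
W (px)           160                        160.00
H (px)           120                        120.00
EA (deg)     15.0000             15.0000 / 15.0000
DA (deg)      7.0000               7.0000 / 7.0000
EDMR          1.1667               1.1667 / 1.1667
```

A noiseless phantom generated with EA 15°, DA 7° and grey levels 140/120
is measured back exactly: the angle operators recover the generating
angles on both sides, and the profile densitometry returns
EDMR = 140/120 = 1.1667.

```sh
python examples/04_genotype_prediction.py
```

```
random forest (500 trees): median AUC = 83.9% (IQR 76.8-87.5%) over 50 iterations
  importance ranking: EDMR > DA > EA  (EA=0.281, DA=0.315, EDMR=0.400)
logistic regression: median AUC = 83.0% (IQR 75.0-91.1%) over 50 iterations
  importance ranking: EDMR > DA > EA  (EA=0.826, DA=0.897, EDMR=1.834)
```

On a synthetic 24 + 24 cohort in which DA and EDMR (but not EA) are
shifted in the affected group, both models predict DCV status well above
chance and rank the shifted parameters above EA. The remaining examples
cover threshold derivation, the cohort statistics and the diagnostic-yield
arithmetic; a `simulate → measure → analyze → yield` command-line pipeline
(`enamelmetrics --help`) wraps the same functions.

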