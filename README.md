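# substature

Regression-based stature estimation for subadults (birth to ~20 years) from
long-bone measurements, for forensic anthropologists and bioarchaeologists
building a biological profile from skeletal remains.

Adult stature-estimation formulae do not transfer to growing skeletons: the
bone-length-to-stature relationship changes through ontogeny, steeply in
infancy and flattening through adolescence. This package implements the
pooled-sex approach of modelling stature *y* (cm) directly on a single
long-bone measurement *x* (mm) with one of three functional families:

| family | equation | used for |
|---|---|---|
| linear | *y = ax + b* | lengths and breadths |
| asymptotic exponential | *y = a − b·e^(−cx)* | lengths |
| three-parameter logistic | *y = a / (1 + b·e^(−cx))* | breadths |

and reporting every estimate with a **prediction interval** — the interval
expected to contain a *new* individual's stature with stated probability,
which is what a practitioner introducing a new case must use.

The package ships:

- an embedded, checksummed **registry of 38 published equations** (20 linear,
  18 nonlinear) covering 18 single-bone measurements of the humerus, radius,
  ulna, femur, tibia and fibula plus two composite limb lengths
  (humerus+radius, femur+tibia), together with their printed performance
  metrics (Kendall's τ, residual SD, two-sample KS *D*, hold-out test
  accuracy, MAD);
- the full **fit-and-validate pipeline** that produces such models from a
  reference cohort: closed-form OLS and trust-region nonlinear least squares
  with analytic Jacobians, exact-t and delta-method prediction intervals
  (residual bootstrap as a cross-check), an 80/20 train/hold-out split, and
  the validation battery (coverage accuracy, MAD, two-sample KS, Kendall τ-b,
  Bland–Altman limits of agreement, misclassification cross-tabulation);
- a **synthetic cohort generator** with the age structure, growth-curve shape
  and heteroscedastic noise the method assumes, so the whole pipeline is
  testable end to end without any data download.

## Worked example

```python
from substature import (MeasurementRecord, Bone, MeasurementType,
                        estimate_stature, load_registry)

rec = MeasurementRecord(
    id="case-01", sex="F", age_years=6.0,
    measurements={
        (Bone.HUMERUS, MeasurementType.LENGTH): 210.0,        # mm
        (Bone.RADIUS, MeasurementType.LENGTH): 155.0,
        (Bone.FEMUR, MeasurementType.MIDSHAFT_BREADTH): 19.0,
    },
)
for r in estimate_stature(rec, load_registry(), level=0.95):
    print(f"{r.label:45s} {r.point_cm:6.1f} cm  "
          f"95% PI [{r.pi_lower_cm:.1f}, {r.pi_upper_cm:.1f}]  {r.method}")
```

prints

```
upper_limb_length~asymptotic_exponential       125.8 cm  95% PI [117.1, 134.5]  approx_z
humerus_length~asymptotic_exponential          127.1 cm  95% PI [118.1, 136.1]  approx_z
radius_length~asymptotic_exponential           126.0 cm  95% PI [116.7, 135.4]  approx_z
upper_limb_length~linear                       120.4 cm  95% PI [109.6, 131.2]  approx_z
humerus_length~linear                          121.9 cm  95% PI [111.0, 132.8]  approx_z
radius_length~linear                           118.9 cm  95% PI [106.7, 131.2]  approx_z
femur_midshaft_breadth~linear                  126.7 cm  95% PI [107.3, 146.0]  approx_z
femur_midshaft_breadth~logistic3               131.4 cm  95% PI [114.4, 148.5]  approx_z
```

The upper-limb composite was derived automatically from the humerus and
radius lengths. One estimate is returned per available measurement × family,
sorted most-precise-first by each published model's MAD; nonlinear length
models lead because they track the infancy-steep growth relation best.
Registry intervals are the conservative normal approximation *ŷ ± z·s* from
the printed residual SD (`approx_z`) — the published tables do not carry the
training moments needed for an exact interval. Models you refit yourself
(`fit_all`, or the `fit` subcommand) return exact-t (linear) or delta-method
(nonlinear) intervals instead.

## Command line

```sh
substature simulate --n 1000 --seed 7 --out cohort.csv
substature fit --training cohort.csv --out models.json
substature evaluate --models models.json --test cohort.csv --out eval/
substature estimate --input cohort.csv --registry --out cases/
substature registry --list
```

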