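# croplab

Season-long crop-type mapping from dual-polarization SAR time series.

Optical vegetation indices fail exactly where cloud cover is persistent —
which is much of the growing season in monsoonal agricultural regions. C-band
SAR observes through clouds, and a dual-pol sensor (VV + VH) carries enough
polarimetric information to track canopy development: as a crop grows, the
backscattered wave becomes progressively depolarized by volume scattering.
`croplab` implements the full pipeline from calibrated complex scattering
data to per-field crop identification for three cover classes — **soybean**,
**oat**, and **fallow** (abandoned cropland) — together with a speckle
simulator that generates realistic synthetic seasons, so everything runs and
is tested without any satellite downloads.

## The index at the core

Per pixel and date, the complex scattering amplitudes (S_VV, S_VH) are
averaged over a moving window into the 2×2 Hermitian covariance

```
C2 = [[⟨|S_VV|²⟩,      ⟨S_VV·S_VH*⟩],
      [⟨S_VH·S_VV*⟩,   ⟨|S_VH|²⟩  ]]
```

with eigenvalues λ₁ ≥ λ₂ ≥ 0. Two descriptors follow:

* degree of polarization (Barakat): `m = sqrt(1 − 4·det(C2)/Tr(C2)²)`,
* dominant-scattering measure: `β = λ₁/(λ₁+λ₂)`,

and the **dual-pol radar vegetation index** is `DpRVI = 1 − m·β` ∈ [0, 1]:
near 0 over bare, polarized surfaces; rising toward 1 under the depolarized
volume scattering of a dense canopy. Its seasonal course is distinctively
different per class — soybean peaks (~0.59) in mid-September, oat peaks
(~0.66) in late July, fallow stays quasi-flat (~0.65) — and the 16-value
seasonal series is the feature vector for classification. The intensity-only
companions `RVI = 4σ_VH/(σ_VV+σ_VH)` and the `VV/VH` ratio are provided for
comparison studies.

The pipeline stages (one module each):

1. **polarimetry** — C2 formation, refined Lee adaptive speckle filtering,
   eigen-decomposition, DpRVI/RVI/VV-VH rasters;
2. **timeseries** — per-pixel seasonal series on the day-of-year grid,
   cubic-polynomial restoration of missing acquisitions, per-field 2σ
   anomaly screening, seasonal maxima;
3. **classify** — random forest (120 trees, Gini), linear SVM (C = 1,
   squared hinge, balanced weights), and QDA on the 16-value series, with
   stratified cross-validated grid search and confusion-matrix metrics
   (overall accuracy, per-class F1);
4. **fields** — per-field majority vote over pixel predictions and
   crop-identification accuracy tables;
5. **simulate** — synthetic dual-pol scenes: class phenology trajectories,
   fully developed complex-Gaussian speckle, labeled field polygons,
   anomalous pixels, missing dates.

## Worked example

Simulate a default season (80 fields: 10 fallow / 10 soybean / 20 oat in
each of the training and held-out partitions, 16 dates, 25-look speckle),
run the polarimetry chain, extract screened series, and classify:

```python
from croplab import (
    LabeledDataset, build_dataset, class_maxima_summary, evaluate, train_rf,
)
from croplab.simulate import KHABAROVSKIY_PROFILES, SimulationConfig, generate_scene

config = SimulationConfig(n_looks=25)
scene = generate_scene(config, KHABAROVSKIY_PROFILES, seed=0)
rasters = scene.index_rasters("dprvi", window=1)
dataset = build_dataset(rasters, scene.fields, grid=scene.date_grid())

print(class_maxima_summary(dataset).round(3))

train = LabeledDataset.from_series(dataset, "train")
test = LabeledDataset.from_series(dataset, "validation")
report = evaluate(train_rf(train, seed=0), test)
print(f"RF held-out OA: {report.oa:.1f}%")
print({c: round(f, 3) for c, f in report.f1.items()})
```

prints

```
  class_label  mean_max  std_max  mean_doy  std_doy  n_fields
0      fallow     0.624    0.008     219.4   50.403        20
1         oat     0.630    0.010     213.7    6.069        40
2     soybean     0.568    0.010     260.2    6.031        20
RF held-out OA: 98.9%
{'fallow': 0.986, 'soybean': 0.991, 'oat': 0.99}
```

The per-class rows are the mean ± spread of field-level seasonal maxima and
their dates: oat peaks around DOY 214, soybean around DOY 260, fallow has no
stable peak date (spread ±50 days). At 25 looks the estimator's small-sample
bias pulls the maxima slightly below their configured targets; at 225 looks
they are recovered to ±0.01. The held-out overall accuracy is the share of
correctly labeled pixel series in the 40 unseen fields.

The same pipeline runs from the shell on files:

```bash
croplab simulate scene/ --seed 0
croplab index scene/ dprvi/ --index dprvi --window 5
croplab series dprvi/ scene/fields.geojson series.csv --grid-json scene/grid.json
croplab classify train series.csv model.bin --method rf
croplab classify eval model.bin series.csv report.json --predictions-csv preds.csv
croplab fields preds.csv out/
```

Real data enters at the `index` step: any co-registered per-date stack of
calibrated complex VV/VH rasters plus a GeoJSON of labeled field polygons.

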