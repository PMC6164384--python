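# nmrqsar

A toolkit for QSAR modeling of natural-product samples from 1D NMR
spectra, plus the supporting model-building machinery for
molecular-descriptor regression workflows.

Two workflows are covered:

* **NMR classification** — convert ¹H/¹³C peak lists of crude extracts,
  fractions and pure compounds into fixed-width chemical-shift-bin
  descriptor vectors (e.g. 0.1-ppm proton bins over 0–12 ppm plus
  0.5-ppm carbon bins over 0–200 ppm, 520 descriptors total) and predict
  anticancer activity classes with a class-weight-balanced random forest
  validated out-of-bag.
* **Descriptor regression support** — Kohonen self-organizing-map (SOM)
  train/test partitioning and the SOM-response-pattern applicability
  domain (ASD), correlation-based feature selection (CFS) with
  best-first/greedy/exhaustive search, stepwise AIC descriptor
  elimination, importance-based top-N selection, an RF/k-NN/SVM harness
  (10-fold CV, OOB estimation, C tuning), and the full metric suite
  (sensitivity, specificity, Q, G-mean, squared-Pearson R², RMSE, MAE,
  the |error| ≥ 1 share, and the 3×MAE outlier rule).

## Layout

| module | purpose |
| --- | --- |
| `nmrqsar.binning` | binning schemes, joint ¹H-then-¹³C descriptor index, peak-list vectorization, descriptor matrices |
| `nmrqsar.activity` | IC₅₀ ↔ pIC₅₀ transforms, molecule (µM) and extract (µg/mL) activity labeling |
| `nmrqsar.som` | Kohonen SOM training, stratified partitioning, response patterns, ASD applicability domain, Ward clustering |
| `nmrqsar.feature_selection` | CFS merit and subset search, stepwise AIC elimination, top-N by importance |
| `nmrqsar.models` | RF / k-NN / SVM harness, OOB permutation importances, 50:50 class rebalancing, cross-validation, C tuning |
| `nmrqsar.metrics` | confusion-count metrics, regression reports, outlier flags, table-style rounding |
| `nmrqsar.simulate` | seeded generators for two-class peak-list collections and sparse-signal regression tables |
| `nmrqsar.io` | peak-list CSV/TSV, activity CSV, JCAMP-DX peak tables |
| `nmrqsar.cli` | `nmrqsar` command-line entry point |

## CLI

```sh
# synthesize a labeled two-class data set
nmrqsar simulate --out-peaks peaks.csv --out-activity activity.csv --seed 1

# peak lists -> 520-column descriptor matrix (0.1 ppm 1H / 0.5 ppm 13C)
nmrqsar binify peaks.csv --out matrix.csv

# SOM-stratified train/test split
nmrqsar partition matrix.csv activity.csv --out split.csv --test-fraction 0.33 --seed 1

# descriptor selection (cfs | m5 | rf)
nmrqsar select matrix.csv activity.csv --out selected.csv --method rf --seed 1

# train a class-weight-balanced random forest, predict, evaluate
nmrqsar train matrix.csv activity.csv --out model.joblib --seed 1
nmrqsar predict model.joblib matrix.csv --out predictions.csv
nmrqsar evaluate predictions.csv activity.csv --out report.json

# applicability-domain check (ASD < 0.421 by default)
nmrqsar ad-check train_matrix.csv query_matrix.csv --out ad.csv --seed 1
```

Options may also be supplied per subcommand from a YAML file via
`nmrqsar --config config.yaml <subcommand> ...`; explicit flags override
the config. Every command writes a small `*.manifest.json` provenance
record next to its output.

## Notes

* Bins are half-open `[lo, hi)`; a shift exactly on a shared edge
  belongs to the upper bin. Default bin origins are 0.0019 ppm (¹H) and
  −0.0073 ppm (¹³C), matching the documented descriptor intervals; pass
  `origin=0.0` for plain grids.
* Descriptor semantics default to binary occupancy; peak-count and
  summed-intensity modes are available.
* The 0.421 ASD threshold is calibrated to one particular map and data
  set; recalibrate it when the SOM setup changes.
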