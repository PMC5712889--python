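# nirtransfer

Calibration transfer between near-infrared (NIR) spectrometers: build a
regression model for an analyte (e.g. soluble solids content of fruit, in
%Brix) on one *master* instrument, then keep using it with spectra measured
on a different *slave* instrument — different wavelength grid, resolution,
gain, and baseline — after standardizing the slave spectra onto the master's
space with a small set of shared "standardization" samples.

The package provides, as a library and a `nirtransfer` CLI:

- **Spectra I/O** — a `SpectraSet` container (strictly increasing nm grid,
  absorbance matrix, ids, optional reference values) with exact-round-trip
  CSV readers/writers and wavenumber-header conversion.
- **Preprocessing** — moving average, standard normal variate (SNV), mean
  normalization, composed through a serializable `PreprocessPlan`.
- **Sample selection** — Kennard-Stone maximin selection, calibration /
  prediction splits, standardization-set selection.
- **Regression** — PLS1 (NIPALS) with PRESS-based component selection, and
  LS-SVM with an RBF kernel tuned by fast leave-one-out cross-validation.
- **Transfer** — piecewise direct standardization (PDS), **linear
  interpolation-PDS** (interpolate the slave spectra onto the master grid,
  then PDS — the headline method), and a common-wavelengths-reserved-PDS
  baseline that keeps only channels the two grids share.
- **Evaluation** — R², RMSE, RPD, the standard error of laboratory (SEL)
  from replicate reference measurements, and Passing-Bablok regression for
  method agreement / master-instrument selection.
- **Synthetic data** — a seeded generator of paired master/slave grape-like
  NIR datasets so every stage is testable end to end without downloads.
- **Pipeline** — one-call experiments (`run_experiment`, `compare_methods`,
  `sweep_standardization`) from a YAML-configurable `ExperimentConfig`.

See [docs/methods.md](docs/methods.md) for the scientific details and
design choices.

## Quick start (CLI)

Simulate a paired dataset, train a master model, and carry it over to the
slave instrument:

```bash
nirtransfer simulate --n 120 --seed 7 --out-master m.csv --out-slave s.csv

nirtransfer train --input m.csv --model pls \
    --preprocess moving_average:3,snv --out pls.json
# PLS: 15 components

nirtransfer evaluate --model pls.json --input m.csv \
    --preprocess moving_average:3,snv --label calibration
# calibration: n=120  R2=1.000  RMSE=0.040%  RPD=48.208

nirtransfer transfer build --master-std m.csv --slave-std s.csv \
    --half-width 5 --reference-column reference --out tm.json
# linear_interp_pds model with 801 master channels -> tm.json

nirtransfer transfer apply --model tm.json --input s.csv \
    --reference-column reference --out s_on_m.csv

nirtransfer evaluate --model pls.json --input s_on_m.csv \
    --preprocess moving_average:3,snv --label "slave, transferred"
# slave, transferred: n=120  R2=0.987  RMSE=0.244%  RPD=7.971
```

(The demo builds the transfer from all 120 pairs; in practice you select a
small standardization subset with `nirtransfer select` / Kennard-Stone —
the `run` pipeline below does exactly that.)

The full experiment — simulate 700 samples, Kennard-Stone 550/150 split,
LS-SVM master model, KS-selected standardization set, automatic PDS
half-width search — runs with one command:

```bash
nirtransfer run            # defaults; or: nirtransfer run -c config.yaml
# master calibration: n=550  R2=0.995  RMSE=0.132%  RPD=14.744
# master prediction: n=150  R2=0.981  RMSE=0.220%  RPD=7.194
# untransferred slave: n=150  R2=0.004  RMSE=1.724%  RPD=0.917
# transferred:linear_interp_pds: n=150  R2=0.917  RMSE=0.737%  RPD=2.144
# half-width: 9
```

The untransferred slave spectra are useless with the master model
(R² ≈ 0); linear interpolation-PDS recovers most of the master's
performance from 45 standardization samples.

Other commands: `nirtransfer sweep` (standardization-set size sweep, both
keep-/remove-standards protocol variants), `nirtransfer select`
(Kennard-Stone indices), `nirtransfer compare` (Passing-Bablok agreement
between two measurement series).

## Quick start (library)

```python
from nirtransfer import ExperimentConfig, compare_methods

out = compare_methods(ExperimentConfig(seed=0))
for name, report in out.items():
    print(name, report)
```

`compare_methods` scores the master model, the raw (untransferred) slave
spectra, common-wavelengths-reserved-PDS, and linear interpolation-PDS on
the same split, so the transfer routes are directly comparable.

Lower-level pieces are all public: `read_spectra`, `PreprocessPlan`,
`kennard_stone` / `ks_split`, `pls_fit` / `lssvm_fit` (+ `lssvm_tune`),
`linear_interp_pds` / `build_common_pds` / `apply_transfer`,
`evaluate`, `sel`, `passing_bablok`, `choose_master`,
`generate_paired_dataset`.

## Data format

Plain CSV: first column the sample id, an optional named reference column,
then one column per wavelength with the wavelength (nm) as header.
Headers in wavenumbers (cm⁻¹) are converted on read with
`read_spectra(..., wavenumber=True)`. Writers emit 17 significant digits so
a write/read round trip preserves float64 exactly. Replicate reference
tables (for SEL) are `id,y1,y2,...` CSVs.

## Testing

`pytest` runs ~124 tests, including oracle checks (brute-force
Kennard-Stone, dense-solver LS-SVM, leave-one-out refits, OLS limit of
PLS, enumeration Passing-Bablok) and six end-to-end acceptance properties
in `tests/test_acceptance.py`. Everything is seeded; no fixture files are
required.
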