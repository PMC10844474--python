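# brixvis

A Vis-NIR full-transmission spectroscopy pipeline for predicting fruit
soluble solids content (SSC, °Brix), built around the workflow used for
online tomato grading:

1. **Multi-point scan aggregation** (`brixvis.scanproc`) — each fruit
   passing the detector yields a K×P matrix of position spectra; the
   attenuated end points are trimmed, saturated points dropped, and the
   rest combined by SNR-weighted averaging against a sample-free
   background spectrum.
2. **Pretreatment** (`brixvis.preprocess`) — 13-point Savitzky–Golay
   smoothing, Standard Normal Variate, or raw pass-through.
3. **PLSR** (`brixvis.plsr`) — single-response NIPALS partial least
   squares with 5-fold cross-validated latent-variable selection and the
   Rc/RMSEC/Rp/RMSEP evaluation metrics.
4. **Wavelength selection** (`brixvis.larsselect`) — a from-scratch LARS
   path with the lasso modification (exact piecewise-linear lasso path,
   KKT-certified), a ridge-augmented variant for L2-flavoured selection,
   λ-grid scanning, and reduced-model PLSR refits.
5. **Study orchestration** (`brixvis.pipeline`) — repeated 7:3
   calibration/prediction splits (default 100 repeats), the
   orientation × pretreatment × model grid, reporting and fixture IO.
6. **Synthetic data** (`brixvis.synthetic_data`) — a Beer–Lambert
   forward model that generates multi-point transmission scans with
   known informative bands, multiplicative scatter, end-point
   attenuation, detector saturation and orientation-dependent optical
   paths, so every stage can be tested against ground truth.

## CLI

```bash
# synthetic fixture set (scan CSVs + background + manifest)
brixvis generate --variety provence --orientation O2 --seed 1 --out fixtures/o2

# scans -> one effective spectrum per fruit
brixvis aggregate --fixtures fixtures/o2 --out spectra.csv

# full-spectrum PLSR with CV-chosen latent variables
brixvis train --spectra spectra.csv --pretreatment SNV --out model.json

# characteristic wavelengths via LARS-lasso (omit --lam for CV choice)
brixvis select --spectra spectra.csv --penalty L1 --lam 0.004 --out sel.json

# held-out evaluation
brixvis evaluate --spectra spectra.csv --model model.json --pretreatment SNV

# the repeated-split orientation x pretreatment x model grid
brixvis grid --fixtures-o2 fixtures/o2 --repeats 100 --seed 0 --out report.csv
```

`brixvis grid` also reads a YAML config (`--config`) mirroring the flags;
`brixvis plot-scan` / `brixvis plot-repeats` render the λ-scan curve and
the per-cell error-bar chart.

## Acceptance

The original study's numeric results were computed on spectra that were
never made public, so there are no recomputable numeric targets;
`scripts/acceptance.py` therefore emits an empty JSON report:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Acceptance is property-based and lives in `tests/test_acceptance.py`:
lasso-path equivalence with a coordinate-descent oracle (max-abs 1e-6 +
KKT certification), closed-form checks (soft-thresholding, ridge
endpoint, full-rank PLSR vs least squares), pretreatment and aggregation
invariants, ground-truth band recovery on the default synthetic dataset
(≥95/100 seeds), qualitative trend reproduction on scatter/noise
benchmark fixtures (SNV ≥ RAW, O2 ≥ O1, selected ≥ full-spectrum with no
larger spread over 100 repeated splits), and bit-reproducibility of the
whole grid.

## Notes on conventions

- λ is the penalty weight in `(1/2n)·‖y − Xb‖² + λ·Ω(b)` on
  column-standardized predictors (so λ values are scale-free).
- The `R` metric defaults to the `1 − SSres/SStot` form (`mode="paper"`);
  `mode="sqrt"` gives its square root clipped at zero.
- L2 selection runs the LARS path on the ridge-augmented design
  `[X; √(nλ)·I]` and stops at the knot minimizing 5-fold PLSR RMSECV —
  ridge alone never zeroes coefficients, so sparsity comes from path
  stopping.
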