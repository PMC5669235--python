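# nanoqsar

Nano-QSAR modeling of the cytotoxicity of surface-modified TiO2
nanoparticles, built as a tested, reusable pipeline. The package is aimed at
computational nanotoxicologists who want to go from raw assay readouts
(viability plates, turbidity dilution series) to a validated
structure–activity model of a small nanoparticle panel.

It covers, end to end:

* **The bundled study panel** — 18 TiO2-based samples (an unmodified control
  plus monometallic Au or Pd, alloy Au/Pd, and core–shell Au/Pd surface
  loads), each with CHO-K1 cytotoxicity (EC50, µg/mL), antibacterial
  endpoints toward *E. coli* (MIC, inhibition-zone diameter), and
  physicochemical descriptors (BET specific surface area, minimal and
  maximal particle size). The panel ships with two observed-EC50
  assignments (`table1` for reporting, `table3` for modeling) that disagree
  for three swapped label pairs; both are carried verbatim and the choice is
  always explicit.
* **Dose–response estimation** — viability vs concentration is fitted with a
  four-parameter log-logistic curve
  `v(c) = bottom + (top − bottom) / (1 + (c/EC50)^h)` by bounded nonlinear
  least squares; an EC50 outside the tested range (1.56–300 µg/mL in the
  assay design) is reported censored (e.g. `>300`), never extrapolated. MIC
  is the lowest concentration of a descending twofold series with ≥ 80%
  turbidity decrease relative to the growth control.
* **The Gaussian-process regressor** — descriptors standardized on the
  training rows, cosine-normalized polynomial kernel
  `k(x,z) = (x·z + c)^d / sqrt((x·x + c)^d (z·z + c)^d)`, targets centered
  and scaled internally, `(K + σ²I)` solved by Cholesky factorization.
  Degree, lower-order constant and noise are chosen by a deterministic grid
  search maximizing leave-one-out R² on the training set.
* **Validation machinery** — training R² and RMSEC, external Q²_EXT
  (validation-mean centering, with a training-mean option) and RMSEP,
  bootstrap (bagging) validation with out-of-bag scoring, and a Y-scrambling
  chance-correlation test with frozen hyperparameters.
* **Per-topology polynomial sub-models** — interpretable OLS polynomials in
  raw descriptors (pure → average size, cubic; alloy → BET surface,
  quadratic; core–shell → average size, quadratic), with the full R² grid by
  topology and order.
* **Synthetic data** — panels and raw plates with known ground truth, so
  every stage is testable without downloads.

## Worked example

```bash
nanoqsar fit --dataset bundled --variant table3 --seed 1 --out-dir demo
```

prints the modeling table (observed vs predicted EC50 per sample) and the
summary line

```
R2(train)=0.0933  RMSEC=40.92  Q2_EXT=-0.3845  RMSEP=25.74  R2_bagging=-1.8105  RMSE_bagging=48.04
variant=table3  n=12  k=5
```

Read this as a negative scientific result for the bundled panel: the
leave-one-out grid search finds no configuration with out-of-sample skill
(every LOO R² is negative), so it selects a strongly regularized model that
shrinks toward the training mean — training R² near zero, external Q²_EXT
below zero. With twelve training samples and three nearly uncorrelated
descriptors, the honest model is close to the mean predictor. The
per-topology polynomials tell the interpretable part of the story:

```bash
nanoqsar table4 --dataset bundled --variant table1 --out-dir demo
```

```
type of NPs     linear  2nd order  3rd order
pure              0.29       0.48       0.92
alloy             0.51       0.57       0.71
core_shell        0.10       0.42       0.48
```

Linear fits fail everywhere; a cubic in average particle size describes the
six monometallic samples well (R² = 0.92). Other subcommands: `scramble`
(Y-randomization), `ec50` and `mic` (plate-level analysis), `simulate`
(synthetic panels), `predict` (saved-model predictions). See
`nanoqsar <command> --help`.

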