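# riverbio

Linking benthic-macroinvertebrate biodiversity to water physicochemistry.

River managers typically hold long records of water chemistry (temperature
T, discharge Q, pH, dissolved oxygen DO, electrical conductivity EC, BOD₅,
total dissolved solids TDS) but only short biological monitoring records.
`riverbio` implements, as a tested pipeline, the workflow that turns a year
of benthic community counts into a closed-form estimator of a biodiversity
index from chemistry alone:

* **Diversity indices** per station-month sample — Shannon
  H = −Σ Pᵢ ln Pᵢ, Simpson D = 1 − Σ Pᵢ², Margalef MI = (s−1)/ln N,
  where Pᵢ is the relative abundance of taxon *i*, s the taxon richness and
  N the total individual count.
* **Screening** — Pearson correlation matrix of indices and chemistry;
  2-means seasonal clustering with exclusion of the winter cluster;
  collinearity pruning (TDS, a near-exact multiple of EC, is dropped);
  varimax-rotated PCA of the remaining predictors.
* **Genetic-programming symbolic regression** — a from-scratch Koza-style
  engine (function set {+, −, ×, protected ÷}, tournament selection, subtree
  crossover/mutation, elitism) run as many independent restarts per index on
  [0,1]-standardized data split 80/20; a variable-presence tally across
  restart best equations serves as a crude importance measure, and the
  restart with the highest training correlation is kept.
* **Reporting** — the index best modelled by chemistry is selected
  (Margalef, for the seasonal regime emulated here) and observed-vs-
  calculated means, standard deviations, estimation errors, R² and MSE are
  reported per split, with the per-sample series saved for plotting.

Because the motivating monitoring dataset is not publicly deposited, the
package ships a synthetic-data generator (`riverbio.synthetic`) that
reproduces its statistical skeleton — seasonal cycles, a strong negative
T–DO correlation, EC–TDS proportionality — and plants a known
environment→Margalef link of the form `MI ∝ DO/T + 2·DO/(T + EC + BOD₅)`
for recovery testing. See `docs/methods.md` for the model details.

## Worked example

```sh
python analysis/01_simulate.py     # synthetic 6-station x 12-month dataset
python analysis/02_indices.py     # diversity indices per sample
python analysis/03_screen.py      # correlations, clustering, PCA
python analysis/04_gp_search.py   # 20-restart GP on the Margalef index
python analysis/05_report.py      # full pipeline + fit report
```

`03_screen.py` prints the screening structure of the generated data:

```
correlation matrix (indices vs environment):
          temperature  discharge_q     ph  do_mgl     ec   bod5    tds
shannon        -0.839        0.011  0.020   0.771 -0.681 -0.496 -0.681
simpson        -0.699       -0.006  0.017   0.660 -0.574 -0.383 -0.574
margalef       -0.952       -0.011  0.022   0.879 -0.746 -0.591 -0.746

2-means: 100% of Dec-Feb samples share one cluster;
winter cluster excluded -> 37 samples retained for regression
collinearity pruning (|r| >= 0.95): dropped ['tds'], kept ['temperature',
'discharge_q', 'ph', 'do_mgl', 'ec', 'bod5']

rotated PCA: first 4 components explain 92.4% of variance
```

Margalef correlates most strongly with chemistry, winter separates cleanly,
TDS is pruned as redundant with EC, and four rotated components carry most
of the predictor information. `05_report.py` then runs the scaled GP search
(20 restarts × 100 generations per index) and prints:

```
cross-run best training correlation per index:
  shannon   r = 0.790
  simpson   r = 0.777
  margalef  r = 0.972 <- selected

fit statistics (original index scale):
     split  obs mean  calc mean  mean err %  obs std  calc std  std err %    R2   MSE
     train      1.04       1.04         0.1     0.18      0.18        4.2 0.946 0.002
validation      0.97       0.95         1.9     0.20      0.23       15.1 0.717 0.013
```

The planted Margalef link is recovered as the best-modelled index; the mean
of the index is estimated within ~2% on held-out samples, with R² = 0.95
(train) / 0.72 (validation) for this seed.

A `riverbio` console command exposes the same steps
(`riverbio simulate | indices | screen | gp | report`); see `riverbio --help`.

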