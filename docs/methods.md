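# Methods

## Problem and approach

River managers often hold long physicochemical records (temperature,
discharge, pH, dissolved oxygen, conductivity, BOD₅, dissolved solids) but
only short biological monitoring records. If a biodiversity index of the
benthic macroinvertebrate community can be expressed as a closed-form
function of water chemistry, ecosystem condition can be estimated wherever
chemistry is measured. `riverbio` implements that programme end to end:

1. compute Shannon (H = −Σ Pᵢ ln Pᵢ), Simpson (D = 1 − Σ Pᵢ²), and Margalef
   (MI = (s−1)/ln N) indices per station-month sample;
2. screen the joint structure of indices and chemistry (Pearson
   correlations);
3. stratify seasons by 2-means clustering and exclude the winter cluster,
   which in strongly seasonal rivers occupies its own region of environment
   space and would otherwise dominate the regression;
4. prune collinear predictors (TDS is a near-exact multiple of EC in most
   records; EC is kept by convention);
5. min-max standardize predictors and targets to [0, 1] and split 80/20;
6. run many independent genetic-programming (GP) searches per index, tally
   which predictors occur in each restart's best equation, and keep the
   restart with the highest training correlation;
7. cross-check variable importance with a varimax-rotated PCA;
8. select the index whose best equation correlates most strongly and report
   observed-vs-calculated means, standard deviations, estimation errors
   (100·|obs − calc|/|obs|), R² (squared Pearson r), and MSE per split on
   the original index scale.

The reference closed form for the Margalef index,

    MI = DO/T + 2·DO/(T + EC + BOD₅),

is exposed as `pipeline.evaluate_margalef_equation`. The flat typeset source
of this expression is ambiguous about grouping; the adopted reading is the
only one in which both terms are dimensionally coherent ratios of DO to a
temperature-plus-chemistry denominator. The function accepts either raw-unit
or standardized inputs; the caller declares the scale.

### Shannon sign convention

Some presentations write the Shannon index without the leading minus sign,
which would make it non-positive. We implement H = −Σ Pᵢ ln Pᵢ (natural
logarithm, 0·ln 0 := 0) so that larger values mean more diversity, the
interpretation every downstream correlation in this package assumes.

## The GP engine

Expression trees are flat prefix token lists over binary operators
{+, −, ×, ÷} (division protected: x/y := 1 when |y| ≤ 1e−9), predictor
variables, and ephemeral random constants drawn uniformly from [0, 1] (the
same scale as the standardized predictors). Defaults: population 300, 500
generations, crossover 0.9, subtree mutation 0.1, tournament size 3, ramped
half-and-half initialization at depths 2–6, hard depth cap 12 (offspring
over the cap are rejected in favour of the first parent), elitism 1.
Fitness within a run is training RMSE; Pearson r is recorded for the
cross-run selection step. Tournament selection was chosen because it is
invariant to monotone rescaling of the fitness; roulette-wheel selection is
not. A zero-variance prediction vector is assigned r = 0 (worst) rather than
undefined. Ties in cross-run selection break by lower training RMSE, then
lower run index, making selection deterministic and permutation-invariant.

Evaluation is vectorised: the prefix list is scanned once in reverse with a
stack of numpy row-vectors, so a whole population evaluates in milliseconds
on the sample sizes used here. Trees serialize to a canonical prefix string
(constants at 12 significant digits) and re-parse losslessly.

Variable presence is counted as syntactic occurrence of a predictor anywhere
in a restart's best tree, with no symbolic simplification — simplification
would change tallies in ill-defined ways. Because unsimplified trees bloat
toward the depth cap over long searches, presence percentages saturate as
generations grow; at the scaled search size used in the analysis scripts
(100 generations) they remain discriminative.

## Synthetic data

No public dataset accompanies the monitoring design this package emulates
(six stations on one river, sampled monthly for a year), so
`riverbio.synthetic` generates one with the documented statistical skeleton:

* temperature: annual sinusoid peaking in July, 21 ± 7 °C plus N(0, 0.8)
  noise;
* dissolved oxygen: DO = 13 − 0.18·T + N(0, 0.65) mg/L, giving r(T, DO)
  ≈ −0.8, the magnitude reported for such rivers, while keeping DO near the
  well-oxygenated range (≳ 7.6 mg/L);
* conductivity: 250 ± 30 µmhos/cm seasonal plus N(0, 25), sharing enough of
  the annual cycle with temperature for a moderate positive correlation;
* TDS = 0.64 × EC exactly, so the EC–TDS correlation is 1.0 and the
  collinearity-pruning rule has a genuine target;
* discharge: 4 ± 3 peaking in April (spring snowmelt), pH ≈ 7.8 and BOD₅
  ≈ 2 mg/L nearly aseasonal; all variables clipped to physical ranges
  (pH ∈ [6, 9], positive concentrations).

The community table is generated by inverting the Margalef index: per sample,
total abundance N ~ Uniform{50..500} (plausible benthic kick-sample sizes),
target MI\* = planted formula + N(0, noise_sd), richness
s = clamp(round(1 + MI\*·ln N), 1, 30), one individual per chosen taxon plus
a Dirichlet(1)-multinomial allocation of the remainder. The realised index is
exactly (s−1)/ln N, i.e. the planted value up to rounding (≤ 1/ln N) and
noise. The planted formula defaults to the closed form above scaled by 2.6 so
the realised Margalef values match the magnitude of the reference fit table
(non-winter mean ≈ 1.2, sd ≈ 0.4); unscaled, the formula on these unit
ranges sits near 0.5 and the rounding step would drown the signal.
Evenness is irrelevant to Margalef, so the Dirichlet concentration is a free
choice. Stations differ only by i.i.d. noise — the generator plants no
between-station structure, no pollution gradients, and no taxon-specific
tolerance, so passing tests demonstrate recovery of the planted link, not
realism of community assembly.

## Scaled problem sizes

The full search protocol (100 restarts × 500 generations per index) is the
package default, but the analysis scripts, tests, and the acceptance script
use a scaled search — 20 restarts × 100 generations, population 300 — which
recovers the planted structure on 72 samples while keeping each end-to-end
run to a couple of minutes. The GP-recovery experiment (planted y = x₀/x₁ on
50 rows) uses one run of 100 generations.

## Numerical choices and degenerate inputs

* Min-max bounds are fitted on the full post-winter-exclusion dataset before
  the 80/20 split, mirroring a standardize-first protocol; the mild
  train-to-validation leakage this implies is deliberate and documented, not
  silently fixed. Constant columns standardize to 0, keeping outputs
  in-range and making degeneracy visible.
* Correlations are Pearson; constant columns raise a named error rather than
  propagating NaN.
* K-means: k = 2, k-means++ initialization, 10 restarts, seeded (delegated
  to scikit-learn). Winter is December–February (meteorological convention;
  configurable). A tie in winter membership between the two clusters raises
  an ambiguity error instead of guessing.
* Collinearity threshold |r| ≥ 0.95 with caller-supplied keep-priority
  (EC before TDS by default).
* PCA is an eigendecomposition of the correlation matrix; loadings are
  eigenvectors scaled by √eigenvalue, varimax rotation (statsmodels)
  preserves per-variable communalities to ~1e−6; four components are
  retained by default. Component signs are fixed so each column's largest
  loading is positive.
* Sample standard deviations use the n−1 denominator.
* Margalef requires N ≥ 2 (ln N > 0); single-individual samples raise a
  degenerate-sample error. Empty or all-zero count vectors are invalid
  inputs everywhere.
* The train/validation split takes round(0.8·n) training samples uniformly
  without replacement, seeded; splits that would empty a part are errors.

## Known limitations

* Training-set correlation drives cross-run selection (avoiding validation
  leakage); with small training sets and long searches, unrelated targets
  can reach high training correlations by overfitting, so scaled searches
  keep generations moderate.
* The winter-exclusion step assumes exactly two clusters; multi-modal
  seasonality would need a different stratification.
* Presence tallies are syntactic and inflate with tree bloat (see above).
* The generator emulates one river's regime; conclusions about other
  regimes require re-planting the link with appropriate ranges.
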