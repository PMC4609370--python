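# Methods

## Problem setting

`gasvr` builds QSAR regression models of the form *y = f(x)* where *x* is a
vector of molecular descriptors and *y* a continuous property — the
motivating case is log BB, the logarithm of the steady-state brain/blood
concentration ratio. Two coupled choices dominate the quality of an
RBF-kernel support-vector regression (SVR) model: the hyperparameters
(C, γ, ε) and which small subset of the available descriptors to use. The
package treats these as a single optimization problem: a genetic algorithm
(GA) searches over mixed chromosomes that carry the three hyperparameters
as bounded float genes and a fixed-size feature subset as an integer gene,
scored by the mean squared error of 10-fold cross-validation (CV-MSE).

## Model and fitness

The SVR model is ε-insensitive regression with the Gaussian kernel
K(x_i, x_j) = exp(−γ‖x_i − x_j‖²); its prediction is the kernel expansion
f(x) = Σ_i (α_i − α_i*) K(x_i, x) + b over the support vectors. The
quadratic program is solved by scikit-learn's libsvm binding;
`TrainedSVRModel` stores the support vectors, dual-coefficient differences
and bias, and evaluates the expansion itself, so the prediction contract is
checkable independently of the solver (tests compare the two routes to
1e-6).

Fitness is the pooled k-fold CV-MSE, MSE = (1/n) Σ (ŷ_i − y_i)², lower is
better. Fold membership is derived from the *sorted sample identifiers*
(seeded shuffle, contiguous blocks), and fold rows are always processed in
that canonical order; CV-MSE is therefore bit-for-bit invariant to row
permutations of the input table. Within one GA run the fold assignment is
fixed (seed derived from the run seed), making fitness a deterministic
function of the chromosome; identical chromosomes are served from a cache.

Model quality is reported as r², the squared Pearson correlation between
predictions and observations — the convention in QSAR tables. It is
sign-blind and affine-invariant; a constant prediction vector scores 0. A
coefficient-of-determination variant was considered and rejected as the
default because published log BB models are compared on correlation r².

## Feature scaling

Descriptor matrices mix counts, surface areas and quantum-chemical energies
whose scales differ by orders of magnitude; RBF distances on raw columns
are dominated by whichever descriptor has the largest variance. All SVR
fits therefore z-score features, with the statistics learned on the
training portion only (per CV fold, or per train partition for final
models) and applied to held-out data — no leakage, asserted by an
instrumented test that corrupts held-out targets and checks train-side
metrics are bit-identical. Kennard-Stone distances are computed on z-scored
features by default for the same reason, with a flag to disable.

## Data cleaning

Cleaning follows standard descriptor-matrix practice:

1. columns with any missing value are dropped (no imputation);
2. columns with no variation are dropped;
3. pairs with |Pearson r| above a cutoff (default 0.999999 — only
   effectively duplicated columns, since even highly correlated descriptors
   can be complementary) are collapsed by removing one randomly chosen
   member, in a single greedy pass over column-ordered pairs. The pass
   examines every surviving pair, so the output contains no over-cutoff
   pair and a second pass is a no-op (tested). Absolute correlation is
   used; a perfectly anti-correlated copy carries no extra information.

## Train/test splitting

The Kennard-Stone maximin procedure picks a training set spread uniformly
through descriptor space: first the sample closest to the centroid, then
repeatedly the sample maximizing the minimum Euclidean distance to those
already chosen. Ties break to the lowest row index, making the split
deterministic and order-stable. The target is excluded from the distance
computation. The implementation is O(n·n_train) with an incremental
minimum-distance update; tests verify every selection step against a
brute-force maximin enumeration on hundreds of small random tables.

## Genetic algorithm

* **Chromosome**: (C, γ, ε) floats within `GeneBounds`, plus k distinct
  feature indices in [0, N).
* **Selection**: tournament of 3, drawn with replacement, best CV-MSE wins,
  ties to the first drawn.
* **Crossover** (applied to a selected pair with probability 0.8; otherwise
  the fitter parent is cloned): float genes blend as child = β·p1 + (1−β)·p2
  with β ~ U[−0.25, 1.25] drawn independently per gene, clamped to bounds;
  the feature gene crosses position-wise by coin flip, with duplicate slots
  repaired from the parents' unused indices (falling back to a uniform draw
  over the unused remainder of [0, N)).
* **Mutation** (per gene, probability 0.1): a float gene moves a random
  fraction β ~ U[0, 1] of the way to its lower or upper bound (direction by
  fair coin); a feature slot is replaced by a uniform draw that avoids
  indices already present (unchanged if k = N, where no legal replacement
  exists).
* **Generation assembly**: the 2 best individuals are copied unchanged
  (elitism), 8 fresh random "immigrant" chromosomes are injected for
  diversity, and the remainder of the population of 100 is bred as above.
  Elitism makes the per-generation best trace non-increasing (tested).
* **Termination**: a fixed generation budget (default 1000); no
  early-stopping rule is applied.

Gene bounds default to C ∈ [0.01, 100], γ ∈ [10⁻⁴, 2], ε ∈ [0.001, 1] —
wide enough to bracket the hyperparameter ranges that RBF-SVR on z-scored
descriptors plausibly needs, and fully configurable. Initial populations
and immigrants draw float genes uniformly within bounds and feature genes
uniformly without replacement.

Replicate sweeps (`run_replicates`) derive each run's seed deterministically
from (base seed, k, run index) via a seed sequence, so a sweep is exactly
reproducible and individual runs can be reproduced in isolation. The best
replicate per k is the one with minimum CV-MSE; test-set performance is
reported but never used for selection.

## Grid-search baseline

The no-selection baseline discretizes (C, γ, ε) on log₂-spaced axes
(defaults C: 2⁻⁵…2¹⁵, γ: 2⁻¹⁵…2³, ε: 2⁻⁸…2⁻¹) and evaluates CV-MSE at
every point with a fold assignment fixed once per search; ties go to the
first point in iteration order. The acceptance script uses a coarser
4×4×3 grid appropriate to its problem size.

## Synthetic data

Because descriptor matrices from the proprietary toolchains
(AMPAC/CODESSA/Marvin) cannot be redistributed or regenerated, the
`synthetic` module emulates their structure with full ground truth:

* continuous columns ~ Normal with per-column location and scale, scale
  log-uniform over 4 orders of magnitude (forces the scaling decision to
  matter);
* binary indicator columns ~ Bernoulli(p), p ~ U[0.1, 0.5], emulating
  substructure flags such as a carboxylic-acid indicator;
* planted near-duplicate blocks (`copies` mutually identical columns up to
  optional jitter) and constant columns at the high end of the column
  range;
* target = Σ effect · z(informative column) — binary indicators enter raw
  as 0/1 shifts — optionally plus a smooth interaction of the first two
  informative features, plus Gaussian noise. Default effect signs follow
  the sign structure typical of BBB modelling: one positive
  lipophilicity-like effect, negative PSA/H-bonding-like effects, and a
  negative binary indicator.

`paper_shaped_spec()` reproduces the geometry of the motivating dataset
(323 samples × 326 descriptors, 2 indicator columns, 4 planted duplicate
extras + 3 constants, so cleaning removes exactly 7 columns and a 260-point
Kennard-Stone split leaves 63 test samples). `recovery_spec()` is the
200 × 30 benchmark used throughout testing: informative features at
indices {0, 5, 12} with effects (−1, +1, −0.7), index 0 a binary
indicator, and noise calibrated to 10% of the noiseless target's sd by a
two-pass generation (the feature matrix is identical in both passes since
noise is drawn last).

What the generator does **not** emulate: real descriptor covariance
(beyond planted duplicate blocks, columns are independent), physical
relationships among descriptors, heteroscedastic or non-Gaussian
measurement error, and the mixture of in vivo/in vitro measurements. A
passing recovery test therefore shows the machinery can find a planted
low-dimensional signal under realistic scale heterogeneity and nuisance
columns — not that it would identify the "true" descriptors of any
particular laboratory dataset.

## Numerical choices

* SMO solver: scikit-learn SVR defaults (tolerance 1e-3, shrinking on),
  with iterations capped at 10 000 in the default trainer. The cap bounds
  solver time in hostile hyperparameter corners (very large C with a
  near-zero ε-tube can cost two orders of magnitude more time for a
  negligible change in the fitted function); `max_iter=-1` gives the
  uncapped exact solve and is used by the contract tests.
* Zero-variance columns encountered by a scaler get scale 1 (the centered
  column is all zeros either way).
* Kennard-Stone uses squared distances internally (monotone, cheaper);
  argmin/argmax tie-breaking inherits numpy's first-occurrence rule =
  lowest row index.
* Degenerate inputs: constant targets fit a bias-only model; all-identical
  rows are accepted (constant prediction); an empty test partition degrades
  the final-model report to train-side metrics with a warning.

## Problem sizes used in the shipped checks

The test suite and acceptance script exercise the GA at population 30 on
the 200 × 30 benchmark (100 generations × 10 replicates in the test suite;
80 generations × 8 replicates in the acceptance script, which also runs
the grid baseline and the structural checks). These sizes were chosen so
the planted-truth oracles (exhaustive C(30,3) subset enumeration, maximin
enumeration on ≤12-sample tables) remain computable exactly; the package
defaults (population 100, 1000 generations, 50 replicates per k) are the
intended settings for real modelling campaigns.

## Known limitations

* The GA assumes a fixed subset size k per run; sweeping k is an outer
  loop (`run_replicates`), not part of the chromosome.
* CV-MSE fitness with folds fixed per run can overfit the fold assignment
  in principle; replicate runs with different seeds are the intended
  mitigation.
* r² as squared correlation rewards calibration-free association; use the
  reported test RMSE alongside it.
* Single-objective, single-population GA only; no parallel islands, no
  multi-objective accuracy/complexity trade-off.
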