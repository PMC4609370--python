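# gasvr

Genetic-algorithm wrapper feature selection and hyperparameter tuning for
RBF support-vector regression, aimed at QSAR modelling — the motivating
application is predicting blood-brain-barrier penetration (log BB, the log
brain/blood concentration ratio) from computed molecular descriptors.

For an RBF-SVR model the hyperparameters (C, γ, ε) and the descriptor
subset interact: the best kernel width for six features is not the best
width for three hundred. `gasvr` therefore optimizes both at once. A
real-coded genetic algorithm evolves mixed chromosomes

```
[ C | γ | ε | f₁ f₂ … f_k ]        f_i distinct indices into the feature table
```

scored by the fitness

```
MSE_cv = (1/n) Σᵢ (ŷᵢ − yᵢ)²       pooled over 10 cross-validation folds,
```

with the SVR prediction f(x) = Σᵢ (αᵢ − αᵢ*) K(xᵢ, x) + b and kernel
K(xᵢ, xⱼ) = exp(−γ‖xᵢ − xⱼ‖²). Selection is tournament-of-3; float genes
recombine by blend crossover (β ∈ [−0.25, 1.25]) and mutate toward a bound;
the feature gene uses uniform crossover and duplicate-avoiding mutation;
each generation keeps 2 elites and injects 8 random immigrants.

Around the optimizer the package provides the full pipeline:

* `datakit` — CSV feature tables; cleaning (drop missing/invariant
  columns, collapse |r| > 0.999999 near-duplicates); deterministic
  Kennard-Stone maximin train/test splitting.
* `svr_fitness` — SVR training (scikit-learn/libsvm behind an explicit
  kernel-expansion model object), id-keyed 10-fold CV-MSE, r², and an
  exhaustive grid-search baseline.
* `ga_engine` — the GA, replicate sweeps over subset sizes k, per-run
  evolution histories.
* `model_analysis` — feature occurrence counts across replicate models and
  aggregation into physicochemical property groups
  (see `examples/bbb_descriptor_groups.csv` for a five-group example
  mapping: carboxylic-acid indicator, PSA, H-bonding, lipophilicity,
  molecular charge).
* `synthetic` — QSAR-shaped synthetic tables with planted ground truth
  (informative features, near-duplicate blocks, constant columns,
  heterogeneous scales), since real descriptor matrices come from
  proprietary software and cannot ship.

See `docs/methods.md` for the model, the operator definitions and every
numerical choice.

## Worked example

Recover three planted informative features (one of them a binary
indicator with a negative effect) from a synthetic 200-sample × 30-feature
table with noise at 10% of signal:

```python
from gasvr import (GAConfig, evaluate_final_model, evolve, generate,
                   kennard_stone_split, recovery_spec, take_samples)

table, truth = generate(recovery_spec(seed=7))
split = kennard_stone_split(table, n_train=160)
train = take_samples(table, split.train_indices)

config = GAConfig(k_features=3, population_size=30, generations=60, seed=7)
history = evolve(train, config)

best = history.best_individual
print("selected features:", sorted(best.chromosome.features),
      "(planted:", sorted(truth.informative_indices), ")")
print(f"cv_mse={best.fitness:.4f}")
report = evaluate_final_model(table, split, best.chromosome)
print(f"train_r2={report['train_r2']:.3f}  test_r2={report['test_r2']:.3f}  "
      f"test_rmse={report['test_rmse']:.3f}")
```

prints

```
selected features: [0, 5, 12] (planted: [0, 5, 12] )
cv_mse=0.0178
train_r2=0.991  test_r2=0.992  test_rmse=0.122
```

The GA found exactly the planted triple; the cross-validated MSE of the
winning model is far below the target variance, and train/test r² agree,
i.e. the 3-feature model generalizes. A grid-searched SVR using *all*
30 features does markedly worse on the same test partition — the point of
selecting features and hyperparameters together.

The same flow is available from the shell:

```bash
gasvr simulate --preset recovery --seed 7 --out table.csv
gasvr clean    --input table.csv --target y --out clean.csv --log removed.csv
gasvr split    --input clean.csv --target y --n-train 160 --out split.csv
gasvr evolve   --input clean.csv --target y --k 3 --pop 30 --gens 60 --seed 7
gasvr replicates --input clean.csv --target y --k-min 3 --k-max 6 --runs 10 \
                 --summary-out summary.csv --models-out runs/
gasvr analyze  --models 'runs/*.json' --input clean.csv --target y
```

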