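"""Post-hoc analysis of replicate GA runs and final-model reporting.

Replicate runs of a wrapper selector rarely agree on a single subset; what
is stable across replicates is which features keep reappearing. Counting
feature occurrences over the best chromosome of every run, and aggregating
the counts by physicochemical group (e.g. carboxylic-acid indicator,
H-bonding, polar surface area, lipophilicity, molecular charge), turns 50
models into an interpretable ranking of the properties driving the target.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datakit import FeatureTable, SplitResult, take_samples
from .errors import ValidationError
from .ga_engine import Chromosome
from .svr_fitness import cv_mse, mse, r_squared, train_svr

__all__ = ["feature_frequency", "group_occurrence", "evaluate_final_model"]


def _model_features(model) -> tuple[int, ...]:
    if isinstance(model, Chromosome):
        return model.features
    return tuple(int(i) for i in model)


def feature_frequency(
    models: Iterable[Chromosome | Sequence[int]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Occurrence count of every feature across a collection of models.

    ``models`` may hold Chromosomes or bare index sequences. The returned
    frame has one row per universe feature — columns ``feature_index``,
    ``feature_name``, ``count``, ``n_models`` — sorted by descending count,
    ties broken by ascending index.
    """
    universe = list(universe)
    counts: Counter[int] = Counter()
    n_models = 0
    for model in models:
        n_models += 1
        for i in _model_features(model):
            if not 0 <= i < len(universe):
                raise ValidationError(f"feature index {i} outside the universe")
            counts[i] += 1
    frame = pd.DataFrame(
        {
            "feature_index": np.arange(len(universe), dtype=int),
            "feature_name": universe,
            "count": [counts.get(i, 0) for i in range(len(universe))],
            "n_models": n_models,
        }
    )
    frame = frame.sort_values(["count", "feature_index"], ascending=[False, True])
    return frame.reset_index(drop=True)


def group_occurrence(
    freq: pd.DataFrame,
    groups: Mapping[str, str],
) -> pd.Series:
    """Aggregate feature occurrence counts by property group.

    ``groups`` maps feature name to group label; features absent from the
    mapping are pooled under ``"other"``. Returns a Series of totals sorted
    by descending count (ties by group name).
    """
    labels = [groups.get(name, "other") for name in freq["feature_name"]]
    totals = pd.Series(freq["count"].to_numpy(), index=labels).groupby(level=0).sum()
    totals = totals.sort_index(kind="stable")  # tie order: ascending group name
    return totals.sort_values(ascending=False, kind="stable")


def evaluate_final_model(
    table: FeatureTable,
    split: SplitResult,
    chromosome: Chromosome,
    n_folds: int = 10,
    seed: int | None = 0,
) -> dict[str, float]:
    """Train the chromosome's model on the training partition and report metrics.

    The scaler and the SVR are fit on the training rows only; the test
    partition enters solely at prediction time. Returned keys: ``train_r2``,
    ``cv_mse`` (k-fold CV on the training partition), and — when the test
    partition is non-empty — ``test_r2`` and ``test_rmse``.
    """
    for i in chromosome.features:
        if not 0 <= i < table.n_features:
            raise ValidationError(f"chromosome references feature index {i} not in table")
    train = take_samples(table, split.train_indices)
    model = train_svr(train.X, train.y, chromosome.params, feature_indices=chromosome.features)
    report: dict[str, float] = {
        "train_r2": r_squared(model.predict(train.X), train.y),
        "cv_mse": cv_mse(train, chromosome.features, chromosome.params, n_folds=n_folds, seed=seed),
    }
    if split.test_indices:
        test = take_samples(table, split.test_indices)
        pred = model.predict(test.X)
        report["test_r2"] = r_squared(pred, test.y)
        report["test_rmse"] = math.sqrt(mse(pred, test.y))
    else:
        warnings.warn("empty test partition: test metrics omitted", stacklevel=2)
    return report
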