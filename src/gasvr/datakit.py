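"""Feature-table loading, cleaning and representative train/test splitting.

The cleaning pipeline mirrors standard QSAR practice for descriptor
matrices: columns with missing values or no variation are dropped, and
near-perfectly correlated descriptor pairs (|r| above a very high cutoff,
0.999999 by default) are reduced to a single member, chosen at random.
The very high cutoff is deliberate — strongly correlated descriptors can
still be complementary, so only effectively duplicated columns go.

Train/test splitting uses the Kennard-Stone maximin procedure, which picks
a training set spread uniformly through descriptor space: the first point
is the one closest to the centroid, and every subsequent point maximizes
its minimum Euclidean distance to the points already chosen.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyTableError, ValidationError

__all__ = [
    "FeatureTable",
    "SplitResult",
    "read_feature_table",
    "drop_unusable_features",
    "drop_near_duplicate_features",
    "kennard_stone_split",
    "take_samples",
]


@dataclass(frozen=True)
class FeatureTable:
    """Samples x named numeric features plus a continuous target.

    Attributes
    ----------
    sample_ids : tuple of str
        Unique identifier per row.
    feature_names : tuple of str
        Unique name per feature column.
    X : ndarray of shape (n_samples, n_features)
        Feature matrix; missing values are stored as NaN.
    y : ndarray of shape (n_samples,)
        Continuous regression target (log BB for the BBB use case).
    """

    sample_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_names", tuple(str(f) for f in self.feature_names))
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be a 2-D matrix")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample ids must be unique")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("feature names must be unique")
        if not (len(self.sample_ids) == X.shape[0] == y.shape[0]):
            raise ValidationError("sample_ids, X rows and y must have equal length")
        if X.shape[1] != len(self.feature_names):
            raise ValidationError("feature_names must match X columns")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def take_features(self, indices: Sequence[int]) -> "FeatureTable":
        """Return a table restricted to the given feature columns."""
        idx = _as_feature_indices(indices, self.n_features)
        return replace(
            self,
            feature_names=tuple(self.feature_names[i] for i in idx),
            X=self.X[:, idx],
        )


@dataclass(frozen=True)
class SplitResult:
    """Disjoint train/test row indices covering all samples.

    ``train_indices`` is kept in Kennard-Stone selection order;
    ``test_indices`` is ascending.
    """

    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        train = set(self.train_indices)
        test = set(self.test_indices)
        if train & test:
            raise ValidationError("train and test indices overlap")
        if len(train) != len(self.train_indices):
            raise ValidationError("duplicate train indices")


def _as_feature_indices(indices: Sequence[int], n_features: int) -> list[int]:
    idx = [int(i) for i in indices]
    for i in idx:
        if not 0 <= i < n_features:
            raise ValidationError(f"feature index {i} out of range [0, {n_features})")
    return idx


def read_feature_table(
    path,
    target_column: str,
    id_column: str | None = None,
) -> FeatureTable:
    """Read a CSV feature table.

    The file must have a header row. One column (``id_column``, default the
    first column) holds sample identifiers, ``target_column`` holds the
    continuous response, and every other column is a feature. Non-numeric
    cells in feature columns are recorded as missing (NaN).
    """
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    if target_column not in header:
        raise ConfigurationError(f"target column {target_column!r} not found in header")
    if id_column is None:
        id_column = header[0]
        if id_column == target_column:
            raise ConfigurationError("first column is the target; pass id_column explicitly")
    elif id_column not in header:
        raise ConfigurationError(f"id column {id_column!r} not found in header")

    feature_names = [c for c in header if c not in (id_column, target_column)]
    dupes = {c for c in feature_names if feature_names.count(c) > 1}
    if dupes:
        raise ValidationError(f"duplicate feature names in header: {sorted(dupes)}")

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = header  # undo pandas' mangling of any duplicate id/target clash
    y = pd.to_numeric(df[target_column], errors="coerce").to_numpy()
    if np.isnan(y).any():
        raise ValidationError("target column contains missing or non-numeric values")
    feats = df[feature_names].apply(lambda c: pd.to_numeric(c, errors="coerce"))
    return FeatureTable(
        sample_ids=tuple(df[id_column].astype(str)),
        feature_names=tuple(feature_names),
        X=feats.to_numpy(dtype=float),
        y=y,
    )


def drop_unusable_features(
    table: FeatureTable,
) -> tuple[FeatureTable, list[tuple[str, str]]]:
    """Remove feature columns containing missing values or showing no change.

    Returns the reduced table and a removal log of ``(feature, reason)``
    pairs with reason ``"missing"`` or ``"invariant"``. Sample rows and the
    target are untouched. Raises :class:`EmptyTableError` if nothing is left.
    """
    X = table.X
    log: list[tuple[str, str]] = []
    keep: list[int] = []
    for j, name in enumerate(table.feature_names):
        col = X[:, j]
        if np.isnan(col).any():
            log.append((name, "missing"))
        elif col.max() == col.min():
            log.append((name, "invariant"))
        else:
            keep.append(j)
    if not keep:
        raise EmptyTableError("all feature columns were removed")
    return table.take_features(keep), log


def drop_near_duplicate_features(
    table: FeatureTable,
    cutoff: float = 0.999999,
    seed: int | None = None,
) -> tuple[FeatureTable, list[tuple[str, str]]]:
    """Collapse effectively duplicated feature columns.

    A single greedy pass over feature pairs in column order removes one
    randomly chosen member of every surviving pair whose absolute Pearson
    correlation exceeds ``cutoff``. Returns the reduced table and a log of
    ``(kept, removed)`` name pairs.

    The table must already be free of missing values and constant columns
    (run :func:`drop_unusable_features` first).
    """
    if table.n_features < 2:
        raise ConfigurationError("need at least 2 features")
    if not 0.0 < cutoff <= 1.0:
        raise ConfigurationError("cutoff must lie in (0, 1]")
    if np.isnan(table.X).any():
        raise ConfigurationError("missing values present; clean the table first")
    if (table.X.max(axis=0) == table.X.min(axis=0)).any():
        raise ConfigurationError("zero-variance column present; clean the table first")

    rng = np.random.default_rng(seed)
    corr = np.corrcoef(table.X, rowvar=False)
    n = table.n_features
    alive = np.ones(n, dtype=bool)
    log: list[tuple[str, str]] = []
    for i in range(n):
        if not alive[i]:
            continue
        for j in range(i + 1, n):
            if not (alive[i] and alive[j]):
                continue
            if abs(corr[i, j]) > cutoff:
                removed = (i, j)[int(rng.integers(2))]
                kept = j if removed == i else i
                alive[removed] = False
                log.append((table.feature_names[kept], table.feature_names[removed]))
            if not alive[i]:
                break
    return table.take_features(np.flatnonzero(alive)), log


def _standardized(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mu) / sd


def kennard_stone_split(
    table: FeatureTable,
    n_train: int,
    standardize: bool = True,
) -> SplitResult:
    """Kennard-Stone maximin selection of a representative training set.

    The first training point minimizes the Euclidean distance to the
    feature-space centroid; every further point maximizes the minimum
    distance to the points already selected. Ties go to the lowest row
    index, making the split deterministic. The target is never used.

    Distances are computed on z-scored features by default (descriptor
    scales routinely span orders of magnitude); pass ``standardize=False``
    for raw-space distances.
    """
    n = table.n_samples
    if not 1 <= n_train < n:
        raise ConfigurationError(f"n_train must lie in [1, {n - 1}]")
    Z = _standardized(table.X) if standardize else np.asarray(table.X, dtype=float)

    centroid = Z.mean(axis=0)
    d2_centroid = ((Z - centroid) ** 2).sum(axis=1)
    first = int(np.argmin(d2_centroid))

    selected = [first]
    # running minimum squared distance from each sample to the selected set
    min_d2 = ((Z - Z[first]) ** 2).sum(axis=1)
    min_d2[first] = -np.inf
    for _ in range(n_train - 1):
        nxt = int(np.argmax(min_d2))
        selected.append(nxt)
        d2 = ((Z - Z[nxt]) ** 2).sum(axis=1)
        np.minimum(min_d2, d2, out=min_d2)
        min_d2[nxt] = -np.inf

    chosen = set(selected)
    test = tuple(i for i in range(n) if i not in chosen)
    return SplitResult(train_indices=tuple(selected), test_indices=test)


def take_samples(table: FeatureTable, indices: Sequence[int]) -> FeatureTable:
    """Return a table restricted to the given sample rows (in the given order)."""
    idx = [int(i) for i in indices]
    for i in idx:
        if not 0 <= i < table.n_samples:
            raise ValidationError(f"sample index {i} out of range")
    return FeatureTable(
        sample_ids=tuple(table.sample_ids[i] for i in idx),
        feature_names=table.feature_names,
        X=table.X[idx],
        y=table.y[idx],
    )
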