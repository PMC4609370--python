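"""Synthetic QSAR-like feature tables with known ground truth.

Real descriptor matrices for log BB modelling are produced by proprietary
quantum-chemistry and physicochemistry software, so they cannot ship with
the package. This module generates tables that reproduce the *structure*
such software emits — a few hundred samples by a few hundred columns,
continuous descriptors whose scales span orders of magnitude, binary
indicator columns, blocks of (near-)identical descriptors, constant
columns — together with a continuous target driven by a small known set of
informative features. Every other module is tested against these planted
truths.

Column layout is deterministic given the spec: binary indicator columns
occupy the lowest indices, near-duplicate copies and constant columns sit
at the highest indices, and everything in between is an independent
continuous descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datakit import FeatureTable
from .errors import ConfigurationError

__all__ = [
    "DuplicateBlock",
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "with_relative_noise",
    "paper_shaped_spec",
    "recovery_spec",
]


@dataclass(frozen=True)
class DuplicateBlock:
    """A block of ``copies`` mutually (near-)identical columns.

    ``source`` is an ordinary continuous column; ``copies - 1`` extra
    columns equal to it plus Gaussian jitter of sd ``jitter_sd`` are planted
    at the high end of the column range. With zero jitter the block is
    byte-identical, so near-duplicate cleaning removes exactly
    ``copies - 1`` columns per block.
    """

    source: int
    copies: int
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.copies < 2:
            raise ConfigurationError("a duplicate block needs copies >= 2")
        if self.jitter_sd < 0:
            raise ConfigurationError("jitter_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic table; the seed fixes everything."""

    n_samples: int
    n_features: int
    informative_indices: tuple[int, ...]
    effect_sizes: tuple[float, ...]
    n_binary_indicators: int = 0
    duplicate_blocks: tuple[DuplicateBlock, ...] = ()
    n_constant: int = 0
    noise_sd: float = 0.0
    nonlinear: bool = False
    seed: int = 0

    @property
    def n_duplicate_extras(self) -> int:
        return sum(b.copies - 1 for b in self.duplicate_blocks)

    @property
    def special_tail_start(self) -> int:
        """First column index of the planted duplicate/constant tail."""
        return self.n_features - self.n_constant - self.n_duplicate_extras

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_features < 1:
            raise ConfigurationError("need at least 2 samples and 1 feature")
        if len(self.informative_indices) != len(self.effect_sizes):
            raise ConfigurationError("one effect size per informative index required")
        if self.n_binary_indicators + self.n_duplicate_extras + self.n_constant > self.n_features:
            raise ConfigurationError("special columns exceed n_features")
        tail = self.special_tail_start
        for i in self.informative_indices:
            if not 0 <= i < self.n_features:
                raise ConfigurationError(f"informative index {i} out of range")
            if i >= tail:
                raise ConfigurationError("informative features cannot be planted duplicates/constants")
        if len(set(self.informative_indices)) != len(self.informative_indices):
            raise ConfigurationError("informative indices must be distinct")
        for b in self.duplicate_blocks:
            if not 0 <= b.source < tail:
                raise ConfigurationError("duplicate source must be a regular column")
        if self.n_binary_indicators > 0:
            has_neg_binary = any(
                i < self.n_binary_indicators and e < 0
                for i, e in zip(self.informative_indices, self.effect_sizes)
            )
            if not has_neg_binary:
                raise ConfigurationError(
                    "at least one binary indicator must be informative with a negative effect"
                )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Enough state to recompute the noiseless target exactly from X."""

    informative_indices: tuple[int, ...]
    effect_sizes: tuple[float, ...]
    centers: tuple[float, ...]
    scales: tuple[float, ...]
    nonlinear: bool
    noise_sd: float
    signal_sd: float
    description: str

    def noiseless_target(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        z = [
            (X[:, i] - c) / s
            for i, c, s in zip(self.informative_indices, self.centers, self.scales)
        ]
        y = np.zeros(X.shape[0])
        for e, zi in zip(self.effect_sizes, z):
            y = y + e * zi
        if self.nonlinear and len(z) >= 2:
            y = y + 0.5 * z[0] * z[1]
        return y


def generate(spec: SyntheticSpec) -> tuple[FeatureTable, GroundTruth]:
    """Draw a feature table and its ground truth from the spec.

    Continuous columns are Gaussian with per-column location and scale,
    the scale log-uniform over four orders of magnitude (raw descriptor
    matrices mix counts, areas and energies, so standardization has to
    matter). Binary indicators are Bernoulli with moderate prevalence.
    The target is a linear combination of the informative columns'
    z-scores (binary indicators enter raw, as 0/1 shifts), optionally plus
    a smooth two-feature interaction, plus Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    n, N = spec.n_samples, spec.n_features
    n_bin = spec.n_binary_indicators
    tail = spec.special_tail_start
    dup_start = tail
    const_start = N - spec.n_constant

    X = np.empty((n, N))
    names: list[str] = []
    for j in range(n_bin):
        p = rng.uniform(0.1, 0.5)
        X[:, j] = rng.binomial(1, p, size=n).astype(float)
        names.append(f"ind{j:03d}")
    for j in range(n_bin, tail):
        scale = 10.0 ** rng.uniform(-2.0, 2.0)
        loc = rng.uniform(-1.0, 1.0) * scale
        X[:, j] = rng.normal(loc, scale, size=n)
        names.append(f"x{j:03d}")
    j = dup_start
    for block in spec.duplicate_blocks:
        for _ in range(block.copies - 1):
            X[:, j] = X[:, block.source] + rng.normal(0.0, block.jitter_sd, size=n)
            names.append(f"dup{j:03d}_of_{block.source:03d}")
            j += 1
    for j in range(const_start, N):
        X[:, j] = rng.uniform(-1.0, 1.0)
        names.append(f"const{j:03d}")

    centers, scales = [], []
    for i in spec.informative_indices:
        if i < n_bin:
            centers.append(0.0)
            scales.append(1.0)
        else:
            centers.append(float(X[:, i].mean()))
            scales.append(float(X[:, i].std()))
    truth = GroundTruth(
        informative_indices=tuple(spec.informative_indices),
        effect_sizes=tuple(float(e) for e in spec.effect_sizes),
        centers=tuple(centers),
        scales=tuple(scales),
        nonlinear=spec.nonlinear,
        noise_sd=float(spec.noise_sd),
        signal_sd=0.0,  # filled below
        description=(
            "linear combination of z-scored informative columns "
            "(binary indicators raw)"
            + (" plus 0.5*z1*z2 interaction" if spec.nonlinear else "")
            + f" plus N(0, {spec.noise_sd}) noise"
        ),
    )
    y0 = truth.noiseless_target(X)
    truth = replace(truth, signal_sd=float(y0.std()))
    y = y0 + rng.normal(0.0, spec.noise_sd, size=n)

    table = FeatureTable(
        sample_ids=tuple(f"s{i:04d}" for i in range(n)),
        feature_names=tuple(names),
        X=X,
        y=y,
    )
    return table, truth


def with_relative_noise(spec: SyntheticSpec, fraction: float) -> SyntheticSpec:
    """Return the spec with noise_sd set to ``fraction`` of the signal sd.

    The noise draw happens after all feature draws, so the calibration
    generation and the final generation share identical X and noiseless
    target for the same seed.
    """
    _, truth = generate(replace(spec, noise_sd=0.0))
    return replace(spec, noise_sd=float(fraction * truth.signal_sd))


def paper_shaped_spec(seed: int = 0) -> SyntheticSpec:
    """A spec matching the geometry of the published log BB descriptor set.

    323 samples by 326 features; two binary indicator columns (a
    carboxylic-acid-like flag with a negative effect and an assay-type
    flag); six informative features in total, one positive
    (lipophilicity-like) and the rest negative (PSA/H-bonding-like);
    three zero-jitter duplicate blocks (4 planted extra columns) and three
    constant columns, so cleaning removes exactly 7 columns. A
    Kennard-Stone split with 260 training points then leaves 63 test
    points.
    """
    return SyntheticSpec(
        n_samples=323,
        n_features=326,
        informative_indices=(0, 2, 3, 4, 5, 6),
        effect_sizes=(-1.0, 1.0, -0.8, -0.8, -0.6, -0.5),
        n_binary_indicators=2,
        duplicate_blocks=(
            DuplicateBlock(source=10, copies=3),
            DuplicateBlock(source=20, copies=2),
            DuplicateBlock(source=30, copies=2),
        ),
        n_constant=3,
        noise_sd=0.3,
        nonlinear=False,
        seed=seed,
    )


def recovery_spec(seed: int = 0, noise_fraction: float = 0.1) -> SyntheticSpec:
    """The 200 x 30 feature-recovery benchmark.

    Three informative features — one negative binary indicator and two
    continuous descriptors of opposite sign — among 27 pure-noise columns;
    target noise calibrated to ``noise_fraction`` of the signal sd.
    """
    base = SyntheticSpec(
        n_samples=200,
        n_features=30,
        informative_indices=(0, 5, 12),
        effect_sizes=(-1.0, 1.0, -0.7),
        n_binary_indicators=1,
        noise_sd=0.0,
        seed=seed,
    )
    return with_relative_noise(base, noise_fraction)
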