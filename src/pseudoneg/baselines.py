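"""Classical resampling baselines: SMOTE, random over- and under-sampling.

These are the comparators the pseudo-negative selectors are judged against.
SMOTE creates synthetic minority samples by interpolating along the segment
between a minority sample and one of its k nearest minority neighbors
(Euclidean on raw features, k=5 by default): s = x + g*(x_nn - x) with g
uniform on [0, 1]. ROS duplicates uniformly drawn minority rows; RUS
removes uniformly drawn majority rows. All three are seeded and
reproducible, never modify existing rows, and preserve feature
dimensionality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .core import LabeledDataset
from .exceptions import ConfigError

__all__ = [
    "BaselineConfig",
    "resolve_amount",
    "smote",
    "random_oversample",
    "random_undersample",
    "apply_baseline",
]


@dataclass(frozen=True)
class BaselineConfig:
    """Configuration for a classical resampling baseline.

    ``amount`` is an absolute number of synthetic / duplicated / removed
    samples; alternatively ``percentage`` uses the same base semantics as
    pseudo-negative selection (percentage of the positive count by default).
    """

    method: Literal["smote", "ros", "rus"] = "smote"
    k_neighbors: int = 5
    amount: int | None = None
    percentage: float | None = None
    percentage_base: Literal["positives", "negatives"] = "positives"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.amount is None) == (self.percentage is None):
            raise ConfigError("exactly one of 'amount' and 'percentage' must be set")
        if self.amount is not None and self.amount < 0:
            raise ConfigError(f"amount must be nonnegative, got {self.amount}")
        if self.percentage is not None and not (0 <= self.percentage <= 100):
            raise ConfigError(f"percentage must be in [0, 100], got {self.percentage}")
        if self.k_neighbors < 1:
            raise ConfigError("k_neighbors must be >= 1")
        if self.method not in ("smote", "ros", "rus"):
            raise ConfigError(f"unknown method {self.method!r}")


def resolve_amount(config: BaselineConfig, dataset: LabeledDataset) -> int:
    """Resolve amount/percentage to an absolute count (half-up rounding)."""
    if config.amount is not None:
        return config.amount
    base = dataset.m if config.percentage_base == "positives" else dataset.n
    return int(math.floor(config.percentage / 100.0 * base + 0.5))


def _append(dataset: LabeledDataset, rows: np.ndarray, positive: bool) -> LabeledDataset:
    n_new = rows.shape[0]
    new_ids = np.arange(dataset.n_samples, dataset.n_samples + n_new)
    # synthetic/duplicated rows get fresh ids so provenance stays traceable
    return LabeledDataset(
        features=np.vstack([dataset.features, rows]),
        labels=np.concatenate([dataset.labels, np.full(n_new, positive)]),
        feature_names=dataset.feature_names,
        ids=np.concatenate([dataset.ids, new_ids]),
    )


def smote(dataset: LabeledDataset, config: BaselineConfig) -> LabeledDataset:
    """Append synthetic minority samples interpolated toward k-NN neighbors."""
    amount = resolve_amount(config, dataset)
    if amount == 0:
        return dataset
    k = config.k_neighbors
    if dataset.m < k + 1:
        raise ConfigError(
            f"SMOTE needs at least k_neighbors+1 = {k + 1} minority samples "
            f"(each sample needs {k} neighbors besides itself); got m = {dataset.m}"
        )
    rng = np.random.default_rng(config.seed)
    X_min = dataset.features[dataset.positive_indices]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neighbor_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]  # drop self
    base = rng.integers(0, X_min.shape[0], size=amount)
    pick = rng.integers(0, k, size=amount)
    gap = rng.uniform(0.0, 1.0, size=amount)
    x = X_min[base]
    x_nn = X_min[neighbor_idx[base, pick]]
    synth = x + gap[:, None] * (x_nn - x)
    return _append(dataset, synth, positive=True)


def random_oversample(dataset: LabeledDataset, config: BaselineConfig) -> LabeledDataset:
    """Append exact duplicates of uniformly drawn minority rows."""
    amount = resolve_amount(config, dataset)
    if amount == 0:
        return dataset
    rng = np.random.default_rng(config.seed)
    pos = dataset.positive_indices
    draws = rng.choice(pos, size=amount, replace=True)
    return _append(dataset, dataset.features[draws].copy(), positive=True)


def random_undersample(dataset: LabeledDataset, config: BaselineConfig) -> LabeledDataset:
    """Remove uniformly drawn majority rows (without replacement)."""
    amount = resolve_amount(config, dataset)
    if amount == 0:
        return dataset
    if amount > dataset.n:
        raise ConfigError(f"cannot remove {amount} majority rows; only {dataset.n} exist")
    rng = np.random.default_rng(config.seed)
    drop = set(rng.choice(dataset.negative_indices, size=amount, replace=False).tolist())
    keep = np.array([i for i in range(dataset.n_samples) if i not in drop])
    return dataset.subset(keep)


_BASELINES = {"smote": smote, "ros": random_oversample, "rus": random_undersample}


def apply_baseline(dataset: LabeledDataset, config: BaselineConfig) -> LabeledDataset:
    """Dispatch to the baseline named in ``config.method``."""
    return _BASELINES[config.method](dataset, config)
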