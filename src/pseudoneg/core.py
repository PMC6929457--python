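"""Data model and sample-similarity primitives.

The central object is :class:`LabeledDataset`: a numeric feature matrix with
one binary label per row, where the *positive* class is the minority class
of interest. Similarity between two samples is the Pearson correlation
coefficient (PCC) between their feature vectors,

    P(u, v) = cov(u, v) / sqrt(var(u) * var(v)),

computed across features. The *relevance* of a negative sample is its
correlation with the positive class: :func:`relevance_block` computes the
full n_negative x n_positive correlation block, and
:func:`aggregate_relevance` reduces it over the positive set (mean by
default) to one relevance score D_i per negative sample.

PCC is invariant to the population-vs-sample variance convention (the
normalizer cancels); the (n-1) sample convention is used internally.
Samples with zero feature variance make PCC undefined and are rejected
explicitly rather than silently scored 0, because a silent 0 would distort
argmax-based selection downstream.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .exceptions import ConfigError, DataValidationError, DegenerateSampleError

__all__ = [
    "LabeledDataset",
    "SimilarityBlock",
    "CorrelationCounter",
    "pearson",
    "relevance_block",
    "correlation_to_reference",
    "aggregate_relevance",
]

_VAR_TOL = 0.0  # exact zero spread rejects; near-constant rows are legitimate


class CorrelationCounter:
    """Counts pairwise Pearson evaluations for complexity accounting.

    The selection algorithms advertise a cost of at most ``n*m + n*l``
    correlation evaluations (relevance block plus one candidate column per
    selected sample); an instance of this class, threaded through the
    primitives, makes that bound assertable.
    """

    def __init__(self) -> None:
        self.count = 0

    def add(self, k: int) -> None:
        self.count += int(k)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CorrelationCounter(count={self.count})"


@dataclass
class LabeledDataset:
    """A binary-labeled numeric dataset; positive = minority class of interest.

    Parameters
    ----------
    features
        Real matrix of shape (n_samples, n_features); must be finite.
    labels
        Boolean vector, True for positive samples.
    feature_names
        Optional column identifiers.
    ids
        Optional stable per-row identifiers; preserved by subsetting so
        that provenance (e.g. which rows a sampler saw) stays auditable.
        Defaults to 0..n_samples-1.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] | None = None
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels)
        if labels.dtype != bool:
            uniq = set(np.unique(labels).tolist())
            if not uniq <= {0, 1, 0.0, 1.0, True, False}:
                raise DataValidationError(
                    f"labels must be binary; found values {sorted(uniq)!r}"
                )
            labels = labels.astype(bool)
        self.labels = labels
        if self.features.ndim != 2:
            raise DataValidationError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise DataValidationError(
                f"{self.features.shape[0]} feature rows but {self.labels.shape[0]} labels"
            )
        if not np.all(np.isfinite(self.features)):
            bad = np.argwhere(~np.isfinite(self.features))
            coords = [tuple(map(int, rc)) for rc in bad[:5]]
            raise DataValidationError(
                f"non-finite feature values at (row, column) {coords}"
                + ("..." if len(bad) > 5 else "")
            )
        if self.m < 1 or self.n < 1:
            raise DataValidationError(
                f"need at least one sample per class (positives={self.m}, negatives={self.n})"
            )
        if self.feature_names is not None and len(self.feature_names) != self.features.shape[1]:
            raise DataValidationError("feature_names length does not match feature count")
        if self.ids is None:
            self.ids = np.arange(self.features.shape[0])
        else:
            self.ids = np.asarray(self.ids)
            if self.ids.shape[0] != self.features.shape[0]:
                raise DataValidationError("ids length does not match sample count")

    # -- class bookkeeping -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def m(self) -> int:
        """Number of positive (minority) samples."""
        return int(self.labels.sum())

    @property
    def n(self) -> int:
        """Number of negative (majority) samples."""
        return int((~self.labels).sum())

    @property
    def positive_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels)

    @property
    def negative_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.labels)

    # -- validation --------------------------------------------------------
    def degenerate_rows(self) -> np.ndarray:
        """Indices of zero-variance sample rows (PCC undefined for these)."""
        return np.flatnonzero(self.features.std(axis=1) <= _VAR_TOL)

    def check_variance(self) -> None:
        rows = self.degenerate_rows()
        if rows.size:
            raise DegenerateSampleError(rows.tolist())

    def drop_degenerate(self) -> "LabeledDataset":
        """Return a copy without zero-variance rows (explicit opt-in)."""
        keep = self.features.std(axis=1) > _VAR_TOL
        return self.subset(np.flatnonzero(keep))

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            feature_names=self.feature_names,
            ids=self.ids[idx],
        )

    def with_labels(self, labels: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            features=self.features,
            labels=labels,
            feature_names=self.feature_names,
            ids=self.ids,
        )

    def fingerprint(self) -> str:
        """Content hash of features+labels, for integrity checks."""
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(self.features).tobytes())
        h.update(np.ascontiguousarray(self.labels).tobytes())
        return h.hexdigest()


@dataclass
class SimilarityBlock:
    """A block of pairwise sample correlations.

    ``values[i, j]`` is the Pearson correlation between the feature vector of
    the sample at ``row_index[i]`` and the one at ``col_index[j]`` in the
    parent dataset; every entry lies in [-1, 1] up to numeric tolerance.
    """

    values: np.ndarray
    row_index: np.ndarray
    col_index: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_index = np.asarray(self.row_index, dtype=int)
        self.col_index = np.asarray(self.col_index, dtype=int)


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation coefficient between two feature vectors.

    Raises
    ------
    DataValidationError
        If the vectors differ in length or are shorter than 2.
    DegenerateSampleError
        If either vector has zero variance.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise DataValidationError(f"length mismatch: {u.shape[0]} vs {v.shape[0]}")
    if u.shape[0] < 2:
        raise DataValidationError("need at least 2 entries to correlate")
    uc = u - u.mean()
    vc = v - v.mean()
    nu = float(np.dot(uc, uc))
    nv = float(np.dot(vc, vc))
    bad = [i for i, s in enumerate((nu, nv)) if s <= _VAR_TOL]
    if bad:
        raise DegenerateSampleError(bad, "zero-variance input vector(s): " + str(bad))
    r = float(np.dot(uc, vc) / np.sqrt(nu * nv))
    # clip pure floating-point overshoot
    return float(min(1.0, max(-1.0, r)))


def _zscore_rows(x: np.ndarray, *, index_offset_rows: Sequence[int] | None = None) -> np.ndarray:
    """Row-standardize so that correlation becomes a dot product / f."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() <= _VAR_TOL)
    if bad.size:
        rows = bad if index_offset_rows is None else [index_offset_rows[i] for i in bad]
        raise DegenerateSampleError(list(map(int, rows)))
    return (x - mu) / sd


def correlation_to_reference(
    dataset: LabeledDataset,
    candidate_rows: np.ndarray,
    reference_rows: np.ndarray,
    counter: CorrelationCounter | None = None,
) -> SimilarityBlock:
    """Pairwise Pearson block between two row sets of the same dataset.

    Computed as a matrix product of row-standardized features; numerically
    identical (to ~1e-15) to looping :func:`pearson` over all pairs, which
    the test suite uses as the oracle.
    """
    cand = np.asarray(candidate_rows, dtype=int)
    ref = np.asarray(reference_rows, dtype=int)
    zc = _zscore_rows(dataset.features[cand], index_offset_rows=cand.tolist())
    zr = _zscore_rows(dataset.features[ref], index_offset_rows=ref.tolist())
    vals = zc @ zr.T / dataset.n_features
    np.clip(vals, -1.0, 1.0, out=vals)
    if counter is not None:
        counter.add(cand.size * ref.size)
    return SimilarityBlock(values=vals, row_index=cand, col_index=ref)


def relevance_block(
    dataset: LabeledDataset, counter: CorrelationCounter | None = None
) -> SimilarityBlock:
    """Correlation of every negative sample with every positive sample.

    The returned block has shape (n_negatives, n_positives); entry (i, j) is
    P(negative_i, positive_j). Costs exactly n*m pairwise correlation
    evaluations in the instrumented accounting.
    """
    return correlation_to_reference(
        dataset, dataset.negative_indices, dataset.positive_indices, counter=counter
    )


def aggregate_relevance(
    block: SimilarityBlock, mode: Literal["mean", "max"] = "mean"
) -> np.ndarray:
    """Reduce a relevance block over the positive set to one D_i per negative.

    ``mean`` (default) averages the correlations to all positives; ``max``
    takes the single best-matched positive.
    """
    if block.values.size == 0:
        raise DataValidationError("cannot aggregate an empty similarity block")
    if mode == "mean":
        return block.values.mean(axis=1)
    if mode == "max":
        return block.values.max(axis=1)
    raise ConfigError(f"unknown aggregation mode {mode!r}; expected 'mean' or 'max'")
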