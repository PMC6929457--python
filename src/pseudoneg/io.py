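"""Dataset readers/writers, descriptors, and the PSSM window featurizer.

Datasets travel as delimited text (CSV/TSV, header row, one row per
sample): numeric feature columns plus one binary label column. The
descriptor mirrors the conventional summary table for imbalanced
benchmarks — class counts, attribute count, and the imbalance ratio
negatives/positives displayed to one decimal (half-up).

For protein residue data, a position-specific scoring matrix (PSSM) gives
20 conservation scores per residue; the featurizer turns each residue into
one sample by flattening the scores of a window of consecutive residues
centered on it (window 9 -> 9*20 = 180 features), zero-padding past the
sequence ends. Producing PSSMs (e.g. by PSI-BLAST against a reference
database) is upstream of this package; scores are consumed as given, with
an optional logistic rescale for raw log-odds input.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
import warnings

import numpy as np
import pandas as pd

from .core import LabeledDataset
from .exceptions import ConfigError, DataValidationError

__all__ = [
    "DatasetDescriptor",
    "ResidueProfile",
    "read_dataset",
    "write_dataset",
    "describe",
    "read_profile",
    "pssm_window_features",
]

_POSITIVE_CONVENTIONS = {"1", "1.0", "true", "positive", "pos", "+", "yes"}
_NEGATIVE_CONVENTIONS = {"0", "0.0", "false", "negative", "neg", "-", "no"}


@dataclass(frozen=True)
class DatasetDescriptor:
    """Summary of an imbalanced dataset: counts and the imbalance ratio."""

    name: str
    positives: int
    negatives: int
    attributes: int

    @property
    def ratio(self) -> float:
        """negatives/positives, displayed to one decimal, half-up."""
        exact = Decimal(self.negatives) / Decimal(self.positives)
        return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))

    @classmethod
    def from_counts(
        cls, name: str, positives: int, negatives: int, attributes: int
    ) -> "DatasetDescriptor":
        if min(positives, negatives, attributes) < 1:
            raise ConfigError("positives, negatives and attributes must all be >= 1")
        return cls(name, positives, negatives, attributes)

    def __str__(self) -> str:
        return (
            f"{self.name}: {self.positives} positive / {self.negatives} negative, "
            f"{self.attributes} attributes, ratio {self.ratio}"
        )


def describe(dataset: LabeledDataset, name: str = "dataset") -> DatasetDescriptor:
    return DatasetDescriptor.from_counts(name, dataset.m, dataset.n, dataset.n_features)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_dataset(
    path,
    label_column: str = "label",
    positive_label: str | int | None = None,
) -> LabeledDataset:
    """Load a delimited labeled dataset, validating features and labels.

    Labels must take exactly two values; ``positive_label`` picks the
    positive one explicitly, otherwise common conventions (1/0,
    positive/negative, +/-, yes/no, true/false) are recognized. A warning
    is issued when the positive class is the majority, since the methods
    here assume minority positives.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if label_column not in df.columns:
        raise DataValidationError(
            f"label column {label_column!r} not in {list(df.columns)}"
        )
    raw_labels = df[label_column]
    feat = df.drop(columns=[label_column])
    numeric = feat.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~feat.isna()
    if bad.any().any():
        r, c = next(zip(*np.where(bad.values)))
        raise DataValidationError(
            f"non-numeric feature cell at row {int(r)}, column {feat.columns[int(c)]!r}: "
            f"{feat.iloc[int(r), int(c)]!r}"
        )
    if numeric.isna().any().any():
        r, c = next(zip(*np.where(numeric.isna().values)))
        raise DataValidationError(
            f"missing feature value at row {int(r)}, column {feat.columns[int(c)]!r}"
        )

    values = [str(v).strip().lower() for v in raw_labels]
    uniq = sorted(set(values))
    if len(uniq) != 2:
        raise DataValidationError(
            f"label column must take exactly two values; found {uniq}"
        )
    if positive_label is not None:
        pos_key = str(positive_label).strip().lower()
        if pos_key not in uniq:
            raise DataValidationError(
                f"positive label {positive_label!r} not among label values {uniq}"
            )
    else:
        pos_matches = [v for v in uniq if v in _POSITIVE_CONVENTIONS]
        neg_matches = [v for v in uniq if v in _NEGATIVE_CONVENTIONS]
        if len(pos_matches) == 1 and len(neg_matches) == 1:
            pos_key = pos_matches[0]
        else:
            raise DataValidationError(
                f"cannot infer the positive class from label values {uniq}; "
                "pass positive_label explicitly"
            )
    labels = np.array([v == pos_key for v in values])
    dataset = LabeledDataset(
        features=numeric.to_numpy(dtype=float),
        labels=labels,
        feature_names=list(feat.columns),
    )
    if dataset.m > dataset.n:
        warnings.warn(
            f"positive class is the majority ({dataset.m} vs {dataset.n}); "
            "these methods assume minority positives",
            stacklevel=2,
        )
    return dataset


def write_dataset(dataset: LabeledDataset, path, label_column: str = "label") -> None:
    path = Path(path)
    names = dataset.feature_names or [f"x{j}" for j in range(dataset.n_features)]
    df = pd.DataFrame(dataset.features, columns=names)
    df[label_column] = dataset.labels.astype(int)
    df.to_csv(path, sep=_sep_for(path), index=False)


# --------------------------------------------------------------------------
# PSSM windows
# --------------------------------------------------------------------------

@dataclass
class ResidueProfile:
    """Per-residue PSSM scores (n_residues x 20) with binding labels."""

    scores: np.ndarray
    labels: np.ndarray
    sequence_id: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels).astype(bool)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise DataValidationError(
                f"PSSM scores must have exactly 20 columns; got shape {self.scores.shape}"
            )
        if self.labels.shape[0] != self.scores.shape[0]:
            raise DataValidationError("labels length must equal the number of residues")

    @property
    def n_residues(self) -> int:
        return self.scores.shape[0]


def read_profile(
    scores_path, labels_path=None, label_column: str | None = None, sequence_id: str = ""
) -> ResidueProfile:
    """Read a PSSM score table (20 columns, one row per residue).

    Labels come either from ``label_column`` inside the same file or from a
    one-column ``labels_path`` sidecar.
    """
    scores_path = Path(scores_path)
    df = pd.read_csv(scores_path, sep=_sep_for(scores_path))
    if label_column is not None:
        if label_column not in df.columns:
            raise DataValidationError(f"label column {label_column!r} not found")
        labels = df[label_column].to_numpy()
        df = df.drop(columns=[label_column])
    elif labels_path is not None:
        labels = pd.read_csv(labels_path, header=None).to_numpy().ravel()
    else:
        raise ConfigError("provide label_column or labels_path")
    return ResidueProfile(
        scores=df.to_numpy(dtype=float), labels=labels, sequence_id=sequence_id
    )


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def pssm_window_features(
    profile: ResidueProfile,
    window: int = 9,
    rescale: str = "none",
) -> LabeledDataset:
    """One sample per residue: the window x 20 scores centered on it.

    Scores of positions past either sequence end are zero. ``rescale``
    may be 'logistic' to squash raw log-odds scores to (0, 1) first.
    The default window of 9 residues gives 9*20 = 180 features.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigError(f"window must be a positive odd integer, got {window}")
    if rescale not in ("none", "logistic"):
        raise ConfigError(f"unknown rescale {rescale!r}; expected 'none' or 'logistic'")
    scores = _logistic(profile.scores) if rescale == "logistic" else profile.scores
    half = window // 2
    n, w = profile.n_residues, window
    padded = np.vstack([np.zeros((half, 20)), scores, np.zeros((half, 20))])
    feats = np.stack([padded[i : i + w].ravel() for i in range(n)])
    names = [
        f"w{off:+d}_s{j}" for off in range(-half, half + 1) for j in range(20)
    ]
    return LabeledDataset(features=feats, labels=profile.labels, feature_names=names)
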