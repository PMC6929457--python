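"""Metrics, the cross-validation harness, and the classifier registry.

Four metrics summarize a binary confusion matrix, with the positive class
fixed to the original minority class:

    Sen = TP / (TP + FN)
    Spe = TN / (TN + FP)
    Acc = (TP + TN) / (TP + FN + TN + FP)
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP))

Zero-denominator conventions: Sen/Spe with an empty class are reported as
NaN, flagged, and excluded from fold means; MCC with any zero factor is 0
(the standard convention). Sensitivity is the headline metric under class
imbalance — raw accuracy is dominated by the majority class.

The harness runs seeded stratified k-fold cross-validation (k=5 by
default) with resampling applied *inside* each training fold by default
(``sample_scope='train_folds'``), so no test-fold row is ever visible to
the sampler; the whole-dataset variant is available for protocol
comparison but leaks the test distribution into sampling. Test folds are
always scored against the ORIGINAL labels: pseudo-negativity is a training
construct, and a relabeled sample that lands in a test fold is still
evaluated as the negative it was originally labeled.

Classifiers are delegated to scikit-learn behind a small registry keyed by
the conventional short names: ``da`` (linear discriminant analysis),
``rf`` (random forest), ``nn`` (multilayer perceptron), ``adaboost``
(AdaBoost over decision stumps; its decision is the sign of the weighted
sum of weak-learner votes). Backend defaults are kept except where noted
in the registry table; each handle is seeded from the harness seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .baselines import BaselineConfig, apply_baseline
from .core import LabeledDataset
from .exceptions import ConfigError, DataValidationError
from .selection import SamplerConfig, relabel, select

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "sen",
    "spe",
    "acc",
    "mcc",
    "classifier_registry",
    "make_sampler",
    "cross_validate",
    "percentage_sweep",
]


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise DataValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Confusion counts with positive = the original minority class."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise DataValidationError(f"length mismatch: {yt.shape} vs {yp.shape}")
    for name, v in (("y_true", yt), ("y_pred", yp)):
        if not set(np.unique(v).tolist()) <= {0, 1, True, False}:
            raise DataValidationError(f"{name} must be binary")
    yt = yt.astype(bool)
    yp = yp.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(yt & yp)),
        tn=int(np.sum(~yt & ~yp)),
        fp=int(np.sum(~yt & yp)),
        fn=int(np.sum(yt & ~yp)),
    )


def sen(counts: ConfusionCounts) -> float:
    """Sensitivity TP/(TP+FN); NaN when there are no positives."""
    d = counts.tp + counts.fn
    return counts.tp / d if d else float("nan")


def spe(counts: ConfusionCounts) -> float:
    """Specificity TN/(TN+FP); NaN when there are no negatives."""
    d = counts.tn + counts.fp
    return counts.tn / d if d else float("nan")


def acc(counts: ConfusionCounts) -> float:
    if counts.total == 0:
        raise DataValidationError("empty confusion table")
    return (counts.tp + counts.tn) / counts.total


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    if denom == 0:
        return 0.0
    return (tp * tn - fn * fp) / math.sqrt(denom)


# --------------------------------------------------------------------------
# Classifier registry
# --------------------------------------------------------------------------

class ClassifierRegistry:
    """Maps the conventional short names to seeded scikit-learn factories."""

    def __init__(self) -> None:
        self._factories: dict[str, Callable] = {}

    def register(self, name: str, factory: Callable) -> None:
        self._factories[name.lower()] = factory

    @property
    def names(self) -> list[str]:
        return sorted(self._factories)

    def get(self, name: str, seed: int | None = None, **kwargs):
        key = name.lower()
        if key not in self._factories:
            raise ConfigError(
                f"unknown classifier {name!r}; registered: {', '.join(self.names)}"
            )
        return self._factories[key](seed=seed, **kwargs)


classifier_registry = ClassifierRegistry()
classifier_registry.register(
    "da", lambda seed=None, **kw: LinearDiscriminantAnalysis(**kw)
)
classifier_registry.register(
    "rf", lambda seed=None, **kw: RandomForestClassifier(random_state=seed, **kw)
)
# max_iter raised from the backend default so small-sample fits converge
classifier_registry.register(
    "nn",
    lambda seed=None, **kw: MLPClassifier(
        random_state=seed, **{"max_iter": 500, **kw}
    ),
)
classifier_registry.register(
    "adaboost",
    lambda seed=None, **kw: AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=1), random_state=seed, **kw
    ),
)


# --------------------------------------------------------------------------
# Samplers as train-fold transforms
# --------------------------------------------------------------------------

def make_sampler(
    config: SamplerConfig | BaselineConfig | None,
) -> Callable[[LabeledDataset, int], LabeledDataset] | None:
    """Turn a sampler configuration into a train-fold transform.

    The returned callable maps ``(training_dataset, seed) ->
    resampled_dataset``. Pseudo-negative selection is deterministic (the
    seed only updates the config echo); baselines are reseeded per fold.
    """
    if config is None:
        return None
    if isinstance(config, SamplerConfig):

        def _select(train: LabeledDataset, seed: int) -> LabeledDataset:
            from dataclasses import replace

            result = select(train, replace(config, seed=seed))
            return relabel(train, result)

        return _select
    if isinstance(config, BaselineConfig):

        def _baseline(train: LabeledDataset, seed: int) -> LabeledDataset:
            from dataclasses import replace

            return apply_baseline(train, replace(config, seed=seed))

        return _baseline
    raise ConfigError(f"unsupported sampler config type {type(config).__name__}")


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------

_METRICS = {"Sen": sen, "Spe": spe, "Acc": acc, "MCC": mcc}


@dataclass
class MetricsReport:
    """Per-fold and aggregated Sen/Spe/Acc/MCC with their confusion counts.

    Aggregates are arithmetic means over folds; NaN fold metrics (empty
    class in a fold) are excluded from the mean and flagged.
    """

    per_fold: list[dict]
    aggregate: dict
    config: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, fold in enumerate(self.per_fold):
            row = {"fold": k}
            row.update({m: fold[m] for m in _METRICS})
            c = fold["counts"]
            row.update({"TP": c.tp, "TN": c.tn, "FP": c.fp, "FN": c.fn})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> dict:
        return {
            "per_fold": [
                {
                    **{m: fold[m] for m in _METRICS},
                    "counts": vars(fold["counts"]),
                }
                for fold in self.per_fold
            ],
            "aggregate": self.aggregate,
            "config": self.config,
        }


def _fold_metrics(counts: ConfusionCounts) -> dict:
    fold = {name: fn(counts) for name, fn in _METRICS.items()}
    fold["counts"] = counts
    return fold


def _aggregate(per_fold: list[dict]) -> dict:
    agg: dict = {}
    for name in _METRICS:
        vals = np.array([f[name] for f in per_fold], dtype=float)
        ok = ~np.isnan(vals)
        if not ok.all():
            warnings.warn(
                f"{name} undefined in {int((~ok).sum())} fold(s); excluded from mean",
                stacklevel=3,
            )
            agg.setdefault("flags", []).append(f"{name}_undefined_folds")
        agg[name] = float(vals[ok].mean()) if ok.any() else float("nan")
    return agg


def _standardizer(train_X: np.ndarray):
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0)
    sd[sd == 0] = 1.0
    return lambda X: (X - mu) / sd


def cross_validate(
    dataset: LabeledDataset,
    sampler: SamplerConfig | BaselineConfig | Callable | None = None,
    classifier: str | object = "rf",
    folds: int = 5,
    seed: int = 0,
    sample_scope: Literal["train_folds", "whole_dataset"] = "train_folds",
    standardize: bool = False,
    classifier_kwargs: dict | None = None,
) -> MetricsReport:
    """Stratified k-fold cross-validation with in-fold resampling.

    ``sampler`` may be a :class:`SamplerConfig`, a :class:`BaselineConfig`,
    a callable ``(train_dataset, seed) -> dataset``, or None (no
    resampling). ``classifier`` is a registry name or any object exposing
    ``fit``/``predict``. Under the default ``sample_scope='train_folds'``
    the sampler only ever sees training rows; ``'whole_dataset'``
    reproduces the leaky protocol in which sampling precedes the split
    (folds are still stratified on, and scored against, original labels).
    """
    if dataset.m < folds or dataset.n < folds:
        raise ConfigError(
            f"each class needs >= {folds} samples for {folds}-fold stratified CV "
            f"(m={dataset.m}, n={dataset.n})"
        )
    transform = sampler if callable(sampler) else make_sampler(sampler)
    if isinstance(classifier, str):
        clf_name = classifier
    else:
        clf_name = type(classifier).__name__

    original_labels = dataset.labels
    working = dataset
    if transform is not None and sample_scope == "whole_dataset":
        working = transform(dataset, seed)
        if working.n_samples != dataset.n_samples:
            # appended/removed rows change the index space; scoring against
            # original labels is only well-defined for relabel-style samplers
            raise ConfigError(
                "sample_scope='whole_dataset' requires a row-preserving "
                "(relabeling) sampler"
            )

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold = []
    for k, (train_idx, test_idx) in enumerate(
        skf.split(dataset.features, original_labels.astype(int))
    ):
        train = working.subset(train_idx)
        if transform is not None and sample_scope == "train_folds":
            train = transform(train, seed * 1000 + k)
        prep = _standardizer(train.features) if standardize else (lambda X: X)
        if isinstance(classifier, str):
            clf = classifier_registry.get(
                classifier, seed=seed * 1000 + k, **(classifier_kwargs or {})
            )
        else:
            clf = classifier
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter on tiny folds
            clf.fit(prep(train.features), train.labels.astype(int))
            y_pred = np.asarray(clf.predict(prep(dataset.features[test_idx])))
        counts = confusion_counts(original_labels[test_idx].astype(int), y_pred)
        per_fold.append(_fold_metrics(counts))
    return MetricsReport(
        per_fold=per_fold,
        aggregate=_aggregate(per_fold),
        config={
            "classifier": clf_name,
            "folds": folds,
            "seed": seed,
            "sample_scope": sample_scope,
            "standardize": standardize,
            "sampler": _describe_sampler(sampler),
        },
    )


def _describe_sampler(sampler) -> str | dict | None:
    if sampler is None:
        return None
    if isinstance(sampler, (SamplerConfig, BaselineConfig)):
        return {k: v for k, v in vars(sampler).items()}
    return getattr(sampler, "__name__", repr(sampler))


def percentage_sweep(
    dataset: LabeledDataset,
    method: str = "mmpcc",
    classifiers: Sequence[str] = ("rf",),
    percentages: Sequence[float] = (0, 10, 20, 30, 40, 50),
    folds: int = 5,
    seed: int = 0,
    percentage_base: Literal["positives", "negatives"] = "positives",
    sample_scope: Literal["train_folds", "whole_dataset"] = "train_folds",
    standardize: bool = False,
) -> pd.DataFrame:
    """Run cross-validation across a grid of sampling percentages.

    Percentage 0 means no resampling at all. ``method`` may be any selector
    ('mmpcc', 'maxr', 'minr') or baseline ('smote', 'ros', 'rus'). Returns
    one row per (percentage, classifier) with mean Sen/Spe/Acc (as
    percentages, mirroring how such tables are conventionally printed) and
    MCC on its natural [-1, 1] scale; the full reports are attached in a
    ``report`` column.
    """
    rows = []
    for pct in percentages:
        if pct == 0:
            sampler: SamplerConfig | BaselineConfig | None = None
        elif method in ("mmpcc", "maxr", "minr"):
            sampler = SamplerConfig(
                method=method, percentage=pct, percentage_base=percentage_base
            )
        elif method in ("smote", "ros", "rus"):
            sampler = BaselineConfig(
                method=method, percentage=pct, percentage_base=percentage_base
            )
        else:
            raise ConfigError(f"unknown sampling method {method!r}")
        for clf in classifiers:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = cross_validate(
                    dataset,
                    sampler=sampler,
                    classifier=clf,
                    folds=folds,
                    seed=seed,
                    sample_scope=sample_scope,
                    standardize=standardize,
                )
            rows.append(
                {
                    "percentage": pct,
                    "method": method if pct else "none",
                    "classifier": clf,
                    "Sen%": 100 * report.aggregate["Sen"],
                    "Spe%": 100 * report.aggregate["Spe"],
                    "Acc%": 100 * report.aggregate["Acc"],
                    "MCC": report.aggregate["MCC"],
                    "report": report,
                }
            )
    return pd.DataFrame(rows)
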