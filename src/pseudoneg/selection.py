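"""Greedy pseudo-negative selectors: MMPCC, MAXR and MINR.

A *pseudo-negative* is a sample carrying a negative label that the selector
judges to belong to the positive class: it is maximally correlated with the
positive set (max-relevance) while minimally correlated with the
pseudo-negatives already selected (min-redundancy). Selection is an
incremental forward search starting from the empty set. At step k, with
selected set S* of size k-1, each remaining negative candidate i is scored

    Psi_i = D_i - R_i,
    D_i   = aggregate_j P(neg_i, pos_j)          (relevance, mean over j by default)
    R_i   = (1/(k-1)) * sum_{s in S*} P(neg_i, s)  (redundancy; 0 when S* is empty)

and the argmax joins S*. MAXR is the relevance-only ablation (R == 0, i.e.
plain top-l ranking by D); MINR is the redundancy-only ablation (argmin R,
with the first pick minimizing mean correlation to all other negatives,
since R is undefined on an empty selected set). Ties in every argmax/argmin
are broken toward the lowest original sample index, making selection fully
deterministic.

The relevance block is computed once (n*m correlation evaluations) and the
redundancy sums are updated incrementally with one candidate-vs-selected
column per step (n per step, n*l total), so MMPCC costs at most n*m + n*l
pairwise correlations — the instrumented counter in the result makes the
bound checkable.

Selected samples are *relabeled* (moved to the positive class), not
duplicated: the method's premise is that they are unrecognized positives,
and duplication would let the same row count for both classes.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .core import (
    CorrelationCounter,
    LabeledDataset,
    aggregate_relevance,
    correlation_to_reference,
    pearson,
    relevance_block,
)
from .exceptions import ConfigError, IntegrityError

__all__ = [
    "SamplerConfig",
    "SelectionResult",
    "resolve_l",
    "select",
    "select_mmpcc",
    "select_maxr",
    "select_minr",
    "brute_force_step",
    "relabel",
]

Method = Literal["mmpcc", "maxr", "minr"]


@dataclass(frozen=True)
class SamplerConfig:
    """Configuration for pseudo-negative selection.

    Exactly one of ``l`` (absolute number of pseudo-negatives) or
    ``percentage`` must be given; a percentage is resolved against the
    positive count by default (``percentage_base='positives'``), the
    reading under which a 50% sweep keeps l < m. The number of
    pseudo-negatives is in principle chosen by a domain expert; the method
    assumes l < m and warns otherwise.

    ``seed`` does not affect selection (which is deterministic, ties broken
    by lowest sample index); it is carried for audit/echo purposes only.
    """

    method: Method = "mmpcc"
    l: int | None = None
    percentage: float | None = None
    percentage_base: Literal["positives", "negatives"] = "positives"
    aggregation: Literal["mean", "max"] = "mean"
    use_abs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.l is None) == (self.percentage is None):
            raise ConfigError("exactly one of 'l' and 'percentage' must be set")
        if self.l is not None and self.l < 0:
            raise ConfigError(f"l must be nonnegative, got {self.l}")
        if self.percentage is not None and not (0 <= self.percentage <= 100):
            raise ConfigError(f"percentage must be in [0, 100], got {self.percentage}")
        if self.method not in ("mmpcc", "maxr", "minr"):
            raise ConfigError(f"unknown method {self.method!r}")
        if self.percentage_base not in ("positives", "negatives"):
            raise ConfigError(f"unknown percentage_base {self.percentage_base!r}")


@dataclass
class SelectionResult:
    """Ordered pseudo-negative selection with per-step diagnostics.

    ``selected[k]`` is the dataset row index chosen at step k+1;
    ``d_scores``/``r_scores``/``psi_scores`` record the winning candidate's
    relevance, redundancy and Psi = D - R at each step.
    """

    selected: np.ndarray
    d_scores: np.ndarray
    r_scores: np.ndarray
    psi_scores: np.ndarray
    method: str
    config: SamplerConfig
    resolved_l: int
    correlation_evals: int
    dataset_fingerprint: str

    def __len__(self) -> int:
        return len(self.selected)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self.selected) + 1),
                "sample_index": self.selected,
                "D": self.d_scores,
                "R": self.r_scores,
                "Psi": self.psi_scores,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "method": self.method,
            "resolved_l": self.resolved_l,
            "selected": self.selected.tolist(),
            "d_scores": self.d_scores.tolist(),
            "r_scores": self.r_scores.tolist(),
            "psi_scores": self.psi_scores.tolist(),
            "correlation_evals": self.correlation_evals,
            "dataset_fingerprint": self.dataset_fingerprint,
            "config": {
                "method": self.config.method,
                "l": self.config.l,
                "percentage": self.config.percentage,
                "percentage_base": self.config.percentage_base,
                "aggregation": self.config.aggregation,
                "use_abs": self.config.use_abs,
                "seed": self.config.seed,
            },
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload


def resolve_l(config: SamplerConfig, dataset: LabeledDataset) -> int:
    """Resolve the configured l or percentage to an absolute count.

    A percentage is rounded half-up against the base class count and
    clamped to [0, n]. A warning is issued when l >= m (the method assumes
    fewer pseudo-negatives than true positives) and when a nonzero
    percentage resolves to 0.
    """
    if config.l is not None:
        l = config.l
    else:
        base = dataset.m if config.percentage_base == "positives" else dataset.n
        l = int(math.floor(config.percentage / 100.0 * base + 0.5))
        if l == 0 and config.percentage > 0:
            warnings.warn(
                f"percentage {config.percentage}% of {base} resolves to l=0 (no-op)",
                stacklevel=2,
            )
    l = max(0, min(l, dataset.n))
    if l >= dataset.m:
        warnings.warn(
            f"l={l} >= m={dataset.m}: the method assumes fewer pseudo-negatives "
            "than true positives (l < m)",
            stacklevel=2,
        )
    return l


def _relevance_scores(
    dataset: LabeledDataset, config: SamplerConfig, counter: CorrelationCounter
) -> np.ndarray:
    block = relevance_block(dataset, counter=counter)
    values = np.abs(block.values) if config.use_abs else block.values
    return aggregate_relevance(
        type(block)(values, block.row_index, block.col_index), config.aggregation
    )


def _candidate_column(
    dataset: LabeledDataset,
    neg_rows: np.ndarray,
    selected_row: int,
    config: SamplerConfig,
    counter: CorrelationCounter,
) -> np.ndarray:
    col = correlation_to_reference(
        dataset, neg_rows, np.array([selected_row]), counter=counter
    ).values.ravel()
    return np.abs(col) if config.use_abs else col


def _empty_result(dataset, config, method, counter) -> SelectionResult:
    z = np.zeros(0)
    return SelectionResult(
        selected=np.zeros(0, dtype=int),
        d_scores=z,
        r_scores=z.copy(),
        psi_scores=z.copy(),
        method=method,
        config=config,
        resolved_l=0,
        correlation_evals=counter.count if counter else 0,
        dataset_fingerprint=dataset.fingerprint(),
    )


def select_mmpcc(dataset: LabeledDataset, config: SamplerConfig) -> SelectionResult:
    """Greedy max-relevance min-redundancy selection (Psi = D - R)."""
    cfg = replace(config, method="mmpcc") if config.method != "mmpcc" else config
    counter = CorrelationCounter()
    l = resolve_l(cfg, dataset)
    if l == 0:
        return _empty_result(dataset, cfg, "mmpcc", counter)
    neg_rows = dataset.negative_indices
    D = _relevance_scores(dataset, cfg, counter)
    n = neg_rows.size
    redundancy_sum = np.zeros(n)
    available = np.ones(n, dtype=bool)
    sel_pos, sel_d, sel_r, sel_psi = [], [], [], []
    for k in range(1, l + 1):
        R = redundancy_sum / (k - 1) if k > 1 else np.zeros(n)
        psi = D - R
        psi_masked = np.where(available, psi, -np.inf)
        w = int(np.argmax(psi_masked))  # first max -> lowest index on ties
        available[w] = False
        sel_pos.append(int(neg_rows[w]))
        sel_d.append(float(D[w]))
        sel_r.append(float(R[w]))
        sel_psi.append(float(psi[w]))
        if k < l:
            redundancy_sum += _candidate_column(dataset, neg_rows, neg_rows[w], cfg, counter)
    return SelectionResult(
        selected=np.array(sel_pos),
        d_scores=np.array(sel_d),
        r_scores=np.array(sel_r),
        psi_scores=np.array(sel_psi),
        method="mmpcc",
        config=cfg,
        resolved_l=l,
        correlation_evals=counter.count,
        dataset_fingerprint=dataset.fingerprint(),
    )


def select_maxr(dataset: LabeledDataset, config: SamplerConfig) -> SelectionResult:
    """Relevance-only ablation: the l negatives with largest D, descending."""
    cfg = replace(config, method="maxr") if config.method != "maxr" else config
    counter = CorrelationCounter()
    l = resolve_l(cfg, dataset)
    if l == 0:
        return _empty_result(dataset, cfg, "maxr", counter)
    neg_rows = dataset.negative_indices
    D = _relevance_scores(dataset, cfg, counter)
    order = np.argsort(-D, kind="stable")[:l]  # stable -> lowest index on ties
    return SelectionResult(
        selected=neg_rows[order],
        d_scores=D[order],
        r_scores=np.zeros(l),
        psi_scores=D[order],
        method="maxr",
        config=cfg,
        resolved_l=l,
        correlation_evals=counter.count,
        dataset_fingerprint=dataset.fingerprint(),
    )


def select_minr(dataset: LabeledDataset, config: SamplerConfig) -> SelectionResult:
    """Redundancy-only ablation: incremental argmin of mean correlation.

    The first pick minimizes mean correlation to all *other* negatives (the
    redundancy criterion has no selected set to refer to yet); subsequent
    picks minimize mean correlation to the selected set.
    """
    cfg = replace(config, method="minr") if config.method != "minr" else config
    counter = CorrelationCounter()
    l = resolve_l(cfg, dataset)
    if l == 0:
        return _empty_result(dataset, cfg, "minr", counter)
    neg_rows = dataset.negative_indices
    n = neg_rows.size
    block = correlation_to_reference(dataset, neg_rows, neg_rows, counter=counter)
    nn = np.abs(block.values) if cfg.use_abs else block.values
    available = np.ones(n, dtype=bool)
    redundancy_sum = np.zeros(n)
    sel_pos, sel_r = [], []
    for k in range(1, l + 1):
        if k == 1:
            if n == 1:
                R = np.zeros(1)
            else:
                R = (nn.sum(axis=1) - np.diag(nn)) / (n - 1)
        else:
            R = redundancy_sum / (k - 1)
        w = int(np.argmin(np.where(available, R, np.inf)))
        available[w] = False
        sel_pos.append(int(neg_rows[w]))
        sel_r.append(float(R[w]))
        redundancy_sum += nn[:, w]
    return SelectionResult(
        selected=np.array(sel_pos),
        d_scores=np.zeros(l),
        r_scores=np.array(sel_r),
        psi_scores=-np.array(sel_r),
        method="minr",
        config=cfg,
        resolved_l=l,
        correlation_evals=counter.count,
        dataset_fingerprint=dataset.fingerprint(),
    )


_SELECTORS = {"mmpcc": select_mmpcc, "maxr": select_maxr, "minr": select_minr}


def select(dataset: LabeledDataset, config: SamplerConfig) -> SelectionResult:
    """Dispatch to the selector named in ``config.method``."""
    return _SELECTORS[config.method](dataset, config)


def brute_force_step(
    dataset: LabeledDataset,
    selected_so_far: list[int],
    config: SamplerConfig,
) -> tuple[int, float, float, float]:
    """Naive single-step oracle: exhaustive candidate scan, scalar PCC only.

    Returns ``(winner_row_index, D, R, Psi)`` for the next greedy step given
    the already-selected row indices. Intentionally unoptimized (no caching,
    plain Python loops) so it is an independent check on the vectorized
    selectors.
    """
    X = dataset.features
    neg_rows = [int(i) for i in dataset.negative_indices]
    pos_rows = [int(i) for i in dataset.positive_indices]
    selected = [int(i) for i in selected_so_far]
    candidates = [i for i in neg_rows if i not in selected]
    if not candidates:
        raise ConfigError("no remaining negative candidates")

    def corr(a, b):
        r = pearson(X[a], X[b])
        return abs(r) if config.use_abs else r

    best = None
    for i in candidates:
        if config.method in ("mmpcc", "maxr"):
            rels = [corr(i, j) for j in pos_rows]
            D = max(rels) if config.aggregation == "max" else sum(rels) / len(rels)
        else:
            D = 0.0
        if config.method == "maxr":
            R = 0.0
        elif not selected:
            if config.method == "minr":
                others = [j for j in neg_rows if j != i]
                R = sum(corr(i, j) for j in others) / len(others) if others else 0.0
            else:
                R = 0.0
        else:
            R = sum(corr(i, s) for s in selected) / len(selected)
        psi = D - R
        if best is None or psi > best[3]:
            best = (i, D, R, psi)
    return best


def relabel(dataset: LabeledDataset, result: SelectionResult) -> LabeledDataset:
    """Flip the selected samples' labels to positive (move, not duplicate).

    The returned dataset shares features with the input; only the label
    vector is new. Applying the same result twice is rejected because the
    indices are no longer negative the second time.
    """
    if result.dataset_fingerprint != dataset.fingerprint():
        raise IntegrityError("selection result was computed on a different dataset")
    labels = dataset.labels.copy()
    for idx in result.selected:
        if labels[idx]:
            raise IntegrityError(f"sample {int(idx)} is not a negative in this dataset")
        labels[idx] = True
    return dataset.with_labels(labels)
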