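"""Synthetic imbalanced datasets with planted pseudo-negatives.

The generator emulates the setting the pseudo-negative selectors are built
for: a small positive class, a large negative class, and a planted subset
of "negatives" that were actually drawn from the positive-class
distribution — the ground truth a selector should recover.

Model: each class is a spherical Gaussian over f features. A base profile
mu+ is drawn once per dataset, N(0, (profile_sd * sd)^2) per feature; the
negative-class mean is mu- = mu+ + delta * sd * u for a random unit
direction u, so ``delta`` is the class-mean separation in units of the
within-class standard deviation ``sd``. Planted rows are drawn from the
positive distribution but labeled negative. The base profile must vary
across features for sample-wise Pearson correlation to carry class signal
(a flat profile would make every expected correlation zero); profile_sd
sets that variation, in units of sd.

Rows are laid out positives first, then true negatives, then planted
pseudo-negatives; everything is determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LabeledDataset
from .exceptions import ConfigError, IntegrityError
from .selection import SelectionResult

__all__ = ["PlantedParams", "PlantedDataset", "generate_planted", "recovery_score"]


@dataclass(frozen=True)
class PlantedParams:
    """Generator parameters; defaults are the standard test instance."""

    m: int = 20            # positives
    n_true_neg: int = 180  # genuine negatives
    l_true: int = 20       # planted pseudo-negatives
    f: int = 10            # features
    delta: float = 4.0     # class-mean separation, in within-class sd units
    sd: float = 1.0        # within-class standard deviation
    profile_sd: float = 3.0  # base-profile spread across features, in sd units
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.m, self.n_true_neg, self.f) < 1:
            raise ConfigError("m, n_true_neg and f must all be >= 1")
        if self.l_true < 0:
            raise ConfigError("l_true must be >= 0")
        if self.delta < 0:
            raise ConfigError("delta must be >= 0")
        if self.sd <= 0:
            raise ConfigError("sd must be > 0")


@dataclass
class PlantedDataset:
    """A labeled dataset plus the ground-truth planted indices."""

    dataset: LabeledDataset
    planted_indices: np.ndarray  # row indices into dataset, sorted
    params: PlantedParams
    fingerprint: str = field(init=False)

    def __post_init__(self) -> None:
        self.planted_indices = np.asarray(sorted(self.planted_indices), dtype=int)
        if not set(self.planted_indices) <= set(self.dataset.negative_indices.tolist()):
            raise IntegrityError("planted indices must carry negative labels")
        self.fingerprint = self.dataset.fingerprint()


def generate_planted(params: PlantedParams | None = None, **kwargs) -> PlantedDataset:
    """Generate an imbalanced dataset with a known planted subset.

    Accepts either a :class:`PlantedParams` or keyword overrides of its
    fields. Deterministic given the seed.
    """
    if params is None:
        params = PlantedParams(**kwargs)
    elif kwargs:
        raise ConfigError("pass either a PlantedParams or keyword overrides, not both")
    p = params
    rng = np.random.default_rng(p.seed)
    mu_pos = rng.normal(0.0, p.profile_sd * p.sd, p.f)
    u = rng.normal(size=p.f)
    u /= np.linalg.norm(u)
    mu_neg = mu_pos + p.delta * p.sd * u
    X = np.vstack(
        [
            rng.normal(mu_pos, p.sd, (p.m, p.f)),
            rng.normal(mu_neg, p.sd, (p.n_true_neg, p.f)),
            rng.normal(mu_pos, p.sd, (p.l_true, p.f)) if p.l_true else np.empty((0, p.f)),
        ]
    )
    labels = np.concatenate(
        [np.ones(p.m, dtype=bool), np.zeros(p.n_true_neg + p.l_true, dtype=bool)]
    )
    dataset = LabeledDataset(
        features=X,
        labels=labels,
        feature_names=[f"f{j}" for j in range(p.f)],
    )
    planted = np.arange(p.m + p.n_true_neg, p.m + p.n_true_neg + p.l_true)
    return PlantedDataset(dataset=dataset, planted_indices=planted, params=p)


def recovery_score(result: SelectionResult, truth: PlantedDataset) -> dict:
    """Precision/recall of a selection against the planted ground truth.

    precision = |selected ∩ planted| / |selected|;
    recall = |selected ∩ planted| / |planted| (1.0 by convention when no
    samples were planted, flagged in the output).
    """
    if result.dataset_fingerprint != truth.fingerprint:
        raise IntegrityError("selection result was not produced on this planted dataset")
    selected = set(result.selected.tolist())
    planted = set(truth.planted_indices.tolist())
    hits = len(selected & planted)
    empty_planted = len(planted) == 0
    return {
        "precision": hits / len(selected) if selected else 0.0,
        "recall": 1.0 if empty_planted else hits / len(planted),
        "hits": hits,
        "empty_planted_set": empty_planted,
    }
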