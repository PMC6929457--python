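"""Metrics closed forms, the CV harness, and the classifier registry."""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from pseudoneg import (
    ConfigError,
    ConfusionCounts,
    SamplerConfig,
    acc,
    classifier_registry,
    confusion_counts,
    cross_validate,
    generate_planted,
    mcc,
    percentage_sweep,
    sen,
    spe,
)
from .conftest import random_dataset

pytestmark = pytest.mark.filterwarnings("ignore:l=.*>= m=")


# -- confusion counts -------------------------------------------------------

def test_confusion_hand_count():
    y_true = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
    y_pred = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
    c = confusion_counts(y_true, y_pred)
    assert (c.tp, c.fn, c.fp, c.tn) == (3, 1, 1, 5)
    assert c.total == 10


def test_confusion_perfect_and_inverted(rng):
    y = rng.integers(0, 2, 30)
    y[0], y[1] = 0, 1  # both classes present
    c = confusion_counts(y, y)
    assert c.fp == c.fn == 0
    c = confusion_counts(y, 1 - y)
    assert c.tp == c.tn == 0


def test_confusion_input_errors():
    with pytest.raises(Exception):
        confusion_counts(np.array([0, 1]), np.array([0, 1, 1]))
    with pytest.raises(Exception):
        confusion_counts(np.array([0, 2]), np.array([0, 1]))


# -- metrics ----------------------------------------------------------------

def test_metric_hand_example():
    c = ConfusionCounts(tp=3, fn=1, fp=1, tn=5)
    assert sen(c) == pytest.approx(0.75)
    assert spe(c) == pytest.approx(5 / 6)
    assert acc(c) == pytest.approx(0.8)
    assert mcc(c) == pytest.approx(14 / 24)


def test_metric_perfect_prediction():
    c = ConfusionCounts(tp=4, tn=9, fp=0, fn=0)
    assert (sen(c), spe(c), acc(c), mcc(c)) == (1.0, 1.0, 1.0, 1.0)


def test_metric_zero_denominator_conventions():
    allpos = ConfusionCounts(tp=5, fn=0, fp=5, tn=0)  # all-positive predictor
    assert spe(allpos) == 0.0
    assert mcc(allpos) == 0.0
    nopos = ConfusionCounts(tp=0, fn=0, fp=2, tn=8)  # fold without positives
    assert np.isnan(sen(nopos))
    assert mcc(nopos) == 0.0


def test_mcc_matches_sklearn_on_random_tables(rng):
    for _ in range(200):
        tp, tn, fp, fn = (int(x) for x in rng.integers(0, 12, 4))
        if tp + tn + fp + fn == 0:
            continue
        c = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
        y_true = [1] * tp + [1] * fn + [0] * tn + [0] * fp
        y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
        assert mcc(c) == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)
        assert -1 <= mcc(c) <= 1


def test_mcc_near_zero_on_permuted_labels(rng):
    n = 4000
    y = rng.integers(0, 2, n)
    perm = rng.permutation(y)
    value = mcc(confusion_counts(y, perm))
    assert abs(value) < 4 / np.sqrt(n)  # CLT bound


# -- registry ---------------------------------------------------------------

def test_registry_resolves_all_four_names():
    for name in ("da", "rf", "nn", "adaboost"):
        clf = classifier_registry.get(name, seed=0)
        assert hasattr(clf, "fit") and hasattr(clf, "predict")


def test_registry_unknown_name_lists_options():
    with pytest.raises(ConfigError, match="adaboost"):
        classifier_registry.get("svm")


def test_adaboost_separable_toy_and_sign_semantics(rng):
    X = np.vstack([rng.normal(-3, 0.3, (10, 2)), rng.normal(3, 0.3, (10, 2))])
    y = np.array([0] * 10 + [1] * 10)
    clf = classifier_registry.get("adaboost", seed=0)
    clf.fit(X, y)
    assert (clf.predict(X) == y).all()
    # decision is the sign of the weighted sum of weak-learner votes
    votes = np.zeros(len(X))
    for est, w in zip(clf.estimators_, clf.estimator_weights_):
        votes += w * np.where(est.predict(X) == 1, 1.0, -1.0)
    assert np.array_equal(votes > 0, clf.predict(X).astype(bool))


# -- cross-validation -------------------------------------------------------

class _MajorityNegative:
    """Trivial predictor: always the negative (majority) class."""

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.zeros(len(X), dtype=int)


def test_cv_majority_predictor_forces_sen0_spe1(rng):
    ds = random_dataset(rng, m=10, n=40, f=4)
    report = cross_validate(ds, sampler=None, classifier=_MajorityNegative(), seed=0)
    for fold in report.per_fold:
        assert fold["Sen"] == 0.0
        assert fold["Spe"] == 1.0
    assert report.aggregate["Sen"] == 0.0


def test_cv_folds_partition_every_sample(rng):
    ds = random_dataset(rng, m=10, n=25, f=4)
    seen = []

    class Recorder(_MajorityNegative):
        def predict(self, X):
            seen.append(len(X))
            return np.zeros(len(X), dtype=int)

    cross_validate(ds, classifier=Recorder(), folds=5, seed=1)
    assert sum(seen) == ds.n_samples


def test_cv_requires_enough_members_per_class(rng):
    ds = random_dataset(rng, m=3, n=40, f=4)
    with pytest.raises(ConfigError, match="5-fold"):
        cross_validate(ds, folds=5)


def test_cv_sampler_never_sees_test_folds(rng):
    """Leakage audit: an instrumented sampler records the row ids it is
    given; under train_folds scope they must never include test rows."""
    ds = random_dataset(rng, m=10, n=40, f=4)
    seen_ids: list[set] = []

    def spying_sampler(train, seed):
        seen_ids.append(set(train.ids.tolist()))
        return train

    test_folds: list[set] = []

    class Recorder(_MajorityNegative):
        def predict(self, X):
            return np.zeros(len(X), dtype=int)

    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=7)
    for _, test_idx in skf.split(ds.features, ds.labels.astype(int)):
        test_folds.append(set(ds.ids[test_idx].tolist()))
    cross_validate(ds, sampler=spying_sampler, classifier=Recorder(), seed=7)
    assert len(seen_ids) == 5
    for sampler_saw, test_ids in zip(seen_ids, test_folds):
        assert not (sampler_saw & test_ids)


def test_cv_mmpcc_improves_sensitivity_on_planted_data():
    """Relabeling planted pseudo-negatives into the training positives
    should raise mean sensitivity relative to no sampling."""
    gains = []
    for seed in range(10):
        planted = generate_planted(seed=seed)
        base = cross_validate(planted.dataset, sampler=None, classifier="da", seed=seed)
        cfg = SamplerConfig(method="mmpcc", percentage=50)
        boosted = cross_validate(planted.dataset, sampler=cfg, classifier="da", seed=seed)
        gains.append(boosted.aggregate["Sen"] - base.aggregate["Sen"])
    assert np.mean(gains) >= 0


def test_cv_scoring_uses_original_labels(rng):
    """Whole-dataset scope relabels before the split, yet test folds are
    still scored against the original labels: an always-positive
    predictor keeps Spe computed over ALL original negatives."""
    ds = random_dataset(rng, m=10, n=40, f=4)

    class AlwaysPositive(_MajorityNegative):
        def predict(self, X):
            return np.ones(len(X), dtype=int)

    cfg = SamplerConfig(method="maxr", l=5)
    report = cross_validate(
        ds, sampler=cfg, classifier=AlwaysPositive(), seed=0,
        sample_scope="whole_dataset",
    )
    total_negatives = sum(f["counts"].fp + f["counts"].tn for f in report.per_fold)
    assert total_negatives == 40  # none of the 5 relabeled rows left the negative tally
    assert report.aggregate["Spe"] == 0.0


def test_metrics_report_recomputable(rng):
    ds = random_dataset(rng, m=10, n=30, f=4)
    report = cross_validate(ds, classifier="da", seed=2)
    for fold in report.per_fold:
        c = fold["counts"]
        assert fold["Sen"] == pytest.approx(sen(c))
        assert fold["MCC"] == pytest.approx(mcc(c))
    for name in ("Sen", "Spe", "Acc", "MCC"):
        vals = [f[name] for f in report.per_fold]
        assert report.aggregate[name] == pytest.approx(np.nanmean(vals))


# -- percentage sweep -------------------------------------------------------

def test_sweep_zero_percentage_matches_no_sampler(rng):
    ds = random_dataset(rng, m=10, n=30, f=4)
    table = percentage_sweep(ds, method="mmpcc", classifiers=["da"],
                             percentages=[0], seed=3)
    solo = cross_validate(ds, sampler=None, classifier="da", seed=3)
    assert table.iloc[0]["Sen%"] == pytest.approx(100 * solo.aggregate["Sen"])
    assert table.iloc[0]["MCC"] == pytest.approx(solo.aggregate["MCC"])


def test_sweep_row_count(rng):
    ds = random_dataset(rng, m=10, n=30, f=4)
    table = percentage_sweep(ds, method="maxr", classifiers=["da", "rf"],
                             percentages=[0, 20], seed=0)
    assert len(table) == 4
    assert set(table.columns) >= {"percentage", "classifier", "Sen%", "Spe%", "Acc%", "MCC"}
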