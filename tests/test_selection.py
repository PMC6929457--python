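"""Greedy selectors: oracle equivalence, determinism, relabeling."""

import numpy as np
import pytest

from pseudoneg import (
    ConfigError,
    IntegrityError,
    LabeledDataset,
    SamplerConfig,
    aggregate_relevance,
    brute_force_step,
    relabel,
    relevance_block,
    resolve_l,
    select,
    select_maxr,
    select_minr,
    select_mmpcc,
)
from .conftest import random_dataset, rows_with_correlations

pytestmark = pytest.mark.filterwarnings("ignore:l=.*>= m=")


# -- resolve_l --------------------------------------------------------------

def test_resolve_l_passthrough_and_percentages(small_dataset):
    assert resolve_l(SamplerConfig(l=3), small_dataset) == 3
    assert resolve_l(SamplerConfig(percentage=0), small_dataset) == 0
    # half-up rounding: 50% of 333 positives -> 167
    big = LabeledDataset(
        np.random.default_rng(0).normal(size=(1473, 3)),
        np.array([True] * 333 + [False] * 1140),
    )
    assert resolve_l(SamplerConfig(percentage=50, percentage_base="positives"), big) == 167
    assert resolve_l(SamplerConfig(percentage=50, percentage_base="negatives"), big) == 570
    # explicit l above the negative count clamps to n
    assert resolve_l(SamplerConfig(l=10**6), big) == 1140


def test_resolve_l_warns_on_tiny_percentage(small_dataset):
    with pytest.warns(UserWarning, match="no-op"):
        assert resolve_l(SamplerConfig(percentage=1), small_dataset) == 0


def test_config_requires_exactly_one_size():
    with pytest.raises(ConfigError):
        SamplerConfig(l=3, percentage=10)
    with pytest.raises(ConfigError):
        SamplerConfig()


# -- per-step oracle equivalence -------------------------------------------

@pytest.mark.parametrize("method", ["mmpcc", "maxr", "minr"])
def test_selectors_match_bruteforce_oracle(method, rng):
    for _ in range(8):
        m = int(rng.integers(2, 7))
        n = int(rng.integers(4, 16))
        f = int(rng.integers(4, 8))
        l = int(rng.integers(1, min(n, 6) + 1))
        ds = random_dataset(rng, m=m, n=n, f=f)
        cfg = SamplerConfig(method=method, l=l)
        result = select(ds, cfg)
        selected = []
        for k in range(l):
            w, D, R, psi = brute_force_step(ds, selected, cfg)
            assert result.selected[k] == w
            assert result.d_scores[k] == pytest.approx(D, abs=1e-9)
            assert result.r_scores[k] == pytest.approx(R, abs=1e-9)
            assert result.psi_scores[k] == pytest.approx(psi, abs=1e-9)
            selected.append(w)


def test_bruteforce_empty_selected_has_zero_redundancy(rng):
    ds = random_dataset(rng, m=3, n=5, f=6)
    _, _, R, _ = brute_force_step(ds, [], SamplerConfig(method="mmpcc", l=1))
    assert R == 0.0


def test_bruteforce_singleton_pool_wins(rng):
    ds = random_dataset(rng, m=3, n=3, f=6)
    others = ds.negative_indices[:2].tolist()
    w, *_ = brute_force_step(ds, others, SamplerConfig(method="mmpcc", l=3))
    assert w == ds.negative_indices[2]


# -- MMPCC ------------------------------------------------------------------

def test_mmpcc_l1_equals_maxr_first_pick(small_dataset):
    cfg = SamplerConfig(method="mmpcc", l=1)
    r_mm = select_mmpcc(small_dataset, cfg)
    r_mx = select_maxr(small_dataset, SamplerConfig(method="maxr", l=1))
    assert r_mm.selected[0] == r_mx.selected[0]
    assert r_mm.r_scores[0] == 0.0
    assert r_mm.psi_scores == pytest.approx(r_mm.d_scores - r_mm.r_scores)


def test_mmpcc_correlation_budget(rng):
    ds = random_dataset(rng, m=6, n=20, f=5)
    result = select_mmpcc(ds, SamplerConfig(method="mmpcc", l=5))
    assert result.correlation_evals <= 20 * 6 + 20 * 5


def test_selection_is_deterministic(rng):
    ds = random_dataset(rng, m=5, n=15, f=6)
    cfg = SamplerConfig(method="mmpcc", l=4)
    a, b = select(ds, cfg), select(ds, cfg)
    assert np.array_equal(a.selected, b.selected)
    assert np.array_equal(a.psi_scores, b.psi_scores)
    assert a.dataset_fingerprint == b.dataset_fingerprint


def test_selected_are_unique_negatives(rng):
    ds = random_dataset(rng, m=4, n=12, f=6)
    res = select(ds, SamplerConfig(method="mmpcc", l=6))
    assert len(set(res.selected.tolist())) == 6
    assert not ds.labels[res.selected].any()


# -- MAXR -------------------------------------------------------------------

def test_maxr_is_sorted_relevance(rng):
    ds = random_dataset(rng, m=4, n=30, f=6)
    res = select_maxr(ds, SamplerConfig(method="maxr", l=30))
    D = aggregate_relevance(relevance_block(ds), "mean")
    order = np.argsort(-D, kind="stable")
    assert np.array_equal(res.selected, ds.negative_indices[order])
    assert np.all(np.diff(res.d_scores) <= 1e-15)
    assert np.all(res.r_scores == 0)


def test_maxr_prefix_monotonicity(rng):
    ds = random_dataset(rng, m=4, n=20, f=6)
    prev = select_maxr(ds, SamplerConfig(method="maxr", l=5)).selected
    nxt = select_maxr(ds, SamplerConfig(method="maxr", l=6)).selected
    assert np.array_equal(prev, nxt[:5])


def test_maxr_exact_positive_copy_selected_first(rng):
    pos_row = rng.normal(size=6)
    X = np.vstack([pos_row, pos_row, pos_row.copy(), rng.normal(size=(4, 6))])
    ds = LabeledDataset(X, np.array([True, True, False, False, False, False, False]))
    for agg in ("mean", "max"):
        res = select_maxr(ds, SamplerConfig(method="maxr", l=1, aggregation=agg))
        assert res.selected[0] == 2
        assert res.d_scores[0] == pytest.approx(1.0, abs=1e-12)


# -- MINR -------------------------------------------------------------------

def test_minr_first_pick_hand_example(rng):
    # negative pairwise correlations {(1,2): 0.9, (1,3): 0.1, (2,3): 0.2}
    # mean-to-others: 0.5, 0.55, 0.15 -> third negative first
    C = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]])
    neg = rows_with_correlations(C, f=8)
    X = np.vstack([rng.normal(size=(2, 8)), neg])
    ds = LabeledDataset(X, np.array([True, True, False, False, False]))
    res = select_minr(ds, SamplerConfig(method="minr", l=1))
    assert res.selected[0] == 4
    assert res.r_scores[0] == pytest.approx(0.15, abs=1e-9)
    assert np.all(res.d_scores == 0)


def test_minr_anticorrelated_pair_selected_early():
    v = np.array([1.0, 2.0, 5.0, 3.0, 0.0])
    w = 4.0 - v  # pearson(v, w) == -1
    X = np.vstack([v + 0.1, v, v.copy(), w])
    ds = LabeledDataset(X, np.array([True, False, False, False]))
    res = select_minr(ds, SamplerConfig(method="minr", l=2))
    picked = set(res.selected.tolist())
    assert 3 in picked  # w
    assert len(picked & {1, 2}) == 1  # exactly one copy of v


# -- relabel ----------------------------------------------------------------

def test_relabel_moves_samples(rng):
    ds = random_dataset(rng, m=10, n=100, f=5)
    res = select(ds, SamplerConfig(method="maxr", l=25))
    out = relabel(ds, res)
    assert (out.m, out.n) == (35, 75)
    assert ds.m == 10  # original untouched
    assert np.shares_memory(out.features, ds.features)


def test_relabel_zero_is_identity(rng):
    ds = random_dataset(rng, m=3, n=6, f=5)
    res = select(ds, SamplerConfig(method="mmpcc", percentage=0))
    out = relabel(ds, res)
    assert np.array_equal(out.labels, ds.labels)


def test_relabel_roundtrip_and_integrity(rng):
    ds = random_dataset(rng, m=4, n=10, f=5)
    res = select(ds, SamplerConfig(method="mmpcc", l=3))
    out = relabel(ds, res)
    back = out.labels.copy()
    back[res.selected] = False
    assert np.array_equal(back, ds.labels)
    with pytest.raises(IntegrityError):
        relabel(out, res)  # indices are no longer negative there


def test_result_serialization(rng, tmp_path):
    ds = random_dataset(rng, m=3, n=8, f=5)
    res = select(ds, SamplerConfig(method="mmpcc", l=2))
    frame = res.to_frame()
    assert list(frame.columns) == ["step", "sample_index", "D", "R", "Psi"]
    payload = res.to_json(tmp_path / "sel.json")
    assert payload["config"]["method"] == "mmpcc"
    assert (tmp_path / "sel.json").exists()
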