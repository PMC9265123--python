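"""Threshold filtering, stratified splitting, class-weighted sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from chromgat.connectivity import ConnectivityProfile
from chromgat.filtering import (
    DatasetSplit,
    FilterConfig,
    class_weights,
    draw_weighted_batches,
    filter_graphs,
    sample_weights,
    split_dataset,
)
from chromgat.graphs import RearrangementGraph


def _profiled(kappa_bars):
    graphs, profiles = [], []
    for i, kb in enumerate(kappa_bars):
        sid = f"g{i}"
        graphs.append(RearrangementGraph(sid, "x", []))
        profiles.append(ConnectivityProfile(sid, np.zeros((24, 24), int), kb))
    return graphs, profiles


def test_threshold_boundary_inclusive():
    graphs, profiles = _profiled([0.0, 0.1, 0.3, 0.9])
    kept, dropped = filter_graphs(graphs, profiles, FilterConfig(tau_low=0.3))
    assert [g.sample_id for g in kept] == ["g2", "g3"]
    assert [g.sample_id for g in dropped] == ["g0", "g1"]


def test_threshold_zero_keeps_everything():
    graphs, profiles = _profiled([0.0, 0.1, 0.3, 0.9])
    kept, dropped = filter_graphs(graphs, profiles, FilterConfig(tau_low=0.0))
    assert len(kept) == 4 and not dropped


def test_upper_threshold():
    graphs, profiles = _profiled([0.0, 0.1, 0.3, 0.9])
    kept, _ = filter_graphs(graphs, profiles, FilterConfig(tau_low=0.3, tau_high=0.8))
    assert [g.sample_id for g in kept] == ["g2"]


def test_partition_is_exhaustive_and_disjoint(small_cohort_graphs, small_cohort_profiles):
    kept, dropped = filter_graphs(small_cohort_graphs, small_cohort_profiles, FilterConfig())
    assert len(kept) + len(dropped) == len(small_cohort_graphs)
    assert not {g.sample_id for g in kept} & {g.sample_id for g in dropped}


def test_missing_profile_names_sample():
    graphs, profiles = _profiled([0.5, 0.5])
    with pytest.raises(KeyError, match="g1"):
        filter_graphs(graphs, profiles[:1], FilterConfig())


def _labelled(counts):
    graphs = []
    for label, n in counts.items():
        for i in range(n):
            graphs.append(RearrangementGraph(f"{label}{i}", label, []))
    return graphs


def test_split_stratification_arithmetic():
    split = split_dataset(_labelled({"a": 50, "b": 30, "c": 20}), 0.2, seed=7)
    assert split.counts()["test"] == {"a": 10, "b": 6, "c": 4}
    assert len(split.train) == 80


def test_split_deterministic():
    graphs = _labelled({"a": 30, "b": 20})
    s1 = split_dataset(graphs, 0.25, seed=3)
    s2 = split_dataset(graphs, 0.25, seed=3)
    assert [g.sample_id for g in s1.train] == [g.sample_id for g in s2.train]
    assert [g.sample_id for g in s1.test] == [g.sample_id for g in s2.test]


def test_split_452_graphs_gives_361_train_91_test():
    graphs = _labelled({"a": 160, "b": 150, "c": 142})
    split = split_dataset(graphs, 91 / 452, seed=0)
    assert len(split.train) == 361
    assert len(split.test) == 91


def test_split_no_leakage(small_split):
    assert not (
        {g.sample_id for g in small_split.train}
        & {g.sample_id for g in small_split.test}
    )


def test_split_rejects_singleton_class():
    with pytest.raises(ValueError, match="b"):
        split_dataset(_labelled({"a": 10, "b": 1}), 0.2, seed=0)


@pytest.mark.parametrize(
    "counts,expected",
    [
        ({"A": 10, "B": 10}, {"A": 1.0, "B": 1.0}),
        ({"A": 30, "B": 10}, {"A": 0.5, "B": 1.5}),
        ({"A": 7}, {"A": 1.0}),
    ],
)
def test_class_weights(counts, expected):
    labels = [c for c, n in counts.items() for _ in range(n)]
    w = class_weights(labels)
    assert w == pytest.approx(expected)


@settings(derandomize=True)
@given(
    st.dictionaries(
        st.sampled_from("abcdef"),
        st.integers(min_value=1, max_value=50),
        min_size=1,
        max_size=6,
    )
)
def test_class_weights_mean_one_and_inverse_frequency(counts):
    labels = [c for c, n in counts.items() for _ in range(n)]
    w = class_weights(labels)
    assert np.mean(list(w.values())) == pytest.approx(1.0)
    # weight ratio is the inverse count ratio
    classes = list(counts)
    for a in classes:
        for b in classes:
            assert w[a] * counts[a] == pytest.approx(w[b] * counts[b])


def test_weighted_sampling_uniform_class_frequency():
    """Minority oversampling: expected class frequency in drawn batches is
    uniform (chi-square over 10,000 draws)."""
    graphs = _labelled({"a": 60, "b": 30, "c": 10})
    weights = sample_weights(graphs, class_weights([g.label for g in graphs]))
    rng = np.random.default_rng(0)
    labels = [g.label for g in graphs]
    drawn = []
    while len(drawn) < 10_000:
        for batch in draw_weighted_batches(len(graphs), weights, 10, rng):
            drawn.extend(labels[i] for i in batch)
    drawn = drawn[:10_000]
    observed = np.array([drawn.count(c) for c in "abc"])
    _, p = stats.chisquare(observed)
    assert p > 0.01
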