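"""Graph attention classifier: attention normalization, forward contracts,
training determinism, capacity and learning sanity."""

import numpy as np
import pytest

from chromgat.breakpoints import CRERecord, group_by_sample
from chromgat.filtering import DatasetSplit, class_weights, split_dataset
from chromgat.graphs import RearrangementGraph, build_cohort, build_graph
from chromgat.nn.model import (
    GNNConfig,
    ModelState,
    attention_coefficients,
    evaluate_accuracy,
    forward,
    hub_sweep,
    init_state,
    predict,
    train,
)
from chromgat.synthetic import make_chain_cohort

TINY = dict(n_hubs=2, hidden_dim=16, max_epochs=3, seed=0, n_classes=2)


def _random_graph(rng, n_edges):
    edges = [
        (int(rng.integers(1, 25)), int(rng.integers(1, 25)), "unknown")
        for _ in range(n_edges)
    ]
    return RearrangementGraph("s", "a", edges)


def _tiny_split(rng, n=12, edges=8):
    graphs = []
    for i in range(n):
        g = _random_graph(rng, edges)
        graphs.append(
            RearrangementGraph(f"s{i}", "a" if i % 2 else "b", g.edges)
        )
    train_g, test_g = graphs[: n - 4], graphs[n - 4 :]
    return DatasetSplit(
        train=train_g, test=test_g, seed=0,
        class_weights=class_weights([g.label for g in train_g]),
    )


def test_attention_rows_sum_to_one():
    rng = np.random.default_rng(0)
    state = init_state(GNNConfig(**TINY), ["a", "b"])
    for _ in range(20):
        g = _random_graph(rng, int(rng.integers(0, 40)))
        src, dst, alpha = attention_coefficients(state, g)
        sums = np.zeros(24)
        np.add.at(sums, dst, alpha)
        active = np.unique(dst)
        assert sums[active] == pytest.approx(np.ones(len(active)), abs=1e-6)
        assert (alpha >= 0).all()


def test_single_neighbor_gets_full_attention():
    state = init_state(GNNConfig(**TINY), ["a", "b"])
    g = RearrangementGraph("s", "a", [(1, 2, "unknown")])
    src, dst, alpha = attention_coefficients(state, g)
    # node 2 aggregates from node 1 and its self-loop: those two alphas sum to 1;
    # every other node has only its self-loop, whose alpha is exactly 1
    self_only = [a for s, d, a in zip(src, dst, alpha) if s == d and d not in (1,)]
    assert np.array(self_only[1:]) == pytest.approx(1.0)


def test_forward_is_a_distribution_and_deterministic():
    rng = np.random.default_rng(1)
    state = init_state(GNNConfig(**TINY), ["a", "b"])
    g = _random_graph(rng, 15)
    lp1, lp2 = forward(state, g), forward(state, g)
    assert np.exp(lp1).sum() == pytest.approx(1.0, abs=1e-6)
    assert (lp1 <= 0).all()
    assert lp1 == pytest.approx(lp2)


def test_forward_on_edgeless_graph():
    state = init_state(GNNConfig(**TINY), ["a", "b"])
    lp = forward(state, RearrangementGraph("s", "a", []))
    assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-6)


def test_predict_contracts():
    rng = np.random.default_rng(2)
    state = init_state(GNNConfig(**TINY), ["a", "b"])
    labels, probs = predict(state, [_random_graph(rng, 10) for _ in range(5)])
    assert len(labels) == 5 and probs.shape == (5, 2)
    assert probs.sum(axis=1) == pytest.approx(np.ones(5), abs=1e-6)
    assert set(labels) <= {"a", "b"}
    empty_labels, empty_probs = predict(state, [])
    assert empty_labels == [] and empty_probs.shape == (0, 2)


def test_training_is_deterministic_given_seed():
    rng = np.random.default_rng(3)
    split = _tiny_split(rng)
    cfg = dict(TINY)
    h1 = train(split, GNNConfig(**cfg)).history
    h2 = train(split, GNNConfig(**cfg)).history
    assert [(s.train_loss, s.train_acc, s.test_acc) for s in h1] == [
        (s.train_loss, s.train_acc, s.test_acc) for s in h2
    ]


def test_model_overfits_random_labels():
    """Capacity sanity: gradient flows through all layers — a 10-graph cohort
    with arbitrary labels is memorized."""
    rng = np.random.default_rng(4)
    graphs = [
        RearrangementGraph(f"s{i}", ["a", "b"][int(rng.integers(2))],
                           _random_graph(rng, 20).edges)
        for i in range(10)
    ]
    if len({g.label for g in graphs}) < 2:  # force both labels present
        graphs[0] = RearrangementGraph("s0", "a", graphs[0].edges)
        graphs[1] = RearrangementGraph("s1", "b", graphs[1].edges)
    split = DatasetSplit(train=graphs, test=[], seed=0,
                         class_weights=class_weights([g.label for g in graphs]))
    cfg = GNNConfig(n_hubs=6, hidden_dim=32, dropout=0.0, max_epochs=150,
                    seed=0, n_classes=2)
    state = train(split, cfg)
    assert evaluate_accuracy(state, graphs) == 1.0


def test_training_loss_decreases(small_split):
    cfg = GNNConfig(n_hubs=3, hidden_dim=32, max_epochs=12, seed=0, n_classes=3)
    state = train(small_split, cfg)
    assert state.history[-1].train_loss <= state.history[0].train_loss


def test_learns_separable_cohort(small_split):
    cfg = GNNConfig(n_hubs=3, hidden_dim=32, max_epochs=25, seed=0, n_classes=3)
    state = train(small_split, cfg)
    assert evaluate_accuracy(state, small_split.train) >= 0.95
    assert evaluate_accuracy(state, small_split.test) >= 0.9


def test_checkpoint_round_trip(tmp_path, small_split):
    rng = np.random.default_rng(5)
    cfg = GNNConfig(**TINY, feature_scheme="adjacency_row")
    state = train(_tiny_split(rng), cfg)
    path = tmp_path / "model.ckpt.json"
    state.save(path)
    loaded = ModelState.load(path)
    g = _random_graph(rng, 12)
    assert forward(loaded, g) == pytest.approx(forward(state, g))
    assert loaded.config == state.config


def test_hub_sweep_table():
    cohort = build_cohort(group_by_sample(make_chain_cohort(20, seed=0)))
    split = split_dataset(cohort, 0.25, seed=0)
    cfg = GNNConfig(hidden_dim=16, max_epochs=10, seed=0, n_classes=2)
    rows = hub_sweep(split, cfg, hub_range=[1, 3])
    assert [r["n_hubs"] for r in rows] == [1, 3]
    assert all(0.0 <= r["test_accuracy"] <= 1.0 for r in rows)
    # deeper message passing sees the multi-hop chain signal at least as well
    acc = {r["n_hubs"]: r["test_accuracy"] for r in rows}
    assert acc[3] >= acc[1]
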