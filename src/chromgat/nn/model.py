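"""Graph attention network for cancer-type classification of rearrangement graphs.

Architecture: ``n_hubs`` stacked graph-attention message-passing layers, so
each chromosome's embedding aggregates aberration information up to ``n_hubs``
hops away, followed by global max pooling over the 24 chromosome embeddings, a
dense layer, and log-softmax over cancer types.

Per layer, node u aggregates its in-neighborhood xi(u) as

    m(u) = sum_{v in xi(u)} alpha_{u,v} * (W h_v)

with attention coefficients alpha softmax-normalized over xi(u), scored by a
LeakyReLU of a learned linear form on the (transformed) source and destination
embeddings — the standard graph-attention construction.  A self-loop is added
to every node so each chromosome retains its own state across layers.
Parallel edges keep multiset semantics by default: a neighbor connected by k
aberrations appears k times in the softmax, letting multiplicity shift
attention mass (switchable to deduplicated neighborhoods).

Training minimizes the mean negative log likelihood of the true class over
batches drawn by class-weighted sampling with replacement, using Adam.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ..breakpoints import N_CHROMOSOMES
from ..filtering import DatasetSplit, draw_weighted_batches, sample_weights
from ..graphs import RearrangementGraph, node_features
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import (
    Adam,
    Tensor,
    attention_matmul,
    blocked_max,
    constant,
    log_softmax,
    nll_loss,
    parameter,
    segment_softmax,
    sparse_matmul,
)

CHECKPOINT_VERSION = 1


@dataclass
class GNNConfig:
    """Architecture and optimization settings.

    Defaults: 6 message-passing hubs, Adam at learning rate 0.001, batch size
    10, at most 200 epochs, dropout 0.2 — the operating point of the
    classifier; hidden width 64 and a single attention head are this
    package's defaults.
    """

    n_hubs: int = 6
    hidden_dim: int = 64
    attention_heads: int = 1
    dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 10
    max_epochs: int = 200
    seed: int = 0
    n_classes: int = 3
    feature_scheme: str = "adjacency_row"
    dedup_neighbors: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.n_hubs <= 10:
            raise ValueError("n_hubs must be in 1..10")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class EpochStats:
    epoch: int
    train_loss: float
    train_acc: float
    test_acc: float


@dataclass
class ModelState:
    """Learned parameters plus the configuration that shaped them."""

    config: GNNConfig
    params: dict[str, Tensor]
    class_order: list[str]
    history: list[EpochStats] = field(default_factory=list)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def save(self, path: str | Path) -> None:
        doc = {
            "version": CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "class_order": self.class_order,
            "params": {k: v.data.tolist() for k, v in self.params.items()},
            "history": [asdict(h) for h in self.history],
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "ModelState":
        doc = json.loads(Path(path).read_text())
        if doc.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {doc.get('version')}")
        return cls(
            config=GNNConfig(**doc["config"]),
            params={k: parameter(np.array(v)) for k, v in doc["params"].items()},
            class_order=list(doc["class_order"]),
            history=[EpochStats(**h) for h in doc["history"]],
        )


def feature_dim(scheme: str) -> int:
    if scheme == "adjacency_row":
        return N_CHROMOSOMES
    if scheme == "adjacency_row_plus_types":
        return N_CHROMOSOMES + 7
    raise ValueError(f"unknown feature scheme {scheme!r}")


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan = sum(shape) if len(shape) > 1 else shape[0] + 1
    limit = np.sqrt(6.0 / fan)
    return rng.uniform(-limit, limit, size=shape)


def init_state(config: GNNConfig, class_order: Sequence[str]) -> ModelState:
    """Glorot-initialized parameters; shapes fully determined by the config."""
    if len(class_order) != config.n_classes:
        raise ValueError("class_order length must equal n_classes")
    rng = np.random.default_rng(config.seed)
    h, heads = config.hidden_dim, config.attention_heads
    if h % heads:
        raise ValueError("hidden_dim must be divisible by attention_heads")
    hh = h // heads
    d_in = feature_dim(config.feature_scheme)
    params: dict[str, Tensor] = {}
    for layer in range(config.n_hubs):
        din = d_in if layer == 0 else h
        for head in range(heads):
            pre = f"layer{layer}.head{head}"
            params[f"{pre}.W"] = parameter(_glorot(rng, (din, hh)))
            params[f"{pre}.a_src"] = parameter(_glorot(rng, (hh,)))
            params[f"{pre}.a_dst"] = parameter(_glorot(rng, (hh,)))
    params["head.W"] = parameter(_glorot(rng, (h, config.n_classes)))
    params["head.b"] = parameter(np.zeros(config.n_classes))
    return ModelState(config=config, params=params, class_order=list(class_order))


@dataclass
class PreparedBatch:
    """A disjoint union of graphs, ready for message passing.

    Edge gathers and per-destination aggregation are precomputed as constant
    sparse selection/incidence matrices so the forward and backward passes run
    as sparse matmuls.
    """

    x: np.ndarray        # (n_graphs*24, d) node features
    src: np.ndarray      # edge sources (message senders), node-indexed
    dst: np.ndarray      # edge destinations (aggregating nodes)
    n_graphs: int
    S_src: sp.csr_matrix   # (E, N) row e selects node src[e]
    S_srcT: sp.csr_matrix
    S_dst: sp.csr_matrix
    S_dstT: sp.csr_matrix


def prepare_batch(
    graphs: Sequence[RearrangementGraph],
    config: GNNConfig,
) -> PreparedBatch:
    """Stack graphs into one disjoint union with self-loops on every node.

    Edge direction follows the aberration (source -> sink chromosome);
    messages flow along edges into their destination's aggregation.
    """
    xs, srcs, dsts = [], [], []
    for i, g in enumerate(graphs):
        off = i * N_CHROMOSOMES
        xs.append(node_features(g, config.feature_scheme))
        edge_pairs = [(u, v) for u, v, _ in g.edges]
        if config.dedup_neighbors:
            edge_pairs = sorted(set(edge_pairs))
        for u, v in edge_pairs:
            srcs.append(off + u - 1)
            dsts.append(off + v - 1)
        for w in range(N_CHROMOSOMES):  # message-passing self-loops
            srcs.append(off + w)
            dsts.append(off + w)
    n = len(graphs)
    x = np.concatenate(xs, axis=0)
    src = np.array(srcs, dtype=int)
    dst = np.array(dsts, dtype=int)
    n_nodes, n_edges = x.shape[0], len(src)
    ones = np.ones(n_edges)
    rows = np.arange(n_edges)
    S_src = sp.csr_matrix((ones, (rows, src)), shape=(n_edges, n_nodes))
    S_dst = sp.csr_matrix((ones, (rows, dst)), shape=(n_edges, n_nodes))
    return PreparedBatch(
        x=x, src=src, dst=dst, n_graphs=n,
        S_src=S_src, S_srcT=S_src.T.tocsr(),
        S_dst=S_dst, S_dstT=S_dst.T.tocsr(),
    )


def gat_aggregate(
    h: Tensor,
    batch: PreparedBatch,
    params: dict[str, Tensor],
    prefix: str,
    heads: int,
) -> Tensor:
    """One attention message-passing layer over the batched edge list.

    For every destination node the attention over its incoming edges is
    softmax-normalized (non-negative, sums to one); the aggregated message is
    the attention-weighted sum of transformed source embeddings, passed
    through an ELU nonlinearity.  Multiple heads are concatenated.
    """
    n_nodes = batch.x.shape[0]
    outs = []
    for head in range(heads):
        pre = f"{prefix}.head{head}"
        W, a_src, a_dst = params[f"{pre}.W"], params[f"{pre}.a_src"], params[f"{pre}.a_dst"]
        z = h @ W
        # per-node score scalars, then per-edge sums — the standard
        # concatenation-based scoring a.[Wh_u || Wh_v] decomposes this way
        t_src = z @ a_src.reshape(-1, 1)
        t_dst = z @ a_dst.reshape(-1, 1)
        scores = (
            sparse_matmul(batch.S_src, batch.S_srcT, t_src)
            + sparse_matmul(batch.S_dst, batch.S_dstT, t_dst)
        ).reshape(-1).leaky_relu(0.2)
        alpha = segment_softmax(scores, batch.dst, n_nodes)
        outs.append(attention_matmul(alpha, z, batch.src, batch.dst, n_nodes))
    out = outs[0]
    for extra in outs[1:]:  # concatenate heads along features
        joined = np.concatenate([out.data, extra.data], axis=1)
        left, right = out, extra
        cat = Tensor(joined, parents=(left, right))
        w = left.data.shape[1]

        def bw(g, left=left, right=right, w=w):
            if left.requires_grad:
                left._accumulate(g[:, :w])
            if right.requires_grad:
                right._accumulate(g[:, w:])

        cat._backward = bw
        out = cat
    return out.elu()


def attention_coefficients(
    state: ModelState,
    graph: RearrangementGraph,
    layer: int = 0,
    head: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Attention values (and edge endpoints) of one layer on one graph.

    Returns ``(src, dst, alpha)`` over the edge list including the
    message-passing self-loops; within each destination the alphas sum to 1.
    Introspection helper (first layer sees raw features; deeper layers would
    need the forward pass, so only layer 0 is exact here for layer > 0 inputs).
    """
    cfg = state.config
    batch = prepare_batch([graph], cfg)
    h = constant(batch.x)
    for li in range(layer + 1):
        pre = f"layer{li}.head{head}"
        W = state.params[f"{pre}.W"]
        a_src, a_dst = state.params[f"{pre}.a_src"], state.params[f"{pre}.a_dst"]
        z = h @ W
        scores = (
            sparse_matmul(batch.S_src, batch.S_srcT, z @ a_src.reshape(-1, 1))
            + sparse_matmul(batch.S_dst, batch.S_dstT, z @ a_dst.reshape(-1, 1))
        ).reshape(-1).leaky_relu(0.2)
        alpha = segment_softmax(scores, batch.dst, batch.x.shape[0])
        if li == layer:
            return batch.src, batch.dst, alpha.data
        h = gat_aggregate(h, batch, state.params, f"layer{li}", cfg.attention_heads)
    raise AssertionError("unreachable")


def forward_batch(
    state: ModelState,
    batch: PreparedBatch,
    rng: Optional[np.random.Generator] = None,
) -> Tensor:
    """Log-probability matrix (n_graphs x n_classes) for a prepared batch.

    Passing ``rng`` enables feature dropout (training mode); evaluation runs
    deterministic with dropout off.
    """
    cfg = state.config
    h = constant(batch.x)
    for layer in range(cfg.n_hubs):
        if rng is not None and cfg.dropout > 0:
            mask = (rng.random(h.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            h = h * constant(mask)
        h = gat_aggregate(h, batch, state.params, f"layer{layer}", cfg.attention_heads)
    pooled = blocked_max(h, N_CHROMOSOMES)
    logits = pooled @ state.params["head.W"] + state.params["head.b"].reshape(1, -1)
    return log_softmax(logits)


def forward(state: ModelState, graph: RearrangementGraph) -> np.ndarray:
    """Per-class log-probability vector for a single graph (evaluation mode)."""
    if not state.params:
        raise ValueError("uninitialized model state")
    return forward_batch(state, prepare_batch([graph], state.config)).data[0]


def predict(
    state: ModelState,
    graphs: Sequence[RearrangementGraph],
) -> tuple[list[str], np.ndarray]:
    """Predicted labels and the class-probability matrix.

    Argmax ties break toward the lowest class index.  A feature-scheme
    mismatch surfaces as a shape error in the first layer.
    """
    if not graphs:
        return [], np.zeros((0, state.config.n_classes))
    log_p = forward_batch(state, prepare_batch(graphs, state.config)).data
    idx = log_p.argmax(axis=1)  # np.argmax returns the first (lowest) maximum
    return [state.class_order[i] for i in idx], np.exp(log_p)


def _accuracy(state: ModelState, batch: PreparedBatch, labels: np.ndarray) -> float:
    log_p = forward_batch(state, batch).data
    return float((log_p.argmax(axis=1) == labels).mean())


def train(
    split: DatasetSplit,
    config: GNNConfig,
    log_path: str | Path | None = None,
) -> ModelState:
    """Train the classifier on a stratified split.

    Batches are drawn by class-weighted sampling with replacement so every
    class is equally represented in expectation.  All randomness (parameter
    init, dropout masks, batch sampling) derives from ``config.seed``; two
    runs with one seed produce identical histories.  Divergence (non-finite
    loss) aborts with a diagnostic.
    """
    if not split.train:
        raise ValueError("empty training set")
    class_order = sorted({g.label for g in split.train})
    config.n_classes = len(class_order)
    state = init_state(config, class_order)
    rng = np.random.default_rng(config.seed + 1)  # training stream, distinct from init
    label_index = {c: i for i, c in enumerate(class_order)}

    train_graphs = split.train
    y_train = np.array([label_index[g.label] for g in train_graphs])
    y_test = np.array([label_index[g.label] for g in split.test]) if split.test else np.array([], int)
    weights = sample_weights(train_graphs, split.class_weights)
    eval_train = prepare_batch(train_graphs, config)
    eval_test = prepare_batch(split.test, config) if split.test else None

    opt = Adam(state.parameters(), lr=config.learning_rate)
    log_fh = open(log_path, "w") if log_path else None
    if log_fh:
        log_fh.write("epoch\tloss\ttrain_acc\ttest_acc\n")
    try:
        for epoch in range(1, config.max_epochs + 1):
            losses = []
            for idx in draw_weighted_batches(len(train_graphs), weights,
                                             config.batch_size, rng):
                batch = prepare_batch([train_graphs[i] for i in idx], config)
                log_p = forward_batch(state, batch, rng=rng)
                loss = nll_loss(log_p, y_train[idx])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch} (loss={loss.data})"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            stats = EpochStats(
                epoch=epoch,
                train_loss=float(np.mean(losses)),
                train_acc=_accuracy(state, eval_train, y_train),
                test_acc=_accuracy(state, eval_test, y_test) if eval_test else float("nan"),
            )
            state.history.append(stats)
            if log_fh:
                log_fh.write(
                    f"{stats.epoch}\t{stats.train_loss:.6f}"
                    f"\t{stats.train_acc:.6f}\t{stats.test_acc:.6f}\n"
                )
    finally:
        if log_fh:
            log_fh.close()
    return state


def evaluate_accuracy(state: ModelState, graphs: Sequence[RearrangementGraph]) -> float:
    labels, _ = predict(state, graphs)
    return float(np.mean([p == g.label for p, g in zip(labels, graphs)]))


def hub_sweep(
    split: DatasetSplit,
    config: GNNConfig,
    hub_range: Sequence[int] = range(1, 11),
) -> list[dict]:
    """Retrain at each hop radius and report test accuracy per value."""
    rows = []
    for n_hubs in hub_range:
        cfg = GNNConfig(**{**asdict(config), "n_hubs": n_hubs})
        state = train(split, cfg)
        rows.append({
            "n_hubs": n_hubs,
            "test_accuracy": evaluate_accuracy(state, split.test),
            "train_accuracy": evaluate_accuracy(state, split.train),
        })
    return rows
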