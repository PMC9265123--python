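"""Informative-graph selection and dataset assembly.

Sparse graphs carry too few rearrangement endpoints to support graph-level
classification, so samples whose average connectivity falls below a threshold
(default 0.3) are removed.  The score is always taken on the integrated
(inter+intra) graph: restricting to self-loops first would zero every score
and empty the intrachromosomal experiment.  An optional upper threshold
supports the complementary reading of removing extremely dense graphs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .connectivity import ConnectivityProfile
from .graphs import RearrangementGraph


@dataclass
class FilterConfig:
    """Average-connectivity window; lower bound inclusive (kappa_bar >= tau_low keeps)."""

    tau_low: float = 0.3
    tau_high: float | None = None

    def __post_init__(self) -> None:
        if self.tau_low < 0:
            raise ValueError("tau_low must be non-negative")
        if self.tau_high is not None and self.tau_high <= self.tau_low:
            raise ValueError("tau_high must exceed tau_low")


def filter_graphs(
    graphs: Sequence[RearrangementGraph],
    profiles: Sequence[ConnectivityProfile],
    config: FilterConfig | None = None,
) -> tuple[list[RearrangementGraph], list[RearrangementGraph]]:
    """Partition graphs into (kept, dropped) by their kappa_bar score.

    Each graph needs exactly one matching profile (by sample_id), computed on
    the integrated graph regardless of the downstream edge mode.
    """
    config = config or FilterConfig()
    by_id = {p.sample_id: p for p in profiles}
    kept: list[RearrangementGraph] = []
    dropped: list[RearrangementGraph] = []
    for g in graphs:
        if g.sample_id not in by_id:
            raise KeyError(f"no connectivity profile for sample {g.sample_id!r}")
        kb = by_id[g.sample_id].kappa_bar
        ok = kb >= config.tau_low and (config.tau_high is None or kb <= config.tau_high)
        (kept if ok else dropped).append(g)
    return kept, dropped


@dataclass
class DatasetSplit:
    """Stratified train/test partition with per-class balancing weights."""

    train: list[RearrangementGraph]
    test: list[RearrangementGraph]
    seed: int
    class_weights: dict[str, float] = field(default_factory=dict)

    def counts(self) -> dict[str, dict[str, int]]:
        return {
            "train": dict(Counter(g.label for g in self.train)),
            "test": dict(Counter(g.label for g in self.test)),
        }


def class_weights(labels: Sequence[str]) -> dict[str, float]:
    """Inverse-frequency class weights rescaled to mean 1.

    Used as per-graph sampling weights so minority classes are oversampled and
    batches are drawn with uniform expected class frequency.
    """
    if not labels:
        raise ValueError("labels must be non-empty")
    counts = Counter(labels)
    raw = {c: 1.0 / n for c, n in counts.items()}
    mean = sum(raw.values()) / len(raw)
    return {c: w / mean for c, w in raw.items()}


def split_dataset(
    graphs: Sequence[RearrangementGraph],
    test_fraction: float,
    seed: int,
) -> DatasetSplit:
    """Deterministic stratified split; every class needs >= 2 graphs."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = [g.label for g in graphs]
    counts = Counter(labels)
    thin = [c for c, n in counts.items() if n < 2]
    if thin:
        raise ValueError(f"cannot stratify: classes with <2 graphs: {thin}")
    train, test = train_test_split(
        list(graphs),
        test_size=test_fraction,
        stratify=labels,
        random_state=seed,
    )
    return DatasetSplit(
        train=list(train),
        test=list(test),
        seed=seed,
        class_weights=class_weights([g.label for g in train]),
    )


def sample_weights(
    graphs: Sequence[RearrangementGraph],
    weights: Mapping[str, float],
) -> np.ndarray:
    """Per-graph sampling weight (its class weight), for weighted batch draws."""
    return np.array([weights[g.label] for g in graphs], dtype=float)


def draw_weighted_batches(
    n: int,
    weights: np.ndarray,
    batch_size: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """One epoch of class-weighted sampling with replacement, split into batches."""
    p = weights / weights.sum()
    idx = rng.choice(n, size=n, replace=True, p=p)
    return [idx[i : i + batch_size] for i in range(0, n, batch_size)]
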