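"""Synthetic COSMIC-like breakpoint cohorts with controllable class structure.

The generator emulates a structural-variant export: per sample it draws an
aberration count from a negative-binomial-like distribution (spanning sparse
to dense graphs), then per aberration decides intra- vs interchromosomal by a
fixed rate, draws the chromosome pair of an interchromosomal event from a
class-specific signature mixed with uniform background noise, and draws the
single chromosome plus a typed mutation kind for an intrachromosomal event.
Interchromosomal events always carry mutation type "unknown", matching the
convention of real exports; class identity therefore lives entirely in the
interchromosomal pair signature.

The intra rate defaults to 0.75: in real tumor catalogues intrachromosomal
events outnumber interchromosomal ones roughly three to one (e.g. breast
~68k intra vs ~19k inter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .breakpoints import CRERecord, N_CHROMOSOMES, write_breakpoints

#: the six typed mutation kinds an intrachromosomal event may carry
INTRA_TYPES = (
    "inverted orientation",
    "noninverted orientation",
    "inversion",
    "deletion",
    "tandem duplication",
    "insertion",
)


@dataclass
class ClassSpec:
    """One cancer class: its size and interchromosomal pair signature."""

    label: str
    n_samples: int
    signature: dict[tuple[int, int], float]  # ordered (src, sink) -> probability
    intra_rate: float = 0.75
    intra_type_dist: dict[str, float] | None = None  # default: uniform over six

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0 <= self.intra_rate <= 1:
            raise ValueError("intra_rate must be in [0, 1]")
        total = sum(self.signature.values())
        if self.signature and abs(total - 1.0) > 1e-9:
            self.signature = {k: v / total for k, v in self.signature.items()}


@dataclass
class CountDistribution:
    """Negative-binomial aberration count per sample, truncated below at 1.

    ``mean`` sets the expected count; ``dispersion`` is the NB shape parameter
    (smaller = heavier spread between sparse and dense samples).
    """

    mean: float = 120.0
    dispersion: float = 4.0

    def draw(self, rng: np.random.Generator) -> int:
        p = self.dispersion / (self.dispersion + self.mean)
        return max(1, int(rng.negative_binomial(self.dispersion, p)))


@dataclass
class SyntheticConfig:
    classes: list[ClassSpec]
    aberrations_per_sample: CountDistribution = field(default_factory=CountDistribution)
    background_rate: float = 0.1  # mass on uniform random ordered pairs
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_rate <= 1:
            raise ValueError("background_rate must be in [0, 1]")


def _draw_inter_pair(
    rng: np.random.Generator,
    spec: ClassSpec,
    background_rate: float,
) -> tuple[int, int]:
    if spec.signature and rng.random() >= background_rate:
        pairs = list(spec.signature)
        probs = np.array([spec.signature[p] for p in pairs])
        return pairs[rng.choice(len(pairs), p=probs / probs.sum())]
    # uniform background over ordered pairs of distinct chromosomes
    u = int(rng.integers(1, N_CHROMOSOMES + 1))
    v = int(rng.integers(1, N_CHROMOSOMES))
    if v >= u:
        v += 1
    return u, v


def generate_cohort(
    config: SyntheticConfig,
    path: str | Path | None = None,
) -> list[CRERecord]:
    """Generate the cohort; optionally write it as a breakpoint TSV.

    Output is schema-valid for the breakpoint reader with the default column
    map, and fully deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    records: list[CRERecord] = []
    for spec in config.classes:
        type_names = list(spec.intra_type_dist or {t: 1 / len(INTRA_TYPES) for t in INTRA_TYPES})
        type_probs = np.array(
            [(spec.intra_type_dist or {t: 1 / len(INTRA_TYPES) for t in INTRA_TYPES})[t]
             for t in type_names]
        )
        type_probs = type_probs / type_probs.sum()
        for i in range(spec.n_samples):
            sid = f"{spec.label}_s{i:04d}"
            n_ab = config.aberrations_per_sample.draw(rng)
            for _ in range(n_ab):
                if rng.random() < spec.intra_rate:
                    c = int(rng.integers(1, N_CHROMOSOMES + 1))
                    mtype = type_names[rng.choice(len(type_names), p=type_probs)]
                    u = v = c
                else:
                    u, v = _draw_inter_pair(rng, spec, config.background_rate)
                    mtype = "unknown"
                pos_from = int(rng.integers(1, 10**8))
                pos_to = int(rng.integers(1, 10**8))
                records.append(
                    CRERecord(
                        sample_id=sid,
                        cancer_type=spec.label,
                        chrom_from=u,
                        chrom_to=v,
                        mutation_type=mtype,
                        pos_from=pos_from,
                        pos_to=pos_to,
                    )
                )
    if path is not None:
        write_breakpoints(records, path)
    return records


# -- presets ----------------------------------------------------------------

#: Disjoint dominant interchromosomal signatures for the three-class preset.
SEPARABLE_SIGNATURES = {
    "breast": {(1, 2): 0.5, (3, 4): 0.5},
    "pancreatic": {(5, 6): 0.5, (7, 8): 0.5},
    "prostate": {(9, 10): 0.5, (11, 12): 0.5},
}


def make_separable_cohort(
    n_per_class: int = 200,
    seed: int = 0,
    path: str | Path | None = None,
) -> list[CRERecord]:
    """Three classes with disjoint interchromosomal signatures.

    Class signal lives only in the interchromosomal pairs; intrachromosomal
    events are uniform background across classes.  The aberration-count
    distribution spans sparse to dense so the connectivity filter genuinely
    partitions the cohort, with most samples passing the default 0.3
    threshold.
    """
    if n_per_class < 20:
        raise ValueError("n_per_class must be >= 20")
    config = SyntheticConfig(
        classes=[
            ClassSpec(label=label, n_samples=n_per_class, signature=dict(sig),
                      intra_rate=0.5)
            for label, sig in SEPARABLE_SIGNATURES.items()
        ],
        aberrations_per_sample=CountDistribution(mean=100.0, dispersion=2.0),
        background_rate=0.5,
        seed=seed,
    )
    return generate_cohort(config, path=path)


def make_chain_cohort(
    n_per_class: int = 40,
    seed: int = 0,
    path: str | Path | None = None,
) -> list[CRERecord]:
    """Two classes whose signal involves a multi-hop rearrangement chain.

    Class "chained" samples carry the full translocation chain
    1 -> 2 -> 3 -> 4 (signal reachable by deep message passing); class
    "broken" samples carry the same pairs minus the middle link, rerouted to a
    random chromosome.  Both sit on shared uniform background noise.
    """
    rng = np.random.default_rng(seed)
    records: list[CRERecord] = []
    for label in ("chained", "broken"):
        for i in range(n_per_class):
            sid = f"{label}_s{i:04d}"
            if label == "chained":
                core = [(1, 2), (2, 3), (3, 4)]
            else:
                detour = int(rng.integers(13, N_CHROMOSOMES + 1))
                core = [(1, 2), (2, detour), (3, 4)]
            edges = list(core)
            for _ in range(12):  # shared background
                u = int(rng.integers(1, N_CHROMOSOMES + 1))
                v = int(rng.integers(1, N_CHROMOSOMES))
                if v >= u:
                    v += 1
                edges.append((u, v))
            for u, v in edges:
                records.append(
                    CRERecord(
                        sample_id=sid, cancer_type=label,
                        chrom_from=u, chrom_to=v, mutation_type="unknown",
                        pos_from=int(rng.integers(1, 10**8)),
                        pos_to=int(rng.integers(1, 10**8)),
                    )
                )
    if path is not None:
        write_breakpoints(records, path)
    return records
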