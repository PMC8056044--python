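"""Synthetic functional networks with planted disease modules.

The generator emulates the statistical structure the prioritization
analysis assumes in real data:

* a weighted, sparse, undirected gene network whose within-module edges
  are denser and heavier (Beta-distributed weights) than the background;
* a risk-GWAS p-value table whose sub-significance tail is enriched for
  genes of the planted disease modules (signal genes draw
  ``p ~ Beta(a, 1)`` with ``a < 1``, nulls draw Uniform(0, 1));
* an endophenotype p-value table whose signal overlaps the risk signal
  only partially, controlled by ``overlap_frac``.

All draws are pure functions of ``(config, config.seed)``: the network,
each p-value table, and the truth assignment use separate, fixed
substreams of the seed so regenerating any one artifact is stable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from netprio.datatypes import ValidationError

# fixed substream tags so each artifact has its own independent stream
_STREAM_TRUTH = 0
_STREAM_NETWORK = 1
_STREAM_RISK = 2
_STREAM_ENDO = 3


@dataclass
class SynthConfig:
    """Parameters of the planted-module generator.

    Defaults describe the benchmark condition used throughout the test
    suite: 3,000 genes with one planted disease module of 150 genes,
    within-module edges at density 0.3 with Beta(8, 2) weights against
    a background at density 0.02 with Beta(2, 8) weights, and 100
    module genes carrying risk-GWAS signal drawn from Beta(0.1, 1).
    """

    n_genes: int = 3000
    module_sizes: tuple[int, ...] = (150,)
    w_within: tuple[float, float] = (8.0, 2.0)
    w_background: tuple[float, float] = (2.0, 8.0)
    edge_density_within: float = 0.3
    edge_density_background: float = 0.02
    signal_beta_a: float = 0.1
    n_risk_signal: int = 100
    n_endo_signal: int = 100
    contamination_frac: float = 0.0
    overlap_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if any(s < 0 for s in self.module_sizes):
            raise ValidationError("module_sizes entries must be >= 0")
        if sum(self.module_sizes) > self.n_genes:
            raise ValidationError("module_sizes sum exceeds n_genes")
        for name in ("edge_density_within", "edge_density_background",
                     "contamination_frac", "overlap_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 < self.signal_beta_a <= 1.0):
            raise ValidationError(
                f"signal_beta_a must lie in (0, 1], got {self.signal_beta_a}"
            )
        for name in ("w_within", "w_background"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValidationError(f"{name} Beta parameters must be positive")
        if self.n_risk_signal < 0 or self.n_endo_signal < 0:
            raise ValidationError("signal gene counts must be >= 0")


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic instance.

    ``module_of`` maps every gene to a module index where 0 denotes
    background; ``disease_module_ids`` marks the planted disease
    modules; ``risk_signal_genes`` / ``endo_signal_genes`` are the
    genes given low p-values in the respective tables.
    """

    gene_ids: list[str]
    module_of: dict[str, int]
    disease_module_ids: set[int] = field(default_factory=set)
    risk_signal_genes: set[str] = field(default_factory=set)
    endo_signal_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if set(self.gene_ids) != set(self.module_of):
            raise ValidationError("every gene must have exactly one module label")

    @property
    def planted_genes(self) -> set[str]:
        """Genes belonging to any disease module."""
        return {g for g, m in self.module_of.items()
                if m in self.disease_module_ids and m != 0}

    @property
    def background_genes(self) -> set[str]:
        return {g for g, m in self.module_of.items() if m == 0}

    @property
    def held_out_planted(self) -> set[str]:
        """Planted genes with no risk signal — unlabeled true positives."""
        return self.planted_genes - self.risk_signal_genes


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _beta_weights(rng: np.random.Generator, params: tuple[float, float],
                  size: int) -> np.ndarray:
    w = rng.beta(*params, size=size)
    # keep weights strictly inside (0, 1]; Beta draws with shape < 1 can
    # underflow to exactly 0
    return np.clip(w, 1e-12, 1.0)


def _assign_modules(config: SynthConfig) -> tuple[list[str], dict[str, int]]:
    genes = [f"G{i + 1:06d}" for i in range(config.n_genes)]
    module_of = {g: 0 for g in genes}
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        for g in genes[pos:pos + size]:
            module_of[g] = m
        pos += size
    return genes, module_of


def generate_network(config: SynthConfig) -> tuple[nx.Graph, PlantedTruth]:
    """Draw a weighted network and its planted truth.

    Module membership is assigned first; within-module gene pairs are
    linked with probability ``edge_density_within`` and Beta-``w_within``
    weights, all remaining pairs with probability
    ``edge_density_background`` and Beta-``w_background`` weights.
    Non-sampled pairs are simply absent (sparse graph); self-edges are
    never generated.  Signal-gene sets for both GWAS tables are drawn
    here so that one truth object covers the whole instance.
    """
    genes, module_of = _assign_modules(config)
    module_arr = np.array([module_of[g] for g in genes])
    graph = nx.Graph()
    graph.add_nodes_from(genes)

    rng = _rng(config, _STREAM_NETWORK)
    n = config.n_genes

    # background pass over all pairs, row by row to bound memory; pairs
    # inside the same planted module are excluded (handled below)
    for i in range(n - 1):
        js = np.arange(i + 1, n)
        hit = rng.random(js.size) < config.edge_density_background
        same = (module_arr[js] == module_arr[i]) & (module_arr[i] != 0)
        js = js[hit & ~same]
        if js.size:
            w = _beta_weights(rng, config.w_background, js.size)
            graph.add_weighted_edges_from(
                (genes[i], genes[j], float(wj)) for j, wj in zip(js, w)
            )

    # within-module pass
    for m in range(1, len(config.module_sizes) + 1):
        members = [g for g in genes if module_of[g] == m]
        pairs = list(itertools.combinations(members, 2))
        if not pairs:
            continue
        hit = rng.random(len(pairs)) < config.edge_density_within
        kept = [p for p, h in zip(pairs, hit) if h]
        if kept:
            w = _beta_weights(rng, config.w_within, len(kept))
            graph.add_weighted_edges_from(
                (a, b, float(wj)) for (a, b), wj in zip(kept, w)
            )

    truth = _draw_truth(config, genes, module_of)
    return graph, truth


def _draw_truth(config: SynthConfig, genes: list[str],
                module_of: dict[str, int]) -> PlantedTruth:
    rng = _rng(config, _STREAM_TRUTH)
    disease_modules = {m for m in range(1, len(config.module_sizes) + 1)
                       if config.module_sizes[m - 1] > 0}
    planted = sorted(g for g in genes
                     if module_of[g] in disease_modules and module_of[g] != 0)
    background = sorted(g for g in genes if module_of[g] == 0)

    n_contam = int(round(config.contamination_frac * config.n_risk_signal))
    n_from_planted = min(config.n_risk_signal - n_contam, len(planted))
    n_contam = min(n_contam, len(background))
    risk = set(rng.choice(planted, size=n_from_planted, replace=False)) \
        if n_from_planted else set()
    if n_contam:
        risk |= set(rng.choice(background, size=n_contam, replace=False))

    # endo signal: overlap_frac of it re-uses risk-signal genes, the rest
    # comes from planted-but-unlabeled genes, then background
    n_shared = min(int(round(config.overlap_frac * config.n_endo_signal)),
                   len(risk))
    endo = set(rng.choice(sorted(risk), size=n_shared, replace=False)) \
        if n_shared else set()
    remaining = config.n_endo_signal - len(endo)
    pool = sorted(set(planted) - risk)
    take = min(remaining, len(pool))
    if take:
        endo |= set(rng.choice(pool, size=take, replace=False))
        remaining -= take
    pool = sorted(set(background) - risk - endo)
    take = min(remaining, len(pool))
    if take:
        endo |= set(rng.choice(pool, size=take, replace=False))

    return PlantedTruth(
        gene_ids=genes,
        module_of=module_of,
        disease_module_ids=disease_modules,
        risk_signal_genes=risk,
        endo_signal_genes=endo,
    )


def generate_pvalues(truth: PlantedTruth, config: SynthConfig, which: str):
    """Draw a gene-level p-value table for one GWAS source.

    ``which`` selects the signal set: ``"risk"`` uses
    ``truth.risk_signal_genes``, ``"endo"`` uses
    ``truth.endo_signal_genes``.  Signal genes draw
    ``p ~ Beta(signal_beta_a, 1)`` (CDF ``p**a``, stochastically small
    for ``a < 1``); all other genes draw Uniform(0, 1).  Draws lie in
    (0, 1].
    """
    import pandas as pd

    from netprio.datatypes import GenePValueTable

    if which == "risk":
        signal = truth.risk_signal_genes
        rng = _rng(config, _STREAM_RISK)
    elif which == "endo":
        signal = truth.endo_signal_genes
        rng = _rng(config, _STREAM_ENDO)
    else:
        raise ValidationError(f"unknown p-value table label {which!r}")

    n = len(truth.gene_ids)
    # 1 - U gives draws in (0, 1]; Beta(a,1) via inverse CDF p = u**(1/a)
    u = 1.0 - rng.random(n)
    p = u.copy()
    is_signal = np.array([g in signal for g in truth.gene_ids])
    p[is_signal] = u[is_signal] ** (1.0 / config.signal_beta_a)
    p = np.clip(p, 1e-300, 1.0)
    return GenePValueTable(pd.Series(p, index=truth.gene_ids), source_label=which)
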