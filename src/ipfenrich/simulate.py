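"""Synthetic pathway collections with planted enrichment.

The generator emulates the inputs of a literature-mining enrichment study
without any database download:

* a collection of M pathways over a shared gene universe.  A small pool of
  housekeeping-like genes is shared across pathways (heterogeneous
  gene-to-pathway frequencies); every other pathway gene is specific to
  exactly one pathway.  The universe is deliberately larger than the union
  of pathway genes — real text-mined sets contain many genes the pathway
  database does not know;
* node boxes of the three kinds, with multi-gene homolog-group and complex
  boxes drawn from a configurable kind mix — KEGG maps routinely collapse
  gene families and complexes into one box;
* connected node graphs built as a random spanning tree plus
  density-controlled extra edges, so shortest-path importance is never
  degenerate;
* mined gene sets with *planted* enrichment: a coverage fraction of one
  pathway's genes plus noise genes, where noise can be biased toward
  promiscuous (high-pathway-frequency) genes to mimic the famous,
  heavily co-mentioned genes text mining over-reports.

Reproducibility: one integer seed drives named substreams — pathway ``m``
uses ``SeedSequence(seed, spawn_key=(m,))`` — so adding pathways never
perturbs earlier ones, and a fixed config always regenerates the identical
collection and mined set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .pathway_db import (
    Pathway,
    PathwayCollection,
    PathwayNode,
    build_collection,
)

__all__ = ["SimConfig", "universe_genes", "gen_collection", "gen_mined_set"]

_KINDS = ("single", "homolog_group", "complex")
# spawn keys for non-pathway substreams (kept clear of pathway indices)
_PARTITION_KEY = 1 << 20
_MINED_KEY = (1 << 20) + 1


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic enrichment experiment."""

    n_pathways: int = 50
    universe_size: int = 1500
    genes_per_pathway: tuple[int, int] = (12, 30)
    node_kind_mix: tuple[float, float, float] = (0.4, 0.35, 0.25)
    group_size_range: tuple[int, int] = (2, 5)
    edge_density: float = 0.2
    housekeeping_fraction: float = 0.04
    housekeeping_share: float = 0.05
    planted_pathway: str = "pw001"
    coverage: float = 0.6
    noise_genes: int = 3
    noise_promiscuity_bias: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathways < 1:
            raise ValueError("n_pathways must be >= 1")
        if self.universe_size < 1:
            raise ValueError("universe_size must be >= 1")
        lo, hi = self.genes_per_pathway
        if not 1 <= lo <= hi:
            raise ValueError("genes_per_pathway must be an increasing range >= 1")
        glo, ghi = self.group_size_range
        if not 1 <= glo <= ghi:
            raise ValueError("group_size_range must be an increasing range >= 1")
        if ghi > self.universe_size:
            raise ValueError("group sizes exceed the gene universe")
        mix = np.asarray(self.node_kind_mix, dtype=float)
        if mix.shape != (3,) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError(
                "node_kind_mix must be 3 non-negative proportions summing to 1"
            )
        if not 0.0 < self.edge_density <= 1.0:
            raise ValueError("edge_density must lie in (0, 1]")
        if not 0.0 <= self.housekeeping_fraction < 1.0:
            raise ValueError("housekeeping_fraction must lie in [0, 1)")
        if not 0.0 <= self.housekeeping_share <= 1.0:
            raise ValueError("housekeeping_share must lie in [0, 1]")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")
        if self.noise_genes < 0:
            raise ValueError("noise_genes must be >= 0")
        if not 0.0 <= self.noise_promiscuity_bias <= 1.0:
            raise ValueError("noise_promiscuity_bias must lie in [0, 1]")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


def universe_genes(cfg: SimConfig) -> list[str]:
    """The ordered gene universe; the housekeeping pool is the prefix."""
    width = len(str(cfg.universe_size))
    return [f"g{i:0{width}d}" for i in range(1, cfg.universe_size + 1)]


def _n_housekeeping(cfg: SimConfig) -> int:
    return int(round(cfg.housekeeping_fraction * cfg.universe_size))


def _rng(cfg: SimConfig, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(key,)))


def _partition_nodes(
    pid: str, genes: list[str], cfg: SimConfig, rng: np.random.Generator
) -> list[PathwayNode]:
    """Group a pathway's genes into node boxes drawn from the kind mix."""
    glo, ghi = cfg.group_size_range
    nodes: list[PathwayNode] = []
    pos = 0
    while pos < len(genes):
        kind = _KINDS[rng.choice(3, p=cfg.node_kind_mix)]
        size = 1 if kind == "single" else int(rng.integers(glo, ghi + 1))
        size = min(size, len(genes) - pos)
        nodes.append(
            PathwayNode(f"{pid}-n{len(nodes) + 1:02d}", kind, genes[pos : pos + size])
        )
        pos += size
    return nodes


def _random_edges(
    node_ids: list[str], density: float, rng: np.random.Generator
) -> frozenset[tuple[str, str]]:
    """Random spanning tree plus density-controlled extra edges."""
    n = len(node_ids)
    if n < 2:
        return frozenset()
    order = rng.permutation(n)
    edges: set[tuple[str, str]] = set()
    for i in range(1, n):
        j = int(rng.integers(0, i))
        a, b = node_ids[order[i]], node_ids[order[j]]
        edges.add((a, b) if a <= b else (b, a))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = node_ids[i], node_ids[j]
            pair = (a, b) if a <= b else (b, a)
            if pair not in edges and rng.random() < density:
                edges.add(pair)
    return frozenset(edges)


def gen_collection(cfg: SimConfig) -> PathwayCollection:
    """Generate the pathway collection described by ``cfg``."""
    genes = universe_genes(cfg)
    n_hk = _n_housekeeping(cfg)
    hk_pool = genes[:n_hk]
    specific_pool = genes[n_hk:]
    perm = _rng(cfg, _PARTITION_KEY).permutation(specific_pool)

    width = len(str(cfg.n_pathways))
    lo, hi = cfg.genes_per_pathway
    pathways: list[Pathway] = []
    cursor = 0
    for m in range(cfg.n_pathways):
        rng = _rng(cfg, m)
        pid = f"pw{m + 1:0{max(3, width)}d}"
        size = int(rng.integers(lo, hi + 1))
        k_hk = min(int(round(cfg.housekeeping_share * size)), n_hk)
        hk_genes = (
            [hk_pool[i] for i in rng.choice(n_hk, size=k_hk, replace=False)]
            if k_hk
            else []
        )
        n_spec = size - k_hk
        if cursor + n_spec > len(perm):
            raise ValueError(
                "infeasible config: pathway-specific gene demand exceeds the "
                f"universe (need > {len(perm)} non-housekeeping genes)"
            )
        spec_genes = list(perm[cursor : cursor + n_spec])
        cursor += n_spec
        pathway_genes = hk_genes + spec_genes
        rng.shuffle(pathway_genes)
        nodes = _partition_nodes(pid, pathway_genes, cfg, rng)
        edges = _random_edges([n.node_id for n in nodes], cfg.edge_density, rng)
        pathways.append(
            Pathway(pathway_id=pid, nodes=nodes, edges=edges, name=f"synthetic {pid}")
        )
    return build_collection(pathways)


def gen_mined_set(collection: PathwayCollection, cfg: SimConfig) -> set[str]:
    """Sample a mined gene set with planted enrichment.

    ``round(coverage * |planted genes|)`` genes are drawn without
    replacement from the planted pathway, then ``noise_genes`` from the
    rest of the universe (excluding what was already drawn).  Each noise
    draw is biased with probability ``noise_promiscuity_bias`` toward
    promiscuous genes (pathway frequency >= 2), the way text mining
    over-reports famous multi-pathway genes.  At coverage 0 the mined set
    is independent of which pathway is labelled as planted.
    """
    if cfg.planted_pathway not in collection:
        raise ValueError(f"planted pathway {cfg.planted_pathway!r} not in collection")
    rng = _rng(cfg, _MINED_KEY)
    planted_genes = sorted(collection[cfg.planted_pathway].gene_set)
    k = int(round(cfg.coverage * len(planted_genes)))
    core = [planted_genes[i] for i in rng.choice(len(planted_genes), k, replace=False)]

    taken = set(core)
    pool = [g for g in universe_genes(cfg) if g not in taken]
    if cfg.noise_genes > len(pool):
        raise ValueError(
            f"noise request ({cfg.noise_genes}) exceeds available genes ({len(pool)})"
        )
    promiscuous = [g for g in pool if collection.df(g) >= 2]
    ordinary = [g for g in pool if collection.df(g) < 2]
    noise: list[str] = []
    for _ in range(cfg.noise_genes):
        use_prom = promiscuous and (
            not ordinary or rng.random() < cfg.noise_promiscuity_bias
        )
        source = promiscuous if use_prom else ordinary
        idx = int(rng.integers(0, len(source)))
        noise.append(source.pop(idx))
    return set(core) | set(noise)
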