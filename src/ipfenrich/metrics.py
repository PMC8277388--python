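"""The generalized IPF metric grid and the hypergeometric baseline.

Every IPF variant scores a mined gene set T against a pathway P as

    score(T, P) = sum over node boxes j of  Weight(j, P) * Score(T, j)

where the three independent components are

* ``node_weight`` — Weight(j, P): the constant 1, or the softmax of
  shortest-path occurrence counts (:mod:`ipfenrich.path_weights`);
* ``score_rule`` — Score(T, j): the plain sum of mined-member gene weights,
  or the kind-aware aggregation (max for single/homolog boxes, completeness
  coefficient times sum for complexes; :mod:`ipfenrich.node_scoring`);
* ``gene_weight`` — the constant 1, or the inverse-pathway-frequency
  weight (:mod:`ipfenrich.gene_weights`).

The seven named variants are the grid cells a practitioner would actually
use; ``p_value`` is the classical hypergeometric over-representation test
kept as the baseline.  IPF scores rank descending, p-values ascending.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from scipy.stats import hypergeom

from .gene_weights import GeneWeightTable
from .node_scoring import NodeScoreConfig, node_score
from .path_weights import NodeImportance
from .pathway_db import Pathway, PathwayCollection

__all__ = [
    "MetricSpec",
    "METRICS",
    "IPF_VARIANTS",
    "get_metric",
    "ipf_score",
    "HypergeomParams",
    "hypergeom_pvalue",
    "pvalue_rank_score",
]


@dataclass(frozen=True)
class MetricSpec:
    """One cell of the metric grid (or the p-value baseline)."""

    name: str
    node_weight: Literal["one", "softmax"] = "one"
    score_rule: Literal["plain_sum", "aggregated"] = "plain_sum"
    gene_weight: Literal["one", "ipf"] = "one"

    @property
    def is_pvalue(self) -> bool:
        return self.name == "p_value"

    @property
    def uses_softmax(self) -> bool:
        return not self.is_pvalue and self.node_weight == "softmax"

    @property
    def uses_gene_weight(self) -> bool:
        return not self.is_pvalue and self.gene_weight == "ipf"

    @property
    def ascending(self) -> bool:
        """True when smaller scores rank better (only the p-value)."""
        return self.is_pvalue


METRICS: dict[str, MetricSpec] = {
    m.name: m
    for m in (
        MetricSpec("IPF_gene", "one", "plain_sum", "ipf"),
        MetricSpec("IPF_node", "one", "aggregated", "one"),
        MetricSpec("IPF_shortpath", "softmax", "plain_sum", "one"),
        MetricSpec("IPF_shortpath_gene", "softmax", "plain_sum", "ipf"),
        MetricSpec("IPF_shortpath_node", "softmax", "aggregated", "one"),
        MetricSpec("IPF_gene_node", "one", "aggregated", "ipf"),
        MetricSpec("IPF_gene_node_shortpath", "softmax", "aggregated", "ipf"),
        MetricSpec("p_value"),
    )
}

#: The seven IPF variant names, in grid order.
IPF_VARIANTS: tuple[str, ...] = tuple(n for n in METRICS if n != "p_value")


def get_metric(name: str) -> MetricSpec:
    try:
        return METRICS[name]
    except KeyError:
        raise KeyError(
            f"unknown metric {name!r}; choose from {sorted(METRICS)}"
        ) from None


def ipf_score(
    mined: Iterable[str],
    pathway: Pathway,
    weights: GeneWeightTable | None = None,
    importance: NodeImportance | None = None,
    spec: MetricSpec = METRICS["IPF_node"],
) -> float:
    """Score ``mined`` against one pathway under an IPF variant."""
    if spec.is_pvalue:
        raise ValueError(
            "p_value is not an IPF metric; use pvalue_rank_score instead"
        )
    if spec.uses_softmax and importance is None:
        raise ValueError(f"{spec.name} needs a NodeImportance for the pathway")
    cfg = NodeScoreConfig(
        use_gene_weight=spec.uses_gene_weight,
        use_node_aggregation=spec.score_rule == "aggregated",
    )
    mined_set = set(mined)
    total = 0.0
    for node in pathway.nodes:
        s = node_score(node, mined_set, weights, cfg)
        if s == 0.0:
            continue
        w = importance.weights[node.node_id] if spec.uses_softmax else 1.0
        total += w * s
    return total


# ---------------------------------------------------------------------------
# Hypergeometric baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HypergeomParams:
    """Urn-model parameters: universe N, pathway K, sample k, overlap x."""

    universe_size: int
    pathway_size: int
    sample_size: int
    overlap: int

    def __post_init__(self) -> None:
        N, K, k, x = (
            self.universe_size,
            self.pathway_size,
            self.sample_size,
            self.overlap,
        )
        if N < 1:
            raise ValueError("universe_size must be >= 1")
        if not 0 <= K <= N:
            raise ValueError("pathway_size must lie in [0, universe_size]")
        if not 0 <= k <= N:
            raise ValueError("sample_size must lie in [0, universe_size]")
        if not 0 <= x <= min(K, k):
            raise ValueError("overlap must lie in [0, min(pathway_size, sample_size)]")


def hypergeom_pvalue(params: HypergeomParams) -> float:
    """One-sided upper-tail probability P(X >= overlap)."""
    N, K, k, x = (
        params.universe_size,
        params.pathway_size,
        params.sample_size,
        params.overlap,
    )
    # sf(x - 1) = P(X >= x); scipy evaluates the tail in log space internally
    return float(min(1.0, hypergeom.sf(x - 1, N, K, k)))


def pvalue_rank_score(
    mined: Iterable[str], pathway: Pathway, collection: PathwayCollection
) -> float:
    """Hypergeometric p-value of the mined set's overlap with one pathway.

    The background is the union of all genes in the collection; mined genes
    outside the background are ignored, matching the skip-unknown policy of
    the IPF metrics.
    """
    background = collection.genes
    if not background:
        raise ValueError("collection has an empty gene background")
    mined_set = set(mined) & background
    pathway_genes = pathway.gene_set
    params = HypergeomParams(
        universe_size=len(background),
        pathway_size=len(pathway_genes),
        sample_size=len(mined_set),
        overlap=len(mined_set & pathway_genes),
    )
    return hypergeom_pvalue(params)
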