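"""Scoring a mined gene set against a single node box.

The three node kinds are scored differently when aggregation is on:

* ``single`` and ``homolog_group`` boxes take the *maximum* weight among
  their mined members — homologous genes play the same role, so hitting
  several of them is no stronger evidence than hitting the best one;
* ``complex`` boxes take the *sum* of mined-member weights scaled by a
  completeness coefficient |hit| / |box|, because complex subunits must act
  together and a partially covered complex is weaker evidence.

With aggregation off, every box contributes the plain sum of its mined
members' weights.  Gene weights are the inverse-pathway-frequency weights,
or the constant 1 when gene weighting is off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .gene_weights import GeneWeightTable
from .pathway_db import PathwayNode

__all__ = ["NodeScoreConfig", "node_score"]


@dataclass(frozen=True)
class NodeScoreConfig:
    """Which of the two node-level components are active."""

    use_gene_weight: bool = True
    use_node_aggregation: bool = True


def node_score(
    node: PathwayNode,
    mined: Iterable[str],
    weights: GeneWeightTable | None,
    cfg: NodeScoreConfig,
) -> float:
    """Score one node box against a mined gene set (0.0 when disjoint)."""
    if cfg.use_gene_weight and weights is None:
        raise ValueError("gene weighting requested but no weight table given")
    hit = node.genes & set(mined)
    if not hit:
        return 0.0

    def w(g: str) -> float:
        return weights.weight(g) if cfg.use_gene_weight else 1.0

    if not cfg.use_node_aggregation:
        return sum(w(g) for g in hit)
    if node.kind == "complex":
        coeff = len(hit) / len(node.genes)
        return coeff * sum(w(g) for g in hit)
    return max(w(g) for g in hit)
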