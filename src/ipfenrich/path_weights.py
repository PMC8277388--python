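"""Shortest-path node importance within one pathway.

A node that lies between many pairs of other nodes is a topological relay
of the pathway.  For every unordered pair of distinct nodes (r, s) in the
same connected component, an intermediate node j (j not in {r, s}) earns
one count if it lies on at least one shortest r-s path.  The credit is
binary per pair — unlike Brandes betweenness it is not split over the
number of shortest paths.  Endpoints earn nothing for their own pairs, and
disconnected pairs contribute nothing.

The integer counts are turned into a probability-like importance weight by
a softmax (computed with max-subtraction for numerical stability), so the
weights of a pathway's nodes are strictly positive and sum to one.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .pathway_db import Pathway

__all__ = [
    "NodeImportance",
    "shortest_path_counts",
    "softmax_node_weights",
    "node_importance",
    "write_importance_tsv",
]


@dataclass
class NodeImportance:
    """Shortest-path occurrence counts and their softmax weights."""

    counts: dict[str, int]
    weights: dict[str, float]


def shortest_path_counts(pathway: Pathway) -> dict[str, int]:
    """Count, per node, the node pairs it intermediates on a shortest path."""
    order = pathway.node_ids
    n = len(order)
    if n == 0:
        raise ValueError("pathway has no nodes")
    counts = np.zeros(n, dtype=np.int64)
    if n > 2 and pathway.edges:
        adj = nx.to_scipy_sparse_array(pathway.graph(), nodelist=order, format="csr")
        D = _csgraph_shortest_path(adj, method="D", directed=False, unweighted=True)
        r_idx, s_idx = np.triu_indices(n, k=1)
        pair_ok = np.isfinite(D[r_idx, s_idx])
        d_pair = D[r_idx, s_idx]
        for j in range(n):
            on_path = D[r_idx, j] + D[j, s_idx] == d_pair
            counts[j] = np.count_nonzero(
                on_path & pair_ok & (r_idx != j) & (s_idx != j)
            )
    return {node_id: int(c) for node_id, c in zip(order, counts)}


def softmax_node_weights(counts: Mapping[str, int]) -> dict[str, float]:
    """Softmax-normalize counts into weights that sum to one."""
    if not counts:
        raise ValueError("counts must be non-empty")
    keys = list(counts)
    x = np.asarray([counts[k] for k in keys], dtype=float)
    e = np.exp(x - x.max())
    w = e / e.sum()
    return dict(zip(keys, w.tolist()))


def node_importance(pathway: Pathway) -> NodeImportance:
    """Counts plus softmax weights for every node of one pathway."""
    counts = shortest_path_counts(pathway)
    return NodeImportance(counts=counts, weights=softmax_node_weights(counts))


def write_importance_tsv(
    pathway: Pathway, importance: NodeImportance, path: str | os.PathLike
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_id\tcount\tweight\n")
        for node_id in pathway.node_ids:
            fh.write(
                f"{node_id}\t{importance.counts[node_id]}"
                f"\t{importance.weights[node_id]:.10g}\n"
            )
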