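"""Inverse pathway frequency weights for genes.

A gene that appears in few pathways is highly specific to those pathways;
a housekeeping gene that appears everywhere says little about any one of
them.  Mirroring the inverse-document-frequency weighting of information
retrieval, each gene receives

    w(g) = log(M / df(g))

where ``M`` is the number of pathways in the collection and ``df(g)`` the
number of pathways whose gene union contains ``g``.  A gene present in
every pathway weighs exactly 0; weights fall monotonically with pathway
frequency.  The log base only rescales all weights by one positive
constant, so every downstream ranking is invariant to it; the natural log
is the default.

Genes outside the collection (common in text-mined sets) have no defined
frequency.  :meth:`GeneWeightTable.weight` applies a skip-unknown policy,
returning 0 so such genes drop out of every score.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import pandas as pd

from .pathway_db import PathwayCollection

__all__ = ["GeneWeightTable", "ipf_gene_weight", "build_weight_table"]


def _log(x: float, base: float | None) -> float:
    return math.log(x) if base is None else math.log(x, base)


@dataclass
class GeneWeightTable:
    """Per-gene inverse pathway frequency weights over one collection."""

    weights: dict[str, float]
    df: dict[str, int]
    M: int
    log_base: float | None = None  # None = natural log

    def weight(self, gene: str) -> float:
        """Weight of ``gene``; 0.0 for genes outside the collection."""
        return self.weights.get(gene, 0.0)

    def __getitem__(self, gene: str) -> float:
        try:
            return self.weights[gene]
        except KeyError:
            raise KeyError(f"unknown gene {gene!r}: not in any pathway") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self.weights

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.weights),
                "df": [self.df[g] for g in self.weights],
                "weight": [self.weights[g] for g in self.weights],
            }
        ).sort_values("gene", ignore_index=True)

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def ipf_gene_weight(
    collection: PathwayCollection, gene: str, log_base: float | None = None
) -> float:
    """log(M / df) for one gene; raises KeyError for genes in no pathway."""
    df = collection.df(gene)
    if df == 0:
        raise KeyError(f"unknown gene {gene!r}: not in any pathway of the collection")
    return _log(collection.M / df, log_base)


def build_weight_table(
    collection: PathwayCollection, log_base: float | None = None
) -> GeneWeightTable:
    """Weight every gene indexed by the collection."""
    if log_base is not None and log_base <= 0:
        raise ValueError("log_base must be positive")
    M = collection.M
    df = {g: len(pids) for g, pids in collection.gene_index.items()}
    weights = {g: _log(M / d, log_base) for g, d in df.items()}
    return GeneWeightTable(weights=weights, df=df, M=M, log_base=log_base)
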