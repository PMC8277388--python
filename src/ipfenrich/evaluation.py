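"""Pathway ranking and CumPer/AUC evaluation against a key-pathway list.

For a mined gene set, every pathway of the collection is scored under one
metric and the pathways are rank-ordered (IPF variants descending,
p-values ascending; ties broken by pathway id so rankings are
reproducible).  A ranking is evaluated against a reference list of key
pathways through the cumulative-percentage curve

    CumPer(i) = |key ∩ top-i| / |key|,   i = 1..M,

i.e. the recall of the key list within the top i ranked pathways, and its
area AUC = mean_i CumPer(i) in [0, 1].  AUC is maximal exactly when every
key pathway precedes every non-key pathway and minimal when the key
pathways are ranked last.  A precision-at-i denominator (|key ∩ top-i| / i)
is available behind ``mode="precision"``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .gene_weights import GeneWeightTable, build_weight_table
from .metrics import MetricSpec, get_metric, ipf_score, pvalue_rank_score
from .path_weights import NodeImportance, node_importance
from .pathway_db import PathwayCollection

__all__ = [
    "RankEntry",
    "EnrichmentRanking",
    "CumPerCurve",
    "rank_pathways",
    "cumper_curve",
    "compare_metrics",
    "read_gene_list",
    "read_key_list",
    "write_ranking_tsv",
    "write_curve_tsv",
]


class RankEntry(NamedTuple):
    pathway_id: str
    score: float
    rank: int


@dataclass
class EnrichmentRanking:
    """Scored, rank-ordered pathways for one mined gene set."""

    entries: list[RankEntry]
    metric: str

    @property
    def pathway_ids(self) -> list[str]:
        return [e.pathway_id for e in self.entries]

    def rank_of(self, pathway_id: str) -> int:
        for e in self.entries:
            if e.pathway_id == pathway_id:
                return e.rank
        raise KeyError(f"pathway {pathway_id!r} not in ranking")


@dataclass
class CumPerCurve:
    """CumPer values at ranks 1..M and their mean (the AUC)."""

    values: list[float]
    auc: float
    mode: str = "recall"


def rank_pathways(
    mined: Iterable[str],
    collection: PathwayCollection,
    spec: MetricSpec | str,
    *,
    log_base: float | None = None,
    weights: GeneWeightTable | None = None,
    importances: Mapping[str, NodeImportance] | None = None,
) -> EnrichmentRanking:
    """Score and rank every pathway of the collection for one mined set.

    Weight tables and node importances are computed on demand; callers
    evaluating several metrics or mined sets on one collection should
    precompute and pass them.
    """
    if isinstance(spec, str):
        spec = get_metric(spec)
    mined_set = {str(g).strip() for g in mined if str(g).strip()}
    if spec.is_pvalue:
        scores = {
            p.pathway_id: pvalue_rank_score(mined_set, p, collection)
            for p in collection.pathways
        }
    else:
        if spec.uses_gene_weight and weights is None:
            weights = build_weight_table(collection, log_base=log_base)
        if spec.uses_softmax and importances is None:
            importances = {
                p.pathway_id: node_importance(p) for p in collection.pathways
            }
        scores = {
            p.pathway_id: ipf_score(
                mined_set,
                p,
                weights=weights,
                importance=importances[p.pathway_id] if spec.uses_softmax else None,
                spec=spec,
            )
            for p in collection.pathways
        }
    sign = 1.0 if spec.ascending else -1.0
    ordered = sorted(scores.items(), key=lambda kv: (sign * kv[1], kv[0]))
    entries = [
        RankEntry(pathway_id=pid, score=score, rank=i)
        for i, (pid, score) in enumerate(ordered, start=1)
    ]
    return EnrichmentRanking(entries=entries, metric=spec.name)


def cumper_curve(
    ranking: EnrichmentRanking, key: Iterable[str], mode: str = "recall"
) -> CumPerCurve:
    """Cumulative-percentage curve of a ranking against a key-pathway list."""
    key_set = {str(k).strip() for k in key if str(k).strip()}
    if not key_set:
        raise ValueError("key pathway set must be non-empty")
    ranked = ranking.pathway_ids
    missing = key_set - set(ranked)
    if missing:
        raise ValueError(
            f"key pathways absent from ranking: {sorted(missing)}"
        )
    if mode not in ("recall", "precision"):
        raise ValueError("mode must be 'recall' or 'precision'")
    values: list[float] = []
    hits = 0
    for i, pid in enumerate(ranked, start=1):
        if pid in key_set:
            hits += 1
        denom = len(key_set) if mode == "recall" else i
        values.append(hits / denom)
    auc = sum(values) / len(values)
    return CumPerCurve(values=values, auc=auc, mode=mode)


def compare_metrics(
    mined_sets: Mapping[str, Iterable[str]],
    collection: PathwayCollection,
    key: Iterable[str],
    specs: Iterable[MetricSpec | str],
    *,
    log_base: float | None = None,
    mode: str = "recall",
) -> pd.DataFrame:
    """One AUC per (mined-set label, metric): the comparison-table protocol."""
    specs = [get_metric(s) if isinstance(s, str) else s for s in specs]
    key = list(key)
    weights = (
        build_weight_table(collection, log_base=log_base)
        if any(s.uses_gene_weight for s in specs)
        else None
    )
    importances = (
        {p.pathway_id: node_importance(p) for p in collection.pathways}
        if any(s.uses_softmax for s in specs)
        else None
    )
    rows = []
    for label, mined in mined_sets.items():
        mined = set(mined)
        for spec in specs:
            ranking = rank_pathways(
                mined,
                collection,
                spec,
                weights=weights,
                importances=importances,
            )
            curve = cumper_curve(ranking, key, mode=mode)
            rows.append({"label": label, "metric": spec.name, "auc": curve.auc})
    return pd.DataFrame(rows, columns=["label", "metric", "auc"])


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_gene_list(path: str | os.PathLike) -> set[str]:
    """One gene id per line; '#' comments and blank lines ignored."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                out.add(token.split("\t")[0])
    return out


def read_key_list(path: str | os.PathLike) -> set[str]:
    """One pathway id per line; same conventions as :func:`read_gene_list`."""
    return read_gene_list(path)


def write_ranking_tsv(ranking: EnrichmentRanking, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pathway_id\tmetric_name\tscore\trank\n")
        for e in ranking.entries:
            fh.write(f"{e.pathway_id}\t{ranking.metric}\t{e.score:.10g}\t{e.rank}\n")


def write_curve_tsv(curve: CumPerCurve, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tcumper\n")
        for i, v in enumerate(curve.values, start=1):
            fh.write(f"{i}\t{v:.10g}\n")
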