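"""Pathway collections represented as node-box graphs.

A KEGG-style pathway map is a graph whose vertices are *node boxes* rather
than individual genes.  A box may hold a single gene, a set of
interchangeable homologous genes (e.g. AKT1/AKT2/AKT3 drawn as one box), or
the subunits of a protein complex that act jointly.  The enrichment metrics
in this package consume exactly three things from a map: the boxes, the
genes inside each box, and the undirected connectivity between boxes.

Two serializations are supported:

* a KGML dialect (the XML carrier of KEGG maps) restricted to ``gene``
  entries, ``group`` entries and ``relation`` edges — everything else
  (compounds, map links, graphics) is ignored;
* a plain tab-separated dialect used for fixtures and synthetic
  collections (see :func:`parse_pathway_tsv`).
"""

from __future__ import annotations

import os
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "NODE_KINDS",
    "PathwayNode",
    "Pathway",
    "PathwayCollection",
    "parse_kgml",
    "parse_pathway_tsv",
    "write_pathway_tsv",
    "build_collection",
    "load_collection",
    "write_collection",
]

#: Legal node-box kinds.  ``single`` boxes hold exactly one gene,
#: ``homolog_group`` boxes hold interchangeable genes (scored by the best
#: member), ``complex`` boxes hold co-acting subunits (scored by a
#: completeness coefficient).
NODE_KINDS = frozenset({"single", "homolog_group", "complex"})


def _clean_gene(gene: str) -> str:
    g = gene.strip()
    if not g:
        raise ValueError("gene identifiers must be non-empty")
    return g


@dataclass(frozen=True)
class PathwayNode:
    """One node box: a set of gene identifiers with a kind."""

    node_id: str
    kind: str
    genes: frozenset[str]

    def __init__(self, node_id: str, kind: str, genes: Iterable[str]):
        if not str(node_id).strip():
            raise ValueError("node_id must be non-empty")
        if kind not in NODE_KINDS:
            raise ValueError(
                f"unknown node kind {kind!r}; expected one of {sorted(NODE_KINDS)}"
            )
        gene_set = frozenset(_clean_gene(g) for g in genes)
        if not gene_set:
            raise ValueError(f"node {node_id!r} has no genes")
        if kind == "single" and len(gene_set) != 1:
            raise ValueError(
                f"node {node_id!r} is kind=single but holds {len(gene_set)} genes"
            )
        object.__setattr__(self, "node_id", str(node_id))
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "genes", gene_set)


def _norm_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class Pathway:
    """An undirected graph of node boxes with a pathway identifier."""

    pathway_id: str
    nodes: list[PathwayNode]
    edges: frozenset[tuple[str, str]] = frozenset()
    name: str = ""

    def __post_init__(self) -> None:
        if not str(self.pathway_id).strip():
            raise ValueError("pathway_id must be non-empty")
        ids = [n.node_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate node ids in {self.pathway_id!r}: {dupes}")
        known = set(ids)
        norm = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop edge on node {a!r} in {self.pathway_id!r}")
            if a not in known or b not in known:
                raise ValueError(
                    f"edge ({a!r}, {b!r}) references unknown node in {self.pathway_id!r}"
                )
            norm.add(_norm_edge(a, b))
        self.edges = frozenset(norm)
        if not self.nodes:
            raise ValueError(f"pathway {self.pathway_id!r} has no nodes")

    @property
    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    @property
    def gene_set(self) -> frozenset[str]:
        out: set[str] = set()
        for n in self.nodes:
            out |= n.genes
        return frozenset(out)

    def graph(self) -> nx.Graph:
        """The node-box graph as a networkx Graph (isolated nodes included)."""
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges)
        return g


@dataclass
class PathwayCollection:
    """M pathways plus a gene -> pathway-membership index."""

    pathways: list[Pathway]
    gene_index: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pathways:
            raise ValueError("a collection needs at least one pathway")
        ids = [p.pathway_id for p in self.pathways]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pathway ids: {dupes}")
        index: dict[str, set[str]] = {}
        for p in self.pathways:
            for g in p.gene_set:
                index.setdefault(g, set()).add(p.pathway_id)
        self.gene_index = index
        self._by_id = {p.pathway_id: p for p in self.pathways}

    @property
    def M(self) -> int:
        return len(self.pathways)

    @property
    def genes(self) -> set[str]:
        return set(self.gene_index)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._by_id

    def __getitem__(self, pathway_id: str) -> Pathway:
        try:
            return self._by_id[pathway_id]
        except KeyError:
            raise KeyError(f"unknown pathway {pathway_id!r}") from None

    def df(self, gene: str) -> int:
        """Pathway frequency of ``gene`` (number of pathways containing it)."""
        return len(self.gene_index.get(gene, ()))


def build_collection(pathways: Iterable[Pathway]) -> PathwayCollection:
    """Index a list of pathways into a :class:`PathwayCollection`."""
    return PathwayCollection(pathways=list(pathways))


# ---------------------------------------------------------------------------
# KGML dialect
# ---------------------------------------------------------------------------

def parse_kgml(path: str | os.PathLike) -> Pathway:
    """Parse one pathway from a KGML file.

    Interpretation of the dialect:

    * ``<entry type="gene">`` becomes one node box; a multi-gene ``name``
      attribute (whitespace-separated) makes it a ``homolog_group``,
      otherwise ``single``;
    * ``<entry type="group">`` with ``<component>`` children becomes one
      ``complex`` box whose gene set is the union of the referenced gene
      entries; the absorbed components are not emitted as standalone nodes;
    * ``<relation>`` elements become undirected edges.  Relations touching
      an absorbed component are re-attached to its group; relations between
      ignored entry types (compound, map, ...) are dropped; a relation
      referencing an id absent from the document is an error.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        line, col = exc.position
        raise ValueError(
            f"malformed XML in {path}: line {line}, column {col}: {exc}"
        ) from exc
    root = tree.getroot()
    pathway_id = (root.get("name") or path.stem).removeprefix("path:")
    name = root.get("title") or ""

    gene_entries: dict[str, list[str]] = {}
    group_components: dict[str, list[str]] = {}
    other_entries: set[str] = set()
    for entry in root.findall("entry"):
        eid = entry.get("id")
        etype = entry.get("type")
        if eid is None:
            raise ValueError(f"{path}: entry without id attribute")
        if etype == "gene":
            genes = (entry.get("name") or "").split()
            genes = [g for g in genes if g and g.lower() != "undefined"]
            if not genes:
                raise ValueError(f"{path}: gene entry {eid!r} has no gene names")
            gene_entries[eid] = genes
        elif etype == "group":
            comps = [c.get("id") for c in entry.findall("component")]
            comps = [c for c in comps if c]
            if not comps:
                raise ValueError(f"{path}: group entry {eid!r} has no components")
            group_components[eid] = comps
        else:
            other_entries.add(eid)

    absorbed: dict[str, str] = {}  # component entry id -> group entry id
    nodes: list[PathwayNode] = []
    for gid, comps in group_components.items():
        genes: set[str] = set()
        for cid in comps:
            if cid not in gene_entries:
                raise ValueError(
                    f"{path}: group {gid!r} references unknown or non-gene entry {cid!r}"
                )
            genes |= set(gene_entries[cid])
            absorbed[cid] = gid
        nodes.append(PathwayNode(gid, "complex", genes))
    for eid, genes in gene_entries.items():
        if eid in absorbed:
            continue
        kind = "single" if len(set(genes)) == 1 else "homolog_group"
        nodes.append(PathwayNode(eid, kind, genes))

    known = {n.node_id for n in nodes}
    edges: set[tuple[str, str]] = set()
    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        ends = []
        skip = False
        for e in (e1, e2):
            if e in absorbed:
                e = absorbed[e]
            if e in other_entries:
                skip = True  # relation through a compound/map entry: not a box edge
                break
            if e not in known:
                raise ValueError(
                    f"{path}: relation references unknown entry {e!r}"
                )
            ends.append(e)
        if skip:
            continue
        a, b = ends
        if a == b:
            warnings.warn(
                f"{path}: dropping self-relation on entry {a!r}", stacklevel=2
            )
            continue
        edges.add(_norm_edge(a, b))

    return Pathway(pathway_id=pathway_id, nodes=nodes, edges=frozenset(edges), name=name)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------
#
# Tab-separated, '#' starts a comment line.  Records:
#   pathway <tab> <pathway_id> [<tab> <name>]
#   node    <tab> <node_id> <tab> <kind> <tab> <gene,gene,...>
#   edge    <tab> <node_id> <tab> <node_id>

def parse_pathway_tsv(path: str | os.PathLike) -> Pathway:
    """Parse one pathway from the TSV dialect documented in this module."""
    path = Path(path)
    pathway_id: str | None = None
    name = ""
    nodes: list[PathwayNode] = []
    node_ids: set[str] = set()
    edges: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            tag = fields[0]
            try:
                if tag == "pathway":
                    pathway_id = fields[1].strip()
                    name = fields[2].strip() if len(fields) > 2 else ""
                elif tag == "node":
                    _, node_id, kind, genes = fields[:4]
                    if node_id in node_ids:
                        raise ValueError(f"duplicate node id {node_id!r}")
                    node_ids.add(node_id)
                    nodes.append(
                        PathwayNode(node_id, kind, genes.split(","))
                    )
                elif tag == "edge":
                    _, a, b = fields[:3]
                    edges.add(_norm_edge(a.strip(), b.strip()))
                else:
                    raise ValueError(f"unknown record type {tag!r}")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if pathway_id is None:
        pathway_id = path.stem
    return Pathway(pathway_id=pathway_id, nodes=nodes, edges=frozenset(edges), name=name)


def write_pathway_tsv(pathway: Pathway, path: str | os.PathLike) -> None:
    """Serialize a pathway in the TSV dialect (round-trips exactly)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# ipfenrich pathway TSV\n")
        if pathway.name:
            fh.write(f"pathway\t{pathway.pathway_id}\t{pathway.name}\n")
        else:
            fh.write(f"pathway\t{pathway.pathway_id}\n")
        for n in pathway.nodes:
            fh.write(f"node\t{n.node_id}\t{n.kind}\t{','.join(sorted(n.genes))}\n")
        for a, b in sorted(pathway.edges):
            fh.write(f"edge\t{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Collection I/O
# ---------------------------------------------------------------------------

_PARSERS = {".tsv": parse_pathway_tsv, ".xml": parse_kgml, ".kgml": parse_kgml}


def _parse_any(path: Path) -> Pathway:
    try:
        parser = _PARSERS[path.suffix.lower()]
    except KeyError:
        raise ValueError(f"unsupported pathway file type: {path}") from None
    return parser(path)


def load_collection(source: str | os.PathLike) -> PathwayCollection:
    """Load a collection from a directory of pathway files or a list file.

    A directory is scanned (sorted) for ``*.tsv``, ``*.xml`` and ``*.kgml``
    files; a plain file is read as a manifest of pathway-file paths, one per
    line, relative to the manifest's directory.
    """
    source = Path(source)
    if source.is_dir():
        files = sorted(
            p for p in source.iterdir() if p.suffix.lower() in _PARSERS
        )
    else:
        with open(source, encoding="utf-8") as fh:
            files = [
                source.parent / line.strip()
                for line in fh
                if line.strip() and not line.lstrip().startswith("#")
            ]
    if not files:
        raise ValueError(f"no pathway files found under {source}")
    return build_collection(_parse_any(p) for p in files)


def write_collection(collection: PathwayCollection, directory: str | os.PathLike) -> None:
    """Write every pathway as ``<pathway_id>.tsv`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for p in collection.pathways:
        write_pathway_tsv(p, directory / f"{p.pathway_id}.tsv")
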