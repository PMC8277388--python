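import hypothesis
import pytest

from ipfenrich import Pathway, PathwayNode, build_collection

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


def make_pathway(pathway_id, nodes, edges=(), name=""):
    """nodes: iterable of (node_id, kind, genes) triples."""
    return Pathway(
        pathway_id=pathway_id,
        nodes=[PathwayNode(i, k, g) for i, k, g in nodes],
        edges=frozenset(tuple(e) for e in edges),
        name=name,
    )


def chain_pathway(pathway_id, genes):
    """One single-gene node per gene, connected as a path graph."""
    nodes = [(f"n{i}", "single", [g]) for i, g in enumerate(genes)]
    edges = [(f"n{i}", f"n{i+1}") for i in range(len(genes) - 1)]
    return make_pathway(pathway_id, nodes, edges)


@pytest.fixture
def toy_collection():
    """Three small pathways with all node kinds and one shared gene."""
    p1 = make_pathway(
        "pwA",
        [
            ("a1", "single", ["TP53"]),
            ("a2", "homolog_group", ["AKT1", "AKT2", "AKT3"]),
            ("a3", "complex", ["RPTOR", "MTOR", "MLST8", "AKT1S1"]),
        ],
        [("a1", "a2"), ("a2", "a3")],
    )
    p2 = make_pathway(
        "pwB",
        [
            ("b1", "single", ["TP53"]),
            ("b2", "single", ["EGFR"]),
            ("b3", "single", ["KRAS"]),
        ],
        [("b1", "b2"), ("b2", "b3"), ("b1", "b3")],
    )
    p3 = chain_pathway("pwC", ["BRCA1", "BRCA2", "PALB2"])
    return build_collection([p1, p2, p3])
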