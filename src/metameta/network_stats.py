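"""Multilayer interaction networks and their centrality statistics.

Edge tables come in four layers -- protein-protein (ppi), gene-miRNA
(gmi), TF-gene (tf) and chemical-gene (chem) -- and every node carries a
role (gene, mirna, tf or chemical).  Networks are undirected simple
graphs (parallel rows collapse; TF->gene directionality, if present in
the table, is ignored for centrality).  Reported statistics are the
interaction count (degree) and the exact unnormalized shortest-path
betweenness; bridge nodes are those adjacent to members of two
designated gene subsets (e.g. a risk panel and a trait-derived list).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import ValidationError

LAYERS = ("ppi", "gmi", "tf", "chem")
ROLES = ("gene", "mirna", "tf", "chemical")


@dataclass(frozen=True)
class EdgeRecord:
    source: str
    target: str
    layer: str = "ppi"
    score: float | None = None


@dataclass(frozen=True)
class NodeStats:
    node: str
    role: str
    degree: int
    betweenness: float


def build_network(
    edges: Iterable[EdgeRecord],
    role_map: Mapping[str, str],
    allow_self_loops: bool = False,
) -> nx.Graph:
    """Undirected simple graph from typed edge rows.

    Every endpoint must appear in ``role_map``; unknown nodes raise a
    validation error listing the offenders.  Node roles are stored as the
    ``role`` attribute, edge layers/scores on the edges.
    """
    edges = list(edges)
    unknown = sorted(
        {e.source for e in edges if e.source not in role_map}
        | {e.target for e in edges if e.target not in role_map}
    )
    if unknown:
        raise ValidationError(f"nodes missing from the role map: {', '.join(unknown)}")
    graph = nx.Graph()
    for node, role in role_map.items():
        if role not in ROLES:
            raise ValidationError(f"unknown role {role!r} for node {node!r}")
        graph.add_node(node, role=role)
    for e in edges:
        if e.source == e.target and not allow_self_loops:
            continue
        graph.add_edge(e.source, e.target, layer=e.layer, score=e.score)
    return graph


def node_statistics(graph: nx.Graph, normalized: bool = False) -> list[NodeStats]:
    """Degree and exact betweenness for every node, sorted by id."""
    if graph.number_of_nodes() == 0:
        raise ValidationError("node_statistics requires a nonempty graph")
    betweenness = nx.betweenness_centrality(graph, normalized=normalized)
    return [
        NodeStats(
            node=n,
            role=graph.nodes[n].get("role", "gene"),
            degree=graph.degree(n),
            betweenness=float(betweenness[n]),
        )
        for n in sorted(graph.nodes)
    ]


def bridge_nodes(
    graph: nx.Graph,
    set_a: Iterable[str],
    set_b: Iterable[str],
) -> tuple[list[str], list[str]]:
    """Nodes adjacent to both gene subsets, plus the shared members.

    Genes appearing in both input sets are excluded from bridging and
    returned separately as ``shared``.  Bridges are sorted by degree
    descending, then id ascending.
    """
    set_a, set_b = set(set_a), set(set_b)
    shared = sorted(set_a & set_b)
    a = set_a - set(shared)
    b = set_b - set(shared)
    bridges = []
    excluded = a | b | set(shared)
    for n in graph.nodes:
        if n in excluded:
            continue
        nbrs = set(graph.neighbors(n))
        if nbrs & a and nbrs & b:
            bridges.append(n)
    bridges.sort(key=lambda n: (-graph.degree(n), n))
    return bridges, shared


def top_nodes(
    stats: Sequence[NodeStats],
    k: int = 10,
    by: Literal["degree", "betweenness"] = "degree",
) -> list[NodeStats]:
    """Top-k nodes under a stable ranking; ties broken by node id."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if k > len(stats):
        import logging

        logging.getLogger(__name__).warning(
            "top_nodes: k=%d exceeds node count %d; returning all", k, len(stats)
        )
        k = len(stats)
    ranked = sorted(stats, key=lambda s: (-getattr(s, by), s.node))
    return ranked[:k]


def stats_frame(stats: Sequence[NodeStats]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in stats])
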