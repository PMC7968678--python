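"""Genome neighborhood network construction, GO enrichment, and export.

The network for a query protein is a star graph per clustering tier: a
hexagonal query node (the query's protein cluster) connected to an ellipse
node per neighbor cluster observed adjacent to it in at least one genome.
Neighbor node size scales linearly with the raw conservation score, so more
phylogenetically conserved neighborhoods draw the eye first; nonconserved
neighbors (raw score 0) are flagged and drawn at minimal size.

Enrichment of GO terms among the neighborhood genes uses the one-sided
hypergeometric upper tail against the background of all GO-annotated
proteins in the database, with Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy import stats

from .conservation import PhyloScoreTable
from .genome_io import GOAnnotationTable, ValidationError
from .homology import ProteinClustering

NODE_SIZE_MIN = 20.0
NODE_SIZE_MAX = 80.0


@dataclass(frozen=True)
class GNNNode:
    cluster_id: str
    role: str  # "query" | "neighbor"
    shape: str  # "hexagon" | "ellipse"
    size: float
    raw_score: float
    nonconserved: bool = False


@dataclass
class GNNGraph:
    """Star graph of one query cluster and its neighbors at one tier."""

    tier: float
    query_cluster: str
    nodes: list[GNNNode] = field(default_factory=list)
    edges: list[tuple[str, str]] = field(default_factory=list)


class UnmappedQueryError(LookupError):
    pass


def build_gnn(
    query_protein: str,
    clusterings: Mapping[float, ProteinClustering],
    score_tables: Mapping[float, PhyloScoreTable],
    tiers: Sequence[float] | None = None,
    s_min: float = NODE_SIZE_MIN,
    s_max: float = NODE_SIZE_MAX,
) -> dict[float, GNNGraph]:
    """Build one neighborhood star graph per clustering tier.

    ``query_protein`` must be a database protein id (map external queries
    first with :func:`neighborgo.homology.map_query`).  Node size is
    ``s_min + (s_max − s_min) · raw/raw_max``; when every neighbor is
    nonconserved (raw_max = 0) all neighbors get the minimal size.
    """
    if tiers is None:
        tiers = sorted(clusterings, reverse=True)
    graphs: dict[float, GNNGraph] = {}
    for tier in tiers:
        clustering = clusterings[tier]
        try:
            query_cluster = clustering.cluster_of(query_protein)
        except LookupError:
            raise UnmappedQueryError(
                f"protein {query_protein!r} is not in the database at tier "
                f"{tier:g}; map the query onto a database protein first "
                "(homology.map_query)"
            ) from None
        table = score_tables[tier]
        neighbors = table.neighbors_of(query_cluster)
        raws = {nb: table.raw(query_cluster, nb) for nb in neighbors}
        raw_max = max(raws.values(), default=0.0)
        graph = GNNGraph(tier=tier, query_cluster=query_cluster)
        graph.nodes.append(
            GNNNode(
                cluster_id=query_cluster,
                role="query",
                shape="hexagon",
                size=s_max,
                raw_score=0.0,
            )
        )
        for nb in neighbors:
            raw = raws[nb]
            size = s_min + (s_max - s_min) * raw / raw_max if raw_max > 0 else s_min
            graph.nodes.append(
                GNNNode(
                    cluster_id=nb,
                    role="neighbor",
                    shape="ellipse",
                    size=float(size),
                    raw_score=float(raw),
                    nonconserved=bool(raw == 0.0),
                )
            )
            graph.edges.append((query_cluster, nb))
        graphs[tier] = graph
    return graphs


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentRow:
    go_id: str
    x: int        # annotated neighbor genes carrying the term
    n_draw: int   # annotated neighbor genes
    K: int        # background proteins carrying the term
    N: int        # background annotated proteins
    p: float
    p_adj: float


def enrich_go(
    neighbor_gene_set: Iterable[str],
    background_annotations: GOAnnotationTable,
    vocabulary: Sequence[str] | None = None,
) -> list[EnrichmentRow]:
    """GO-term over-representation among neighborhood genes.

    Background = all GO-annotated proteins in the database (restricting to
    annotatable proteins avoids biasing p-values with genes that could never
    carry a term).  One-sided hypergeometric upper tail P(X ≥ x) per term,
    Benjamini–Hochberg adjustment across the tested terms, sorted by p then
    GO id.  Terms with x = 0 are reported with p = 1-ish tails but can never
    appear enriched.
    """
    ann = background_annotations.annotations
    background = [p for p, terms in ann.items() if terms]
    N = len(background)
    neighbors = sorted(set(neighbor_gene_set) & set(background))
    if not neighbors:
        return []
    n_draw = len(neighbors)
    if vocabulary is None:
        observed: set[str] = set()
        for p in background:
            observed |= ann[p]
        vocabulary = sorted(observed)
    rows = []
    pvals = []
    for go in vocabulary:
        K = sum(1 for p in background if go in ann[p])
        x = sum(1 for p in neighbors if go in ann[p])
        if K == 0:
            continue
        p_val = float(stats.hypergeom.sf(x - 1, N, K, n_draw))
        rows.append((go, x, K, min(p_val, 1.0)))
        pvals.append(min(p_val, 1.0))
    if not rows:
        return []
    p_adj = stats.false_discovery_control(pvals, method="bh")
    result = [
        EnrichmentRow(go_id=go, x=x, n_draw=n_draw, K=K, N=N, p=p, p_adj=float(q))
        for (go, x, K, p), q in zip(rows, p_adj)
    ]
    result.sort(key=lambda r: (r.p, r.go_id))
    return result


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def _node_data(node: GNNNode, tier: float) -> dict:
    return {
        "id": node.cluster_id,
        "label": node.cluster_id,
        "score": node.raw_score,
        "role": node.role,
        "shape": node.shape,
        "size": node.size,
        "nonconserved": node.nonconserved,
        "tier": tier,
    }


def export_graph(
    graphs: Mapping[float, GNNGraph] | GNNGraph,
    path: str | Path,
    fmt: str = "cytoscape",
) -> None:
    """Export graphs as Cytoscape-elements JSON or GraphML.

    Each tier is a subgraph: the tier is carried as a data attribute on
    every node and edge, so a single file holds all stringency levels.
    """
    if isinstance(graphs, GNNGraph):
        graphs = {graphs.tier: graphs}
    if fmt == "cytoscape":
        elements: dict[str, list] = {"nodes": [], "edges": []}
        for tier, graph in sorted(graphs.items()):
            for node in graph.nodes:
                elements["nodes"].append({"data": _node_data(node, tier)})
            for src, dst in graph.edges:
                elements["edges"].append(
                    {"data": {"source": src, "target": dst, "tier": tier}}
                )
        Path(path).write_text(json.dumps({"elements": elements}, indent=1) + "\n")
    elif fmt == "graphml":
        g = nx.MultiGraph()
        for tier, graph in sorted(graphs.items()):
            for node in graph.nodes:
                g.add_node(f"{tier:g}|{node.cluster_id}", **_node_data(node, tier))
            for src, dst in graph.edges:
                g.add_edge(f"{tier:g}|{src}", f"{tier:g}|{dst}", tier=tier)
        nx.write_graphml(g, path)
    else:
        raise ValidationError(f"unknown export format {fmt!r}")


def read_cytoscape_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
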