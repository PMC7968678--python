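"""Tiered protein clustering from pairwise similarity hits.

A protein cluster (homologous family proxy) is a connected component of the
undirected similarity graph whose edges are protein pairs with best e-value
at or below the tier cutoff.  Three tiers are used by default: 1e-10, 1e-50
and 1e-100, from permissive to stringent; stricter tiers refine looser ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .genome_io import SimilarityHit, ValidationError, best_hits

logger = logging.getLogger("neighborgo")

DEFAULT_TIERS: tuple[float, ...] = (1e-10, 1e-50, 1e-100)
MAP_E_CUTOFF = 1e-25


@dataclass
class ProteinClustering:
    """Partition of the protein universe at a single e-value tier.

    Cluster ids are stable across runs: each cluster is named by its
    lexicographically smallest member id.
    """

    tier: float
    assignment: dict[str, str]
    _members: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._members:
            for pid, cid in self.assignment.items():
                self._members.setdefault(cid, []).append(pid)
            for m in self._members.values():
                m.sort()

    def clusters(self) -> dict[str, list[str]]:
        return self._members

    def cluster_of(self, protein_id: str) -> str:
        try:
            return self.assignment[protein_id]
        except KeyError:
            raise LookupError(f"unknown protein {protein_id!r}") from None

    def members_of(self, cluster_id: str) -> list[str]:
        try:
            return self._members[cluster_id]
        except KeyError:
            raise LookupError(f"unknown cluster {cluster_id!r}") from None


def symmetric_best_evalue(
    hits: Iterable[SimilarityHit],
) -> dict[tuple[str, str], float]:
    """Best e-value per unordered pair, taking the better direction."""
    sym: dict[tuple[str, str], float] = {}
    for (q, s), hit in best_hits(hits).items():
        if q == s:
            continue  # self-hits ignored by clustering
        key = (q, s) if q < s else (s, q)
        prev = sym.get(key)
        if prev is None or hit.e_value < prev:
            sym[key] = hit.e_value
    return sym


def cluster_proteins(
    hits: Iterable[SimilarityHit],
    protein_universe: Iterable[str],
    tier: float,
) -> ProteinClustering:
    """Connected components at e-value cutoff ``tier`` (inclusive).

    Proteins without any passing hit become singletons.
    """
    if tier <= 0:
        raise ValidationError(f"tier must be > 0, got {tier}")
    universe = set(protein_universe)
    graph = nx.Graph()
    graph.add_nodes_from(universe)
    for (a, b), e in symmetric_best_evalue(hits).items():
        if a not in universe or b not in universe:
            missing = [p for p in (a, b) if p not in universe]
            raise ValidationError(f"hit references unknown protein(s): {missing}")
        if e <= tier:
            graph.add_edge(a, b)
    assignment: dict[str, str] = {}
    for component in nx.connected_components(graph):
        cid = min(component)
        for pid in component:
            assignment[pid] = cid
    return ProteinClustering(tier=tier, assignment=assignment)


def cluster_all_tiers(
    hits: Sequence[SimilarityHit],
    protein_universe: Iterable[str],
    tiers: Sequence[float] = DEFAULT_TIERS,
) -> dict[float, ProteinClustering]:
    universe = list(protein_universe)
    return {t: cluster_proteins(hits, universe, t) for t in tiers}


def map_query(
    query_hits: Iterable[SimilarityHit],
    max_targets: int = 1,
    e_cutoff: float = MAP_E_CUTOFF,
) -> dict[str, list[str]]:
    """Map external query proteins onto database proteins by best hit.

    Per query the hits are ranked by (e-value ascending, bitscore
    descending); at most ``max_targets`` subjects with e ≤ ``e_cutoff`` are
    retained.  Queries with no passing hit are omitted (and logged).
    """
    per_query: dict[str, list[SimilarityHit]] = {}
    for hit in query_hits:
        per_query.setdefault(hit.query_id, []).append(hit)
    mapping: dict[str, list[str]] = {}
    for query, hits_ in sorted(per_query.items()):
        ranked = sorted(hits_, key=lambda h: (h.e_value, -h.bitscore, h.subject_id))
        targets: list[str] = []
        for h in ranked:
            if h.e_value > e_cutoff:
                break
            if h.subject_id not in targets:
                targets.append(h.subject_id)
            if len(targets) >= max_targets:
                break
        if targets:
            mapping[query] = targets
        else:
            logger.info("query %s unmapped (no hit with e <= %g)", query, e_cutoff)
    return mapping


def genome_cluster_content(
    collection, clustering: ProteinClustering
) -> dict[str, set[str]]:
    """Per genome, the set of protein-cluster ids it contains."""
    content: dict[str, set[str]] = {g: set() for g in collection.genome_ids}
    for pid, cid in clustering.assignment.items():
        gene = collection.gene_for_protein(pid)
        content[gene.genome_id].add(cid)
    return content
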