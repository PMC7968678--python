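"""Neighborhood conservation scoring.

The conservation (Phylo) score of a (focal cluster, neighbor cluster) pair
rewards adjacency preserved across *phylogenetically diverse* genomes rather
than raw co-occurrence counts, which would be biased toward densely sampled
clades.  The pipeline is:

1. genome–genome distance = Jaccard distance on shared protein-cluster
   content at a fixed clustering tier;
2. an unrooted neighbor-joining tree over those distances (negative NJ
   branch-length estimates clamped to zero);
3. for a cluster pair, the supporting set S = genomes in which some member
   of the focal cluster shares a called gene neighborhood with some member
   of the neighbor cluster;
4. raw score = 0 if |S| ≤ 1 (nonconserved), else the phylogenetic diversity
   of S — the total branch length of the minimal subtree spanning S;
5. raw scores are discretized to {0,1,2,3}: zero stays 0 and the strictly
   positive training scores are cut at their empirical tertiles
   (linear-interpolation quantiles).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .genome_io import GenomeCollection, ValidationError
from .homology import ProteinClustering, genome_cluster_content
from .neighborhood import NeighborhoodCluster

logger = logging.getLogger("neighborgo")


# ---------------------------------------------------------------------------
# Genome distances
# ---------------------------------------------------------------------------


def genome_distance(genome_a_clusters: set[str], genome_b_clusters: set[str]) -> float:
    """Jaccard distance 1 − |A∩B|/|A∪B| between gene-content sets."""
    union = genome_a_clusters | genome_b_clusters
    if not union:
        raise ValidationError("both genomes have empty cluster content")
    inter = genome_a_clusters & genome_b_clusters
    return 1.0 - len(inter) / len(union)


def build_distance_matrix(
    collection: GenomeCollection, clustering: ProteinClustering
) -> DistanceMatrix:
    """All-pairs gene-content Jaccard distances (G·(G−1)/2 evaluations)."""
    content = genome_cluster_content(collection, clustering)
    ids = collection.genome_ids
    n = len(ids)
    if n < 2:
        raise ValidationError("need at least 2 genomes")
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = genome_distance(content[ids[i]], content[ids[j]])
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=ids)


# ---------------------------------------------------------------------------
# Genome tree
# ---------------------------------------------------------------------------


class GenomeTree:
    """Unrooted genome tree with branch lengths; supports phylogenetic
    diversity queries via edge bipartitions."""

    def __init__(self, tree: TreeNode):
        self.tree = tree
        self.leaf_names = sorted(t.name for t in tree.tips())
        # Precompute, per non-root node, the leaf set below its parent edge.
        self._edges: list[tuple[frozenset[str], float]] = []
        for node in tree.traverse(include_self=False):
            length = node.length or 0.0
            below = frozenset(
                t.name for t in (node.tips() if not node.is_tip() else [node])
            )
            self._edges.append((below, length))
        self._all = frozenset(self.leaf_names)

    @property
    def total_length(self) -> float:
        return sum(length for _below, length in self._edges)

    def phylogenetic_diversity(self, leaves: Iterable[str]) -> float:
        """Total branch length of the minimal subtree spanning ``leaves``.

        An edge belongs to the spanning (Steiner) subtree iff removing it
        separates two members of the leaf set, i.e. both sides of its
        bipartition intersect the set.  Empty or singleton sets span nothing.
        """
        s = frozenset(leaves)
        unknown = s - self._all
        if unknown:
            raise LookupError(f"unknown genomes: {sorted(unknown)}")
        if len(s) <= 1:
            return 0.0
        return float(
            sum(
                length
                for below, length in self._edges
                if (below & s) and (s - below)
            )
        )

    def to_newick(self) -> str:
        return str(self.tree)


def build_tree(distance_matrix: DistanceMatrix) -> GenomeTree:
    """Neighbor-joining tree; negative branch-length estimates clamped to 0.

    Deterministic for a fixed input order.  For exactly two genomes the tree
    is the single edge of length d (split evenly across the two pendant
    branches).
    """
    ids = list(distance_matrix.ids)
    if len(ids) < 2:
        raise ValidationError("need at least 2 genomes to build a tree")
    if len(ids) == 2:
        d = float(distance_matrix[0, 1])
        root = TreeNode(name=None)
        for name in ids:
            root.append(TreeNode(name=name, length=d / 2.0))
        return GenomeTree(root)
    tree = nj(distance_matrix)
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return GenomeTree(tree)


# ---------------------------------------------------------------------------
# Phylo scores
# ---------------------------------------------------------------------------


@dataclass
class PhyloScoreTable:
    """Raw conservation score per (focal cluster, neighbor cluster) pair."""

    tier: float
    scores: dict[tuple[str, str], float]
    supporting: dict[tuple[str, str], frozenset[str]]

    def neighbors_of(self, focal_cluster: str) -> list[str]:
        return sorted(
            nb for (f, nb) in self.scores if f == focal_cluster
        )

    def raw(self, focal_cluster: str, neighbor_cluster: str) -> float:
        try:
            return self.scores[(focal_cluster, neighbor_cluster)]
        except KeyError:
            raise LookupError(
                f"no score for pair ({focal_cluster}, {neighbor_cluster})"
            ) from None


def supporting_genomes(
    focal_cluster: str,
    neighbor_cluster: str,
    neighborhoods: Mapping[tuple[str, str], Sequence[NeighborhoodCluster]],
    clustering: ProteinClustering,
) -> frozenset[str]:
    """Genomes where a focal-cluster member shares a called neighborhood
    with a neighbor-cluster member."""
    if focal_cluster not in clustering.clusters():
        raise LookupError(f"unknown cluster {focal_cluster!r}")
    if neighbor_cluster not in clustering.clusters():
        raise LookupError(f"unknown cluster {neighbor_cluster!r}")
    support: set[str] = set()
    for (genome_id, _contig), clusters in neighborhoods.items():
        for nc in clusters:
            fams = {clustering.assignment.get(p) for p in nc.member_protein_ids}
            if focal_cluster in fams and neighbor_cluster in fams:
                support.add(genome_id)
                break
    return frozenset(support)


def phylo_score(
    focal_cluster: str,
    neighbor_cluster: str,
    neighborhoods: Mapping[tuple[str, str], Sequence[NeighborhoodCluster]],
    tree: GenomeTree,
    clustering: ProteinClustering,
) -> float:
    """Raw conservation score for one cluster pair (0 = nonconserved)."""
    support = supporting_genomes(
        focal_cluster, neighbor_cluster, neighborhoods, clustering
    )
    if len(support) <= 1:
        return 0.0
    return tree.phylogenetic_diversity(support)


def build_score_table(
    neighborhoods: Mapping[tuple[str, str], Sequence[NeighborhoodCluster]],
    clustering: ProteinClustering,
    tree: GenomeTree,
) -> PhyloScoreTable:
    """Score every ordered (focal, neighbor) pair observed in ≥ 1 genome."""
    support: dict[tuple[str, str], set[str]] = {}
    for (genome_id, _contig), clusters in neighborhoods.items():
        for nc in clusters:
            fams = sorted(
                {clustering.assignment[p] for p in nc.member_protein_ids}
            )
            for a, b in combinations(fams, 2):
                support.setdefault((a, b), set()).add(genome_id)
                support.setdefault((b, a), set()).add(genome_id)
    scores: dict[tuple[str, str], float] = {}
    frozen: dict[tuple[str, str], frozenset[str]] = {}
    pd_cache: dict[frozenset[str], float] = {}
    for pair, genomes in support.items():
        fs = frozenset(genomes)
        frozen[pair] = fs
        if len(fs) <= 1:
            scores[pair] = 0.0
        else:
            if fs not in pd_cache:
                pd_cache[fs] = tree.phylogenetic_diversity(fs)
            scores[pair] = pd_cache[fs]
    return PhyloScoreTable(tier=clustering.tier, scores=scores, supporting=frozen)


# ---------------------------------------------------------------------------
# Quantile discretization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuantileBins:
    """Tertile cutoffs for positive raw scores; 0 is its own bin.

    Mapping: 0 → 0; (0, q1] → 1; (q1, q2] → 2; (q2, ∞) → 3.
    """

    q1: float
    q2: float

    def __post_init__(self) -> None:
        if self.q1 > self.q2:
            raise ValidationError(f"q1 {self.q1} > q2 {self.q2}")

    def discretize(self, raw: float) -> int:
        if raw < 0:
            raise ValidationError(f"raw score {raw} < 0")
        if raw == 0:
            return 0
        if raw <= self.q1:
            return 1
        if raw <= self.q2:
            return 2
        return 3


def fit_quantile_bins(raw_scores: Iterable[float]) -> QuantileBins:
    """Tertile cutoffs (linear-interpolation quantiles) of positive scores.

    With fewer than 3 distinct positive scores a degenerate binning
    (q1 = q2 = median of positives) is used, with a warning.
    """
    positive = np.asarray([s for s in raw_scores if s > 0], dtype=float)
    if len(np.unique(positive)) < 3:
        med = float(np.median(positive)) if len(positive) else 0.0
        warnings.warn(
            "fewer than 3 distinct positive scores; using degenerate bins "
            f"q1 = q2 = {med}"
        )
        return QuantileBins(q1=med, q2=med)
    q1, q2 = np.quantile(positive, [1.0 / 3.0, 2.0 / 3.0])
    return QuantileBins(q1=float(q1), q2=float(q2))


def discretize(raw: float, bins: QuantileBins) -> int:
    return bins.discretize(raw)
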