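"""Gene neighborhood calling.

A neighborhood cluster approximates an operon: a maximal run of consecutive
same-strand genes whose intergenic gaps are at most ``max_gap`` (250 bp by
default; overlapping genes have gap ≤ 0 and always join).  Two adjacent
clusters transcribed divergently — the left cluster entirely on the minus
strand, the right entirely on plus, i.e. 5′ ends facing across a shared
upstream region — are merged when the gap between them lies in
[``min_gap``, ``max_gap``] (200–1000 bp by default).

All gaps are measured between annotated gene bounds in 0-based half-open
coordinates: ``gap = start(next) − end(prev)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_io import Gene, GenomeCollection, ValidationError

SAME_STRAND_MAX_GAP = 250
DIVERGENT_MIN_GAP = 200
DIVERGENT_MAX_GAP = 1000


@dataclass(frozen=True)
class NeighborhoodCluster:
    """A coordinate-contiguous cluster of genes on one contig."""

    cluster_id: str
    genome_id: str
    contig_id: str
    members: tuple[Gene, ...]

    @property
    def member_gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.members)

    @property
    def member_protein_ids(self) -> tuple[str, ...]:
        return tuple(g.protein_id for g in self.members)

    @property
    def start(self) -> int:
        return self.members[0].start

    @property
    def end(self) -> int:
        return max(g.end for g in self.members)

    @property
    def strands(self) -> frozenset[str]:
        return frozenset(g.strand for g in self.members)


def _check_sorted(genes: Sequence[Gene]) -> None:
    keys = [g.sort_key for g in genes]
    if keys != sorted(keys):
        raise ValidationError("contig genes must be sorted by (start, end, gene_id)")


def call_same_strand_clusters(
    contig_genes: Sequence[Gene], max_gap: int = SAME_STRAND_MAX_GAP
) -> list[NeighborhoodCluster]:
    """Group consecutive same-strand genes with gaps ≤ ``max_gap`` (inclusive).

    A gene on the opposite strand terminates the current run, so clusters are
    runs of *consecutive* genes; transitive closure along the contig follows
    from chaining adjacent pairs.
    """
    _check_sorted(contig_genes)
    clusters: list[NeighborhoodCluster] = []
    run: list[Gene] = []

    def flush() -> None:
        if run:
            g0 = run[0]
            clusters.append(
                NeighborhoodCluster(
                    cluster_id=f"{g0.genome_id}|{g0.contig_id}|n{len(clusters):04d}",
                    genome_id=g0.genome_id,
                    contig_id=g0.contig_id,
                    members=tuple(run),
                )
            )

    for gene in contig_genes:
        if run:
            prev = run[-1]
            gap = gene.start - prev.end
            if gene.strand == prev.strand and gap <= max_gap:
                run.append(gene)
                continue
            flush()
            run = []
        run.append(gene)
    flush()
    return clusters


def merge_divergent_clusters(
    clusters: Sequence[NeighborhoodCluster],
    min_gap: int = DIVERGENT_MIN_GAP,
    max_gap: int = DIVERGENT_MAX_GAP,
) -> list[NeighborhoodCluster]:
    """Merge adjacent divergently transcribed cluster pairs.

    The left cluster must be entirely on '-' and the right entirely on '+'
    (transcribed away from each other), with
    ``min_gap ≤ start(right) − end(left) ≤ max_gap`` (inclusive bounds).
    Merging is applied once left-to-right: an already-merged (mixed-strand)
    cluster is never re-merged.
    """
    order = sorted(range(len(clusters)), key=lambda i: clusters[i].start)
    ordered = [clusters[i] for i in order]
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValidationError(
                f"clusters {a.cluster_id} and {b.cluster_id} overlap"
            )
    merged: list[NeighborhoodCluster] = []
    i = 0
    while i < len(ordered):
        left = ordered[i]
        if i + 1 < len(ordered):
            right = ordered[i + 1]
            gap = right.start - left.end
            if (
                left.strands == frozenset("-")
                and right.strands == frozenset("+")
                and min_gap <= gap <= max_gap
            ):
                merged.append(
                    NeighborhoodCluster(
                        cluster_id=left.cluster_id + "+d",
                        genome_id=left.genome_id,
                        contig_id=left.contig_id,
                        members=left.members + right.members,
                    )
                )
                i += 2
                continue
        merged.append(left)
        i += 1
    return merged


def call_neighborhoods(
    collection: GenomeCollection,
    max_gap: int = SAME_STRAND_MAX_GAP,
    divergent_min_gap: int = DIVERGENT_MIN_GAP,
    divergent_max_gap: int = DIVERGENT_MAX_GAP,
) -> dict[tuple[str, str], list[NeighborhoodCluster]]:
    """Call clusters (same-strand runs, then divergent merge) per contig."""
    out: dict[tuple[str, str], list[NeighborhoodCluster]] = {}
    for genome_id, contig_id, genes in collection.iter_contigs():
        same = call_same_strand_clusters(genes, max_gap=max_gap)
        out[(genome_id, contig_id)] = merge_divergent_clusters(
            same, min_gap=divergent_min_gap, max_gap=divergent_max_gap
        )
    return out


def neighbors_of(
    protein_id: str,
    clusters: Iterable[NeighborhoodCluster],
) -> set[str]:
    """All other member proteins of ``protein_id``'s neighborhood cluster."""
    for cluster in clusters:
        members = cluster.member_protein_ids
        if protein_id in members:
            return set(members) - {protein_id}
    raise LookupError(f"protein {protein_id!r} not found in any cluster")


def flatten(
    per_contig: dict[tuple[str, str], list[NeighborhoodCluster]]
) -> list[NeighborhoodCluster]:
    return [c for clusters in per_contig.values() for c in clusters]
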