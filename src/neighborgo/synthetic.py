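"""Synthetic genome collections with planted conserved operons.

The generator emulates the statistical structure the neighborhood-based
predictor exploits: protein families co-located as conserved operons across
a clade of genomes, with the focal family of each operon carrying GO labels
that the neighborhood profile should predict.  Every output is written in
exactly the formats the readers consume, so the whole pipeline is testable
without any downloads.

Construction, per genome (one linear contig each):

* a random binary "phylogeny" over the genomes defines clades; each planted
  operon is assigned to a clade covering roughly ``clade_fraction`` of the
  genomes and is laid out as a same-strand block with within-operon gaps
  drawn uniformly from [10, 200] bp (inside the 250 bp neighborhood rule);
* background families are placed as singletons with gaps in [400, 5000] bp
  (outside the rule); an occasional divergent −/+ pair with a gap in
  [200, 1000] bp exercises the divergent-merge rule;
* with probability ``noise`` a non-focal operon member is shuffled out of
  its block into the background;
* within-family similarity hits get e-values ≤ 1e-121 so that all three
  clustering tiers (1e-10/1e-50/1e-100) recover the families exactly;
  cross-family decoy hits get e-values ≥ 1e-4 and never form edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    Gene,
    GenomeCollection,
    GOAnnotationTable,
    SimilarityHit,
    ValidationError,
    default_vocabulary,
    write_gene_table,
    write_go_annotations,
    write_similarity_hits,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic genome collection."""

    n_genomes: int = 30
    n_families: int = 400
    n_planted_operons: int = 12
    operon_size: int = 4
    clade_fraction: float = 0.6
    labels_per_operon: int = 2
    within_gap: tuple[int, int] = (10, 200)
    between_gap: tuple[int, int] = (400, 5000)
    divergent_rate: float = 0.05
    background_presence: float = 0.7
    noise: float = 0.1
    seed: int = 0
    vocabulary: tuple[str, ...] = field(default_factory=default_vocabulary)

    def __post_init__(self) -> None:
        for name in ("clade_fraction", "divergent_rate", "noise",
                     "background_presence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.operon_size < 2:
            raise ValidationError("operon_size must be ≥ 2")
        if self.n_planted_operons * self.operon_size > self.n_families:
            raise ValidationError(
                "planted operons exceed the family capacity: "
                f"{self.n_planted_operons}×{self.operon_size} > {self.n_families}"
            )
        if self.labels_per_operon > len(self.vocabulary):
            raise ValidationError("labels_per_operon exceeds vocabulary size")


@dataclass
class PlantedOperon:
    operon_index: int
    families: tuple[int, ...]      # first member is the focal family
    labels: tuple[str, ...]
    clade: tuple[str, ...]

    @property
    def focal_family(self) -> int:
        return self.families[0]

    @property
    def neighbor_families(self) -> tuple[int, ...]:
        return self.families[1:]


@dataclass
class SyntheticTruth:
    """Ground truth: planted operons, pairs, and informative features."""

    operons: list[PlantedOperon]
    family_proteins: dict[int, list[str]]

    @property
    def planted_pairs(self) -> list[tuple[int, int]]:
        return [
            (op.focal_family, nb)
            for op in self.operons
            for nb in op.neighbor_families
        ]

    def family_cluster_id(self, family: int) -> str:
        """Expected homology-cluster id of a family (smallest member id)."""
        return min(self.family_proteins[family])

    @property
    def informative_feature_clusters(self) -> set[str]:
        """Cluster ids of planted neighbor families (the label-bearing
        feature columns)."""
        return {
            self.family_cluster_id(nb)
            for op in self.operons
            for nb in op.neighbor_families
        }

    def to_json(self) -> str:
        payload = {
            "operons": [asdict(op) for op in self.operons],
            "family_proteins": {
                str(f): pids for f, pids in sorted(self.family_proteins.items())
            },
        }
        return json.dumps(payload, indent=1)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    collection: GenomeCollection
    hits: list[SimilarityHit]
    annotations: GOAnnotationTable
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> None:
        """Write genes.tsv / hits.tsv / annotations.tsv / truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_table(self.collection, outdir / "genes.tsv")
        write_similarity_hits(self.hits, outdir / "hits.tsv")
        write_go_annotations(self.annotations, outdir / "annotations.tsv")
        (outdir / "truth.json").write_text(self.truth.to_json() + "\n")


def _random_clades(
    genome_ids: Sequence[str], rng: np.random.Generator
) -> list[tuple[str, ...]]:
    """Subtree leaf-sets of a random binary join tree over the genomes."""
    groups: list[tuple[str, ...]] = [(g,) for g in genome_ids]
    clades: list[tuple[str, ...]] = []
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        merged = tuple(sorted(groups[i] + groups[j]))
        groups[i] = merged
        groups.pop(j)
        clades.append(merged)
    return clades


def _pick_clade(
    clades: list[tuple[str, ...]],
    target_size: float,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    ranked = sorted(clades, key=lambda c: (abs(len(c) - target_size), c))
    best = abs(len(ranked[0]) - target_size)
    pool = [c for c in ranked if abs(len(c) - target_size) == best]
    return pool[int(rng.integers(len(pool)))]


def simulate_collection(config: SimulationConfig) -> SyntheticDataset:
    """Generate a dataset with planted conserved, labeled operons."""
    rng = np.random.default_rng(config.seed)
    genome_ids = [f"G{i:03d}" for i in range(config.n_genomes)]
    families = list(range(config.n_families))

    # planted operons on distinct families, each assigned a clade and labels
    operon_families = rng.permutation(config.n_families)[
        : config.n_planted_operons * config.operon_size
    ]
    clades = _random_clades(genome_ids, rng)
    target = config.clade_fraction * config.n_genomes
    vocab = list(config.vocabulary)
    operons: list[PlantedOperon] = []
    for o in range(config.n_planted_operons):
        fams = tuple(
            int(f)
            for f in operon_families[
                o * config.operon_size : (o + 1) * config.operon_size
            ]
        )
        labels = tuple(
            vocab[i]
            for i in sorted(rng.choice(len(vocab), size=config.labels_per_operon,
                                       replace=False))
        )
        clade = _pick_clade(clades, target, rng)
        operons.append(
            PlantedOperon(operon_index=o, families=fams, labels=labels, clade=clade)
        )

    operon_family_set = {f for op in operons for f in op.families}
    background_families = [f for f in families if f not in operon_family_set]

    genes: list[Gene] = []
    family_proteins: dict[int, list[str]] = {f: [] for f in families}
    lo_w, hi_w = config.within_gap
    lo_b, hi_b = config.between_gap

    for genome in genome_ids:
        # contents: operon blocks for clades containing this genome,
        # plus a random subset of background families
        blocks: list[list[int]] = []
        loose: list[int] = []
        for op in operons:
            if genome not in op.clade:
                continue
            block = [op.focal_family]
            for fam in op.neighbor_families:
                if rng.random() < config.noise:
                    loose.append(fam)  # shuffled out of the planted block
                else:
                    block.append(fam)
            blocks.append(block)
        for fam in background_families:
            if rng.random() < config.background_presence:
                loose.append(fam)

        items: list[tuple[str, object]] = [("block", b) for b in blocks]
        items += [("single", f) for f in loose]
        order = rng.permutation(len(items))
        items = [items[i] for i in order]

        pos = 0
        pending_divergent = False
        for kind, payload in items:
            if kind == "block":
                strand = "+" if rng.random() < 0.5 else "-"
                fams_in_block = list(payload)
                if strand == "-":
                    fams_in_block = fams_in_block[::-1]
                for idx, fam in enumerate(fams_in_block):
                    length = int(rng.integers(300, 1501))
                    pid = f"{genome}|F{fam:04d}"
                    genes.append(
                        Gene(pid, pid, genome, "c1", pos, pos + length, strand)
                    )
                    family_proteins[fam].append(pid)
                    pos += length
                    if idx < len(fams_in_block) - 1:
                        pos += int(rng.integers(lo_w, hi_w + 1))
                pos += int(rng.integers(lo_b, hi_b + 1))
                pending_divergent = False
            else:
                fam = payload
                length = int(rng.integers(300, 1501))
                if pending_divergent:
                    strand = "+"
                    pending_divergent = False
                elif rng.random() < config.divergent_rate:
                    strand = "-"
                    pending_divergent = True
                else:
                    strand = "+" if rng.random() < 0.5 else "-"
                pid = f"{genome}|F{fam:04d}"
                genes.append(Gene(pid, pid, genome, "c1", pos, pos + length, strand))
                family_proteins[fam].append(pid)
                pos += length
                if pending_divergent:
                    pos += int(rng.integers(200, 1001))  # mergeable divergent gap
                else:
                    pos += int(rng.integers(lo_b, hi_b + 1))

    collection = GenomeCollection.from_genes(genes)

    # similarity hits: within-family chains (+ ring closure) at tiny e-values
    hits: list[SimilarityHit] = []
    for fam in families:
        members = sorted(family_proteins[fam])
        if len(members) < 2:
            continue
        pairs = list(zip(members, members[1:]))
        if len(members) > 2:
            pairs.append((members[-1], members[0]))
        for q, s in pairs:
            hits.append(
                SimilarityHit(
                    query_id=q,
                    subject_id=s,
                    pct_identity=float(rng.uniform(75, 99)),
                    e_value=float(10.0 ** rng.uniform(-180, -121)),
                    bitscore=float(rng.uniform(500, 2000)),
                )
            )
    # cross-family decoys, too weak for any tier
    all_pids = [p for pids in family_proteins.values() for p in pids]
    for _ in range(config.n_families // 10):
        q, s = rng.choice(len(all_pids), size=2, replace=False)
        hits.append(
            SimilarityHit(
                query_id=all_pids[q],
                subject_id=all_pids[s],
                pct_identity=float(rng.uniform(15, 30)),
                e_value=float(10.0 ** rng.uniform(-4, 0)),
                bitscore=float(rng.uniform(20, 40)),
            )
        )

    annotations: dict[str, set[str]] = {}
    for op in operons:
        for pid in family_proteins[op.focal_family]:
            annotations.setdefault(pid, set()).update(op.labels)
    table = GOAnnotationTable(
        annotations=annotations, vocabulary=tuple(vocab)
    )

    truth = SyntheticTruth(operons=operons, family_proteins=family_proteins)
    return SyntheticDataset(
        config=config,
        collection=collection,
        hits=hits,
        annotations=table,
        truth=truth,
    )


def permute_labels(
    labels: pd.DataFrame, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Negative control: permute label rows across instances.

    Per-label prevalence is preserved exactly; the association between
    feature rows and label rows is destroyed.  Returns the permuted matrix
    (original index) and the permutation used, so it can be inverted.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(labels))
    permuted = pd.DataFrame(
        labels.to_numpy()[perm], index=labels.index, columns=labels.columns
    )
    return permuted, perm
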