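"""End-to-end composition of the pipeline stages (library level).

Order of stages: neighborhood calling → protein clustering → genome
distances and tree → conservation scores → quantile bins → feature/label
matrices.  The CLI wraps these with file I/O; tests and scripts call them
in memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from . import conservation, features, homology, neighborhood
from .conservation import GenomeTree, PhyloScoreTable, QuantileBins
from .genome_io import GenomeCollection, GOAnnotationTable, SimilarityHit
from .homology import DEFAULT_TIERS, ProteinClustering


@dataclass
class PreprocessResult:
    """All intermediate artifacts of the shared preprocessing stages."""

    tier: float
    neighborhoods: dict
    clustering: ProteinClustering
    tree: GenomeTree
    score_table: PhyloScoreTable
    bins: QuantileBins
    features: pd.DataFrame
    labels: pd.DataFrame


def preprocess(
    collection: GenomeCollection,
    hits: Sequence[SimilarityHit],
    annotations: GOAnnotationTable,
    tier: float = DEFAULT_TIERS[0],
    max_gap: int = neighborhood.SAME_STRAND_MAX_GAP,
    divergent_min_gap: int = neighborhood.DIVERGENT_MIN_GAP,
    divergent_max_gap: int = neighborhood.DIVERGENT_MAX_GAP,
) -> PreprocessResult:
    """Run every stage up to the training matrices at one modeling tier."""
    nbhd = neighborhood.call_neighborhoods(
        collection,
        max_gap=max_gap,
        divergent_min_gap=divergent_min_gap,
        divergent_max_gap=divergent_max_gap,
    )
    clustering = homology.cluster_proteins(hits, collection.protein_ids, tier)
    dm = conservation.build_distance_matrix(collection, clustering)
    tree = conservation.build_tree(dm)
    table = conservation.build_score_table(nbhd, clustering, tree)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate bins possible on tiny data
        bins = conservation.fit_quantile_bins(table.scores.values())
    X, Y = features.build_training_matrices(
        collection, annotations, clustering, table, bins
    )
    return PreprocessResult(
        tier=tier,
        neighborhoods=nbhd,
        clustering=clustering,
        tree=tree,
        score_table=table,
        bins=bins,
        features=X,
        labels=Y,
    )
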