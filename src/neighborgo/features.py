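"""Genome-neighborhood profile features and the binary label matrix.

An instance is an annotated protein; its feature row is the profile of its
protein cluster: one column per neighbor cluster ever observed adjacent to
the focal cluster, valued by the quantile-binned conservation score
({0,1,2,3}; absent neighbor → 0).  Homologous proteins therefore share a
feature row but remain distinct instances, because their GO annotations may
differ.  The fitted feature-column order (the registry) is serialized with
the model so prediction-time profiles can be aligned: columns unseen at
training are dropped (and counted), missing ones zero-filled.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .conservation import PhyloScoreTable, QuantileBins
from .genome_io import GenomeCollection, GOAnnotationTable
from .homology import ProteinClustering

logger = logging.getLogger("neighborgo")


def build_profile(
    focal_cluster: str,
    score_table: PhyloScoreTable,
    bins: QuantileBins,
) -> dict[str, int]:
    """Binned conservation profile of one focal cluster.

    Returns ``{neighbor_cluster_id: bin}`` over every neighbor cluster with a
    score-table entry for the focal cluster (bin may be 0 for nonconserved
    neighbors).  A focal cluster absent from the table — e.g. always a
    singleton gene — yields an empty (all-zero) profile with a warning.
    """
    neighbors = score_table.neighbors_of(focal_cluster)
    if not neighbors:
        warnings.warn(f"focal cluster {focal_cluster!r} has no scored neighbors")
        return {}
    return {
        nb: bins.discretize(score_table.raw(focal_cluster, nb)) for nb in neighbors
    }


def build_training_matrices(
    collection: GenomeCollection,
    annotations: GOAnnotationTable,
    clustering: ProteinClustering,
    score_table: PhyloScoreTable,
    bins: QuantileBins,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aligned (FeatureMatrix, LabelMatrix) over annotated proteins.

    Instances are proteins with ≥ 1 in-vocabulary GO term that are present
    in the genome collection; feature columns are the sorted union of
    scored neighbor clusters over all instances; label columns follow the
    vocabulary order.  Proteins with zero labels are excluded and counted.
    """
    instances: list[str] = []
    n_excluded = 0
    for pid in sorted(annotations.annotations):
        if not annotations.annotations[pid]:
            n_excluded += 1
            continue
        try:
            collection.gene_for_protein(pid)
        except LookupError:
            n_excluded += 1
            continue
        instances.append(pid)
    if n_excluded:
        logger.info("excluded %d proteins without labels or coordinates", n_excluded)

    profiles: dict[str, dict[str, int]] = {}
    feature_ids: set[str] = set()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # singleton focal clusters are expected
        for pid in instances:
            profile = build_profile(clustering.cluster_of(pid), score_table, bins)
            profiles[pid] = profile
            feature_ids.update(profile)
    columns = sorted(feature_ids)
    features = pd.DataFrame(0, index=instances, columns=columns, dtype="int8")
    for pid, profile in profiles.items():
        for nb, value in profile.items():
            features.at[pid, nb] = value

    vocab = list(annotations.vocabulary)
    labels = pd.DataFrame(0, index=instances, columns=vocab, dtype="int8")
    for pid in instances:
        for go in annotations.annotations[pid]:
            labels.at[pid, go] = 1
    return features, labels


def align_to_registry(
    rows: pd.DataFrame, registry: Sequence[str]
) -> tuple[pd.DataFrame, int]:
    """Align prediction-time profiles to the training feature registry.

    Unseen columns are dropped (count returned); registry columns missing
    from ``rows`` are zero-filled.  Column order follows the registry.
    """
    registry = list(registry)
    unseen = [c for c in rows.columns if c not in set(registry)]
    if unseen:
        logger.info("dropping %d feature columns unseen at training", len(unseen))
    aligned = rows.reindex(columns=registry, fill_value=0)
    return aligned.astype("int8"), len(unseen)


def profiles_to_frame(
    profiles: Mapping[str, Mapping[str, int]], registry: Sequence[str] | None = None
) -> pd.DataFrame:
    """Stack per-instance profiles into a dense frame (missing → 0)."""
    columns = (
        list(registry)
        if registry is not None
        else sorted({c for p in profiles.values() for c in p})
    )
    frame = pd.DataFrame(0, index=list(profiles), columns=columns, dtype="int8")
    for pid, profile in profiles.items():
        for nb, value in profile.items():
            if nb in frame.columns:
                frame.at[pid, nb] = value
    return frame


def save_registry(columns: Iterable[str], path: str | Path) -> None:
    Path(path).write_text(json.dumps(list(columns), indent=0) + "\n")


def load_registry(path: str | Path) -> list[str]:
    return list(json.loads(Path(path).read_text()))
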