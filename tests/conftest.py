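import warnings

import pytest

from neighborgo import evaluation, multilabel
from neighborgo.pipeline import preprocess
from neighborgo.synthetic import (
    SimulationConfig,
    permute_labels,
    simulate_collection,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-operon dataset for unit tests (fast to preprocess)."""
    cfg = SimulationConfig(
        n_genomes=12,
        n_families=80,
        n_planted_operons=4,
        operon_size=3,
        clade_fraction=0.7,
        noise=0.0,
        seed=7,
    )
    return simulate_collection(cfg)


@pytest.fixture(scope="session")
def small_preprocessed(small_dataset):
    return preprocess(
        small_dataset.collection,
        small_dataset.hits,
        small_dataset.annotations,
        tier=1e-10,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 30 genomes, 400 families, 12 planted
    operons of size 4, clade fraction 0.6, noise 0.1, 2 labels/operon."""
    return simulate_collection(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_end_to_end(default_dataset):
    """Preprocess + RAkEL 5-fold CV + permuted control + feature ranking,
    computed once per session."""
    ds = default_dataset
    pre = preprocess(ds.collection, ds.hits, ds.annotations, tier=1e-10)
    spec = multilabel.BaseLearnerSpec(n_trees=100, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = evaluation.cross_validate(
            pre.features, pre.labels, "RAkEL", folds=5, seed=11,
            base_spec=spec, k=3,
        )
        labels_permuted, _ = permute_labels(pre.labels, seed=12)
        control = evaluation.cross_validate(
            pre.features, labels_permuted, "RAkEL", folds=5, seed=11,
            base_spec=spec, k=3,
        )
        ranked = multilabel.rfml_rank_features(pre.features, pre.labels, seed=11)
    return {
        "dataset": ds,
        "pre": pre,
        "report": report,
        "control": control,
        "ranked": ranked,
    }
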