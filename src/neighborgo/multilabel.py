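"""Multi-label learning over genome-neighborhood profiles.

Three problem transformations are provided over a pluggable probabilistic
base learner (random forest by default):

* **BR** (binary relevance) — one binary classifier per label;
* **LP** (label powerset) — one multiclass classifier whose classes are the
  distinct labelsets observed in training; the score of a label is the sum
  of the probabilities of the classes containing it;
* **RAkEL** — an ensemble of LP models, each over a random k-subset of the
  labels; a label's score is the mean of the marginal scores of the members
  covering it.

Every ensemble member uses the *same* base-learner seed, so the reduction
identities RAkEL(k=|L|, m=1) ≡ LP and RAkEL(k=1, full coverage) ≡ BR hold
exactly: members differ by their label subsets, never by their seeds.

Feature selection is a multi-label ReliefF adaptation: feature weights
accumulate the co-variation of per-feature differences with a normalized
Hamming dissimilarity between label rows over k-nearest-neighbor pairs.

A single-label "binary mode" (photosynthetic / not) is included; it reports
a high-confidence flag at a 0.8 probability threshold by default.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier

from .genome_io import ValidationError

FEATURE_RANGE = 3.0  # feature values live in {0,1,2,3}
HIGH_CONFIDENCE_THRESHOLD = 0.8
DEFAULT_MIN_PROB = 0.5


# ---------------------------------------------------------------------------
# Base learner
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaseLearnerSpec:
    """Random-forest base learner configuration.

    ``mtry`` is the number of features sampled per split (sklearn
    ``max_features``): an int, a float fraction, or "sqrt"/"log2".
    """

    n_trees: int = 300
    mtry: int | float | str = "sqrt"
    seed: int = 0

    def make(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.mtry,
            random_state=self.seed,
            n_jobs=1,
        )


class _ConstantScorer:
    """Degenerate member for single-class training columns."""

    def __init__(self, value: float):
        self.value = float(value)

    def score(self, n: int) -> np.ndarray:
        return np.full(n, self.value)


# ---------------------------------------------------------------------------
# RF-ML feature selection (multi-label ReliefF)
# ---------------------------------------------------------------------------


def rfml_rank_features(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    k_nn: int = 10,
    n_sample: int | None = None,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Rank features by multi-label ReliefF weight, descending.

    For each sampled instance i and its ``k_nn`` nearest neighbors j
    (Manhattan distance on features scaled by the feature range 3), the
    update accumulates, with dL = Hamming(label rows)/|L| and
    diff_f = |x_if − x_jf|/3::

        N_dY      += dL
        N_dF[f]   += diff_f
        N_dYdF[f] += dL · diff_f

    and the weight is W[f] = N_dYdF[f]/N_dY − (N_dF[f] − N_dYdF[f])/(M − N_dY)
    with M the total number of accumulated pairs.  Positive weight means the
    feature varies together with the labels.  Ties are broken by feature id.
    """
    if len(features) < 2:
        raise ValidationError("need at least 2 instances to rank features")
    X = features.to_numpy(dtype=float)
    Y = labels.to_numpy(dtype=float)
    n, p = X.shape
    dist = cdist(X, X, metric="cityblock") / FEATURE_RANGE
    d_label = cdist(Y, Y, metric="hamming")  # Hamming / |L|

    rng = np.random.default_rng(seed)
    if n_sample is None or n_sample >= n:
        samples = np.arange(n)
    else:
        samples = np.sort(rng.choice(n, size=n_sample, replace=False))
    k = min(k_nn, n - 1)

    n_dy = 0.0
    n_df = np.zeros(p)
    n_dydf = np.zeros(p)
    for i in samples:
        order = np.argsort(dist[i], kind="stable")
        neighbors = [j for j in order if j != i][:k]
        for j in neighbors:
            dl = d_label[i, j]
            diff = np.abs(X[i] - X[j]) / FEATURE_RANGE
            n_dy += dl
            n_df += diff
            n_dydf += dl * diff
    m_total = float(len(samples) * k)

    if n_dy == 0.0:
        warnings.warn("all label rows identical among neighbor pairs; "
                      "feature weights are all zero")
        weights = np.zeros(p)
    else:
        hit_denom = m_total - n_dy
        miss_term = (n_df - n_dydf) / hit_denom if hit_denom > 0 else np.zeros(p)
        weights = n_dydf / n_dy - miss_term

    ranked = sorted(
        zip(features.columns, weights), key=lambda t: (-t[1], t[0])
    )
    return [(str(f), float(w)) for f, w in ranked]


def select_top_features(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    top_n: int | None,
    k_nn: int = 10,
    seed: int = 0,
) -> list[str]:
    """Top-N feature ids by RF-ML weight (None or N ≥ p → all, rank order)."""
    ranked = rfml_rank_features(features, labels, k_nn=k_nn, seed=seed)
    if top_n is None:
        return [f for f, _ in ranked]
    return [f for f, _ in ranked[:top_n]]


# ---------------------------------------------------------------------------
# Problem transformations
# ---------------------------------------------------------------------------


@dataclass
class _LPMember:
    """One label-powerset model over a subset of the label indices."""

    label_indices: tuple[int, ...]
    labelsets: list[tuple[int, ...]]  # class index -> labelset bits
    model: RandomForestClassifier | _ConstantScorer

    def marginals(self, X: np.ndarray) -> np.ndarray:
        """Per-label positive scores (n × len(label_indices))."""
        sets = np.asarray(self.labelsets, dtype=float)  # C × k
        if isinstance(self.model, _ConstantScorer):
            # single observed labelset: probability 1 for that class
            return np.tile(sets[0], (len(X), 1))
        proba = self.model.predict_proba(X)  # n × C
        return proba @ sets


@dataclass
class MultiLabelModel:
    """A fitted problem-transformation model.

    Stores everything prediction needs: the transformation, the fitted
    members, the feature registry (column order), the label vocabulary, and
    the seeds/subsets used, so that serialized models are self-describing.
    """

    transformation: str  # "BR" | "LP" | "RAkEL" | "binary"
    labels: tuple[str, ...]
    feature_registry: tuple[str, ...]
    base_spec: BaseLearnerSpec
    members: list = field(default_factory=list)
    k: int | None = None
    m: int | None = None
    subsets: tuple[tuple[int, ...], ...] | None = None
    subset_seed: int | None = None

    def predict(self, feature_rows: pd.DataFrame) -> pd.DataFrame:
        """Per-instance per-label scores in [0, 1], rows in input order."""
        if tuple(feature_rows.columns) != self.feature_registry:
            raise ValidationError(
                "feature registry mismatch: align prediction rows with "
                "features.align_to_registry before calling predict"
            )
        X = feature_rows.to_numpy(dtype=float)
        n = len(feature_rows)
        L = len(self.labels)
        if n == 0:
            return pd.DataFrame(
                np.zeros((0, L)), index=feature_rows.index, columns=self.labels
            )
        if self.transformation == "BR":
            cols = [
                mem.score(n)
                if isinstance(mem, _ConstantScorer)
                else mem.predict_proba(X)[:, 1]
                for mem in self.members
            ]
            scores = np.column_stack(cols)
        elif self.transformation == "LP":
            scores = self.members[0].marginals(X)
        elif self.transformation == "RAkEL":
            total = np.zeros((n, L))
            coverage = np.zeros(L)
            for member in self.members:
                marg = member.marginals(X)
                for pos, li in enumerate(member.label_indices):
                    total[:, li] += marg[:, pos]
                    coverage[li] += 1
            uncovered = coverage == 0
            coverage[uncovered] = 1.0
            scores = total / coverage
        elif self.transformation == "binary":
            mem = self.members[0]
            scores = (
                mem.score(n)
                if isinstance(mem, _ConstantScorer)
                else mem.predict_proba(X)[:, 1]
            ).reshape(-1, 1)
        else:  # pragma: no cover
            raise ValidationError(f"unknown transformation {self.transformation!r}")
        return pd.DataFrame(
            np.clip(scores, 0.0, 1.0), index=feature_rows.index, columns=self.labels
        )


def _check_matrices(features: pd.DataFrame, labels: pd.DataFrame) -> None:
    if not features.index.equals(labels.index):
        raise ValidationError("feature and label matrices have different row ids")
    if len(features) == 0:
        raise ValidationError("cannot fit on 0 instances")


def fit_br(
    features: pd.DataFrame, labels: pd.DataFrame, base_spec: BaseLearnerSpec
) -> MultiLabelModel:
    """Binary relevance: one binary classifier per label."""
    _check_matrices(features, labels)
    X = features.to_numpy(dtype=float)
    members: list = []
    for col in labels.columns:
        y = labels[col].to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            warnings.warn(f"label {col} has a single class; using constant scorer")
            members.append(_ConstantScorer(float(y[0])))
        else:
            members.append(base_spec.make().fit(X, y))
    return MultiLabelModel(
        transformation="BR",
        labels=tuple(labels.columns),
        feature_registry=tuple(features.columns),
        base_spec=base_spec,
        members=members,
    )


def _fit_lp_member(
    X: np.ndarray, labels: pd.DataFrame, label_indices: Sequence[int],
    base_spec: BaseLearnerSpec,
) -> _LPMember:
    sub = labels.iloc[:, list(label_indices)].to_numpy(dtype=int)
    labelsets, y = np.unique(sub, axis=0, return_inverse=True)
    sets = [tuple(int(v) for v in row) for row in labelsets]
    if len(sets) < 2:
        warnings.warn("single distinct labelset; using constant scorer")
        model: RandomForestClassifier | _ConstantScorer = _ConstantScorer(1.0)
    else:
        model = base_spec.make().fit(X, y)
    return _LPMember(
        label_indices=tuple(int(i) for i in label_indices),
        labelsets=sets,
        model=model,
    )


def fit_lp(
    features: pd.DataFrame, labels: pd.DataFrame, base_spec: BaseLearnerSpec
) -> MultiLabelModel:
    """Label powerset: one multiclass model over observed labelsets."""
    _check_matrices(features, labels)
    X = features.to_numpy(dtype=float)
    member = _fit_lp_member(X, labels, range(labels.shape[1]), base_spec)
    return MultiLabelModel(
        transformation="LP",
        labels=tuple(labels.columns),
        feature_registry=tuple(features.columns),
        base_spec=base_spec,
        members=[member],
    )


def default_rakel_m(n_labels: int, k: int) -> int:
    return min(2 * n_labels, comb(n_labels, k))


def fit_rakel(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    base_spec: BaseLearnerSpec,
    k: int = 3,
    m: int | None = None,
    seed: int | None = None,
) -> MultiLabelModel:
    """RAkEL: ensemble of LP members over m distinct random k-label subsets.

    Subsets are sampled without replacement with the given seed (defaults to
    the base-learner seed).  A label covered by no member scores 0 with a
    warning; with the default m every label is covered in practice.
    """
    _check_matrices(features, labels)
    L = labels.shape[1]
    if not 1 <= k <= L:
        raise ValidationError(f"k={k} outside [1, {L}]")
    n_possible = comb(L, k)
    if m is None:
        m = default_rakel_m(L, k)
    if m > n_possible:
        raise ValidationError(f"m={m} exceeds C({L},{k})={n_possible}")
    if seed is None:
        seed = base_spec.seed
    rng = np.random.default_rng(seed)
    subsets: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    while len(subsets) < m:
        subset = tuple(sorted(int(i) for i in rng.choice(L, size=k, replace=False)))
        if subset not in seen:
            seen.add(subset)
            subsets.append(subset)
    X = features.to_numpy(dtype=float)
    members = [_fit_lp_member(X, labels, s, base_spec) for s in subsets]
    covered = {i for s in subsets for i in s}
    uncovered = sorted(set(range(L)) - covered)
    if uncovered:
        warnings.warn(
            f"labels with no covering member (scored 0): "
            f"{[labels.columns[i] for i in uncovered]}"
        )
    return MultiLabelModel(
        transformation="RAkEL",
        labels=tuple(labels.columns),
        feature_registry=tuple(features.columns),
        base_spec=base_spec,
        members=members,
        k=k,
        m=m,
        subsets=tuple(subsets),
        subset_seed=seed,
    )


def fit(
    transformation: str,
    features: pd.DataFrame,
    labels: pd.DataFrame,
    base_spec: BaseLearnerSpec,
    **kwargs,
) -> MultiLabelModel:
    """Dispatch by transformation name ("BR", "LP" or "RAkEL")."""
    name = transformation.upper()
    if name == "BR":
        return fit_br(features, labels, base_spec)
    if name == "LP":
        return fit_lp(features, labels, base_spec)
    if name == "RAKEL":
        return fit_rakel(features, labels, base_spec, **kwargs)
    raise ValidationError(f"unknown transformation {transformation!r}")


def predict(model: MultiLabelModel, feature_rows: pd.DataFrame) -> pd.DataFrame:
    return model.predict(feature_rows)


# ---------------------------------------------------------------------------
# Binary (photosynthetic / not) mode
# ---------------------------------------------------------------------------


def binary_mode_fit(
    features: pd.DataFrame,
    positive_set: Iterable[str],
    base_spec: BaseLearnerSpec,
) -> MultiLabelModel:
    """Single-label special case of BR: positive = membership in
    ``positive_set``."""
    positives = set(positive_set)
    y = np.array([1 if pid in positives else 0 for pid in features.index])
    if len(np.unique(y)) < 2:
        warnings.warn("one-class training set; using constant scorer")
        member: RandomForestClassifier | _ConstantScorer = _ConstantScorer(float(y[0]))
    else:
        member = base_spec.make().fit(features.to_numpy(dtype=float), y)
    return MultiLabelModel(
        transformation="binary",
        labels=("positive",),
        feature_registry=tuple(features.columns),
        base_spec=base_spec,
        members=[member],
    )


def binary_mode_predict(
    model: MultiLabelModel,
    feature_rows: pd.DataFrame,
    threshold: float = HIGH_CONFIDENCE_THRESHOLD,
) -> pd.DataFrame:
    """Scores plus a high-confidence flag (score ≥ ``threshold``)."""
    scores = model.predict(feature_rows)["positive"]
    return pd.DataFrame(
        {"score": scores, "flagged": scores >= threshold}, index=feature_rows.index
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: MultiLabelModel, path: str | Path, **metadata) -> None:
    """Serialize a fitted model with self-describing metadata."""
    payload = {
        "format": "neighborgo-model-v1",
        "transformation": model.transformation,
        "metadata": dict(metadata),
        "model": model,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path) -> tuple[MultiLabelModel, dict]:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format") != "neighborgo-model-v1":
        raise ValidationError(f"{path} is not a neighborgo model file")
    return payload["model"], payload["metadata"]
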