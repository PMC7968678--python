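"""Model evaluation: protein-centric F1max, repeated nested cross-validation,
paired Wilcoxon comparison, and the sequence-similarity annotation-transfer
baseline.

F1max is the protein-centric metric used in the CAFA assessments.  At a
score threshold t, a protein i's predicted label set is
P_i(t) = {f : score_i(f) ≥ t}; precision pr_i is averaged over the m(t)
proteins with at least one prediction, recall rc_i over all n proteins, and
F1max is the maximum harmonic mean of the two averages over the 11-point
threshold grid t ∈ {0.0, 0.1, …, 1.0}.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from . import multilabel
from .genome_io import GOAnnotationTable, SimilarityHit, ValidationError
from .multilabel import BaseLearnerSpec, MultiLabelModel

THRESHOLD_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))

#: Hyperparameter grid for nested CV: forest size, features per split, and
#: number of RF-ML-selected features (None = all).
DEFAULT_GRID: tuple[dict, ...] = tuple(
    {"n_trees": nt, "mtry": mt, "top_n": tn}
    for nt in (100, 300, 500)
    for mt in ("sqrt", "log2")
    for tn in (50, 100, 200, None)
)


# ---------------------------------------------------------------------------
# F1max
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvalResult:
    """F1max with its argmax threshold and the full per-threshold curves."""

    f1max: float
    threshold: float
    thresholds: tuple[float, ...]
    avg_pr: tuple[float, ...]
    avg_rc: tuple[float, ...]
    m: tuple[int, ...]
    f1: tuple[float, ...]

    @property
    def precision(self) -> float:
        return self.avg_pr[self.thresholds.index(self.threshold)]

    @property
    def recall(self) -> float:
        return self.avg_rc[self.thresholds.index(self.threshold)]


def f1max(
    truth: Mapping[str, set[str]],
    scores: pd.DataFrame,
    grid: Sequence[float] = THRESHOLD_GRID,
) -> EvalResult:
    """Protein-centric F1max over the threshold grid.

    ``truth`` maps every scored protein to its nonempty true label set;
    ``scores`` is instances × labels with values in [0, 1].  F1(t) is
    defined as 0 when no protein has a prediction (m(t) = 0) or when both
    averages vanish.
    """
    ids = list(scores.index)
    for pid in ids:
        if pid not in truth or not truth[pid]:
            raise ValidationError(f"protein {pid!r} has an empty truth set")
    labels = list(scores.columns)
    label_pos = {f: i for i, f in enumerate(labels)}
    S = scores.to_numpy(dtype=float)
    T = np.zeros_like(S, dtype=bool)
    for r, pid in enumerate(ids):
        for f in truth[pid]:
            if f in label_pos:
                T[r, label_pos[f]] = True
    # recall denominator is |T_i| over *all* true labels, even those
    # outside the scored columns
    n_true_eff = np.array([len(truth[pid]) for pid in ids], dtype=float)

    avg_pr, avg_rc, m_t, f1_t = [], [], [], []
    for t in grid:
        pred = S >= t
        tp = (pred & T).sum(axis=1).astype(float)
        n_pred = pred.sum(axis=1).astype(float)
        has_pred = n_pred >= 1
        m = int(has_pred.sum())
        pr = float((tp[has_pred] / n_pred[has_pred]).mean()) if m else 0.0
        rc = float((tp / n_true_eff).mean())
        if m == 0 or (pr + rc) == 0.0:
            f1 = 0.0
        else:
            f1 = 2.0 * pr * rc / (pr + rc)
        avg_pr.append(pr)
        avg_rc.append(rc)
        m_t.append(m)
        f1_t.append(f1)
    best = int(np.argmax(f1_t))  # first threshold achieving the max
    return EvalResult(
        f1max=f1_t[best],
        threshold=grid[best],
        thresholds=tuple(grid),
        avg_pr=tuple(avg_pr),
        avg_rc=tuple(avg_rc),
        m=tuple(m_t),
        f1=tuple(f1_t),
    )


def truth_from_labels(labels: pd.DataFrame) -> dict[str, set[str]]:
    """Per-instance true label sets from a binary label matrix."""
    return {
        pid: {c for c in labels.columns if labels.at[pid, c] == 1}
        for pid in labels.index
    }


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVFoldResult:
    repetition: int
    fold: int
    params: dict
    f1max: float
    precision: float
    recall: float
    outer_test_ids: frozenset[str]
    inner_fold_hash: str


@dataclass
class CVReport:
    folds: list[CVFoldResult] = field(default_factory=list)

    @property
    def f1max_values(self) -> np.ndarray:
        return np.array([f.f1max for f in self.folds])

    @property
    def mean_f1max(self) -> float:
        return float(self.f1max_values.mean())

    @property
    def sd_f1max(self) -> float:
        return float(self.f1max_values.std(ddof=1)) if len(self.folds) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "n_folds": len(self.folds),
            "mean_f1max": self.mean_f1max,
            "sd_f1max": self.sd_f1max,
            "mean_precision": float(np.mean([f.precision for f in self.folds])),
            "mean_recall": float(np.mean([f.recall for f in self.folds])),
        }


def _fit_eval(
    X_train: pd.DataFrame,
    Y_train: pd.DataFrame,
    X_test: pd.DataFrame,
    Y_test: pd.DataFrame,
    transformation: str,
    params: Mapping,
    seed: int,
) -> EvalResult:
    """Select features on the training split, fit, and score the test split."""
    top_n = params.get("top_n")
    if top_n is not None and top_n < X_train.shape[1]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected = multilabel.select_top_features(
                X_train, Y_train, top_n, seed=seed
            )
        X_train = X_train[selected]
        X_test = X_test[selected]
    spec = BaseLearnerSpec(
        n_trees=params.get("n_trees", 300),
        mtry=params.get("mtry", "sqrt"),
        seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate fold labels are expected
        model = multilabel.fit(transformation, X_train, Y_train, spec)
        scores = model.predict(X_test)
    return f1max(truth_from_labels(Y_test), scores)


def nested_cv(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    transformation: str = "RAkEL",
    grid: Sequence[Mapping] = DEFAULT_GRID,
    outer: int = 5,
    inner: int = 3,
    reps: int = 5,
    seed: int = 0,
) -> CVReport:
    """Repeated nested CV: outer folds estimate generalization, inner folds
    pick the grid point with the best mean inner F1max (ties → first in
    declared grid order).  Folds are shuffled, seeded, unstratified.
    """
    if len(features) < outer:
        raise ValidationError(f"need ≥ {outer} instances for {outer} outer folds")
    ids = np.array(features.index)
    report = CVReport()
    for rep in range(reps):
        outer_kf = KFold(n_splits=outer, shuffle=True,
                         random_state=(seed + 7919 * rep) % 2**31)
        for fold, (tr_idx, te_idx) in enumerate(outer_kf.split(ids)):
            X_tr, Y_tr = features.iloc[tr_idx], labels.iloc[tr_idx]
            X_te, Y_te = features.iloc[te_idx], labels.iloc[te_idx]
            inner_seed = (seed + 7919 * rep + 104729 * (fold + 1)) % 2**31
            inner_kf = KFold(n_splits=inner, shuffle=True, random_state=inner_seed)
            inner_splits = list(inner_kf.split(np.arange(len(X_tr))))
            # leak guard: inner folds are drawn from outer-train only
            inner_ids = {
                tuple(sorted(X_tr.index[v])) for _t, v in inner_splits
            }
            assert all(
                set(chunk) <= set(X_tr.index) for chunk in inner_ids
            ), "inner folds leak outer-test instances"
            best_params, best_score = None, -1.0
            for params in grid:
                fold_scores = []
                for itr, ite in inner_splits:
                    res = _fit_eval(
                        X_tr.iloc[itr], Y_tr.iloc[itr],
                        X_tr.iloc[ite], Y_tr.iloc[ite],
                        transformation, params, inner_seed,
                    )
                    fold_scores.append(res.f1max)
                mean_score = float(np.mean(fold_scores))
                if mean_score > best_score:  # strict: ties keep grid order
                    best_score, best_params = mean_score, dict(params)
            res = _fit_eval(
                X_tr, Y_tr, X_te, Y_te, transformation, best_params, inner_seed
            )
            digest = hashlib.sha256(
                repr(sorted(inner_ids)).encode()
            ).hexdigest()[:16]
            report.folds.append(
                CVFoldResult(
                    repetition=rep,
                    fold=fold,
                    params=best_params,
                    f1max=res.f1max,
                    precision=res.precision,
                    recall=res.recall,
                    outer_test_ids=frozenset(X_te.index),
                    inner_fold_hash=digest,
                )
            )
    return report


def cross_validate(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    transformation: str = "RAkEL",
    folds: int = 5,
    seed: int = 0,
    base_spec: BaseLearnerSpec | None = None,
    **fit_kwargs,
) -> CVReport:
    """Plain (non-nested) k-fold CV at fixed hyperparameters."""
    if base_spec is None:
        base_spec = BaseLearnerSpec(seed=seed)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed % 2**31)
    report = CVReport()
    ids = np.arange(len(features))
    for fold, (tr, te) in enumerate(kf.split(ids)):
        X_tr, Y_tr = features.iloc[tr], labels.iloc[tr]
        X_te, Y_te = features.iloc[te], labels.iloc[te]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = multilabel.fit(transformation, X_tr, Y_tr, base_spec, **fit_kwargs)
            scores = model.predict(X_te)
        res = f1max(truth_from_labels(Y_te), scores)
        report.folds.append(
            CVFoldResult(
                repetition=0,
                fold=fold,
                params={"base_spec": base_spec, **fit_kwargs},
                f1max=res.f1max,
                precision=res.precision,
                recall=res.recall,
                outer_test_ids=frozenset(X_te.index),
                inner_fold_hash="",
            )
        )
    return report


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank comparison
# ---------------------------------------------------------------------------


def wilcoxon_compare(
    metric_vector_a: Sequence[float], metric_vector_b: Sequence[float]
) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (Wilcoxon convention); the exact null
    distribution is used for ≤ 25 nonzero pairs, the normal approximation
    with continuity correction above that.  Degenerate inputs (all-zero
    differences, or a single pair) return p = 1.0 with a warning.
    """
    a = np.asarray(metric_vector_a, dtype=float)
    b = np.asarray(metric_vector_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired vectors must have equal length")
    d = a - b
    n_nonzero = int(np.count_nonzero(d))
    if n_nonzero == 0:
        warnings.warn("all paired differences are zero; p = 1.0")
        return 1.0
    if len(d) < 2:
        warnings.warn("fewer than 2 pairs; p = 1.0 (insufficient data)")
        return 1.0
    method = "exact" if n_nonzero <= 25 else "approx"
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", correction=True, method=method
    )
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Annotation-transfer baseline
# ---------------------------------------------------------------------------


def blast_transfer_baseline(
    query_ids: Iterable[str],
    train_annotations: GOAnnotationTable,
    query_hits: Iterable[SimilarityHit],
    e_cutoff: float,
) -> pd.DataFrame:
    """Transfer the best passing hit's training labels to each query.

    The best hit (minimum e-value, tie → maximum bitscore) is used if its
    e-value passes the cutoff; the transferred labels are scored by the
    hit's percent identity / 100.  Queries without a passing hit get an
    all-zero row.
    """
    vocab = list(train_annotations.vocabulary)
    per_query: dict[str, SimilarityHit] = {}
    for hit in query_hits:
        if hit.e_value > e_cutoff:
            continue
        prev = per_query.get(hit.query_id)
        if prev is None or (hit.e_value, -hit.bitscore) < (
            prev.e_value, -prev.bitscore
        ):
            per_query[hit.query_id] = hit
    ids = list(query_ids)
    scores = pd.DataFrame(0.0, index=ids, columns=vocab)
    for query in ids:
        hit = per_query.get(query)
        if hit is None:
            continue
        terms = train_annotations.annotations.get(hit.subject_id, set())
        for go in terms:
            scores.at[query, go] = hit.pct_identity / 100.0
    return scores
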