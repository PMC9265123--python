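"""Baseline classifiers on flat per-aberration features.

The comparison models see each aberration independently as a one-hot vector:
source chromosome (24) + sink chromosome (24) + mutation type (7) = 55
columns.  Unlike the graph classifier they have no access to co-occurrence
structure within a sample, which is the point of the comparison.

Splitting is by sample, not by aberration, so no sample leaks rows into both
sides.  Evaluation can be per aberration (``per_sample=False``, the default)
or with one majority-voted prediction per sample (``per_sample=True``).
The learners themselves are standard scikit-learn estimators; this module is
the harness around them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .breakpoints import CRERecord, MUTATION_TYPES, N_CHROMOSOMES
from .metrics import EvalReport, report_from_labels

BASELINE_NAMES = ("vanilla_nn", "svm_linear", "svm_poly", "knn")

_TYPE_INDEX = {t: i for i, t in enumerate(MUTATION_TYPES)}
FEATURE_DIM = 2 * N_CHROMOSOMES + len(MUTATION_TYPES)


@dataclass
class AberrationFeatures:
    """One row per aberration: [src one-hot | sink one-hot | type one-hot]."""

    X: np.ndarray
    y: list[str]
    sample_ids: list[str]


def featurize_aberrations(records: Sequence[CRERecord]) -> AberrationFeatures:
    X = np.zeros((len(records), FEATURE_DIM))
    y, sids = [], []
    for i, r in enumerate(records):
        X[i, r.chrom_from - 1] = 1.0
        X[i, N_CHROMOSOMES + r.chrom_to - 1] = 1.0
        X[i, 2 * N_CHROMOSOMES + _TYPE_INDEX[r.mutation_type]] = 1.0
        y.append(r.cancer_type)
        sids.append(r.sample_id)
    return AberrationFeatures(X=X, y=y, sample_ids=sids)


def _make_estimator(name: str, params: Mapping, seed: int):
    params = dict(params or {})
    if name == "vanilla_nn":
        # three hidden layers of 60 ReLU units
        return MLPClassifier(
            hidden_layer_sizes=params.pop("hidden_layer_sizes", (60, 60, 60)),
            activation="relu",
            max_iter=params.pop("max_iter", 300),
            random_state=seed,
            **params,
        )
    if name == "svm_linear":
        return SVC(kernel="linear", random_state=seed, **params)
    if name == "svm_poly":
        return SVC(kernel="poly", degree=params.pop("degree", 3), random_state=seed, **params)
    if name == "knn":
        k = int(params.pop("k", 5))
        metric = params.pop("metric", "minkowski")
        if metric == "mahalanobis":
            # covariance is singular on one-hot blocks; ridge-regularize
            return ("mahalanobis", k, params)
        return KNeighborsClassifier(n_neighbors=k, metric=metric, **params)
    raise ValueError(f"unknown baseline {name!r}; options: {BASELINE_NAMES}")


def _knn_mahalanobis(X_train: np.ndarray, k: int, ridge: float = 1e-3):
    cov = np.cov(X_train, rowvar=False) + ridge * np.eye(X_train.shape[1])
    return KNeighborsClassifier(
        n_neighbors=k, metric="mahalanobis",
        metric_params={"VI": np.linalg.inv(cov)},
    )


def run_baseline(
    name: str,
    features: AberrationFeatures,
    split_seed: int,
    params: Mapping | None = None,
    test_fraction: float = 0.2,
    per_sample: bool = False,
) -> EvalReport:
    """Fit one baseline and report test metrics.

    The sample-id set is split (stratified by sample label) and rows follow
    their sample, so aberrations of one sample never straddle the split.
    """
    if name not in BASELINE_NAMES:
        raise ValueError(f"unknown baseline {name!r}; options: {BASELINE_NAMES}")
    params = dict(params or {})
    sample_label = {}
    for sid, label in zip(features.sample_ids, features.y):
        sample_label.setdefault(sid, label)
    sids = sorted(sample_label)
    labels = [sample_label[s] for s in sids]
    train_ids, test_ids = train_test_split(
        sids, test_size=test_fraction, stratify=labels, random_state=split_seed
    )
    train_ids, test_ids = set(train_ids), set(test_ids)
    in_train = np.array([s in train_ids for s in features.sample_ids])
    X_tr, X_te = features.X[in_train], features.X[~in_train]
    y = np.array(features.y)
    y_tr, y_te = y[in_train], y[~in_train]
    sid_te = np.array(features.sample_ids)[~in_train]

    est = _make_estimator(name, params, split_seed)
    if isinstance(est, tuple):  # deferred mahalanobis construction
        _, k, extra = est
        est = _knn_mahalanobis(X_tr, k, **extra)
    est.fit(X_tr, y_tr)
    pred = est.predict(X_te)

    class_order = sorted(set(features.y))
    if not per_sample:
        return report_from_labels(list(y_te), list(pred), class_order, unit="aberrations")
    # majority vote per sample
    true_s, pred_s = [], []
    for sid in sorted(set(sid_te)):
        mask = sid_te == sid
        true_s.append(y_te[mask][0])
        vals, counts = np.unique(pred[mask], return_counts=True)
        pred_s.append(vals[counts.argmax()])
    return report_from_labels(true_s, pred_s, class_order, unit="graphs")
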