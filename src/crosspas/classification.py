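"""Subtype classification of new samples with a K-nearest-neighbor model.

The classifier memorizes the training PAS panel matrix and labels and
predicts by majority vote among the 5 nearest training samples under
Euclidean distance (Minkowski power 2, leaf size 30 for the search index —
the leaf size only affects lookup speed, never the prediction).  The
continuous risk score is the fraction of neighbors labelled G2, which
feeds the C-index and ROC downstream.  Vote ties (impossible at k = 5 with
two classes, possible under config overrides) break toward the lower-risk
label to avoid over-calling the aggressive subtype.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors

from .io_formats import SurvivalTable
from .subtyping import risk_order


@dataclass
class SplitSpec:
    """A 4:1 train/test partition, stratified by event status."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int
    ratio: float = 0.8
    stratified_by_event: bool = True

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


@dataclass
class ClassifierModel:
    """KNN subtype classifier with the pipeline's fixed hyperparameters."""

    train_X: np.ndarray  # (n_train, n_panel_features)
    train_labels: list[str]
    feature_ids: list[str]
    n_neighbors: int = 5
    leaf_size: int = 30
    minkowski_power: int = 2
    _index: NearestNeighbors | None = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "n_neighbors": self.n_neighbors,
            "leaf_size": self.leaf_size,
            "minkowski_power": self.minkowski_power,
            "feature_ids": list(self.feature_ids),
            "train_labels": list(self.train_labels),
            "train_X": self.train_X.tolist(),
        }


def split_train_test(
    sample_ids: list[str], surv: SurvivalTable, seed: int, *, train_fraction: float = 0.8
) -> SplitSpec:
    """Random 4:1 split stratified by the event indicator; deterministic under seed.

    |train| = floor(train_fraction * n) (within stratification rounding),
    remainder to test.
    """
    if surv.sample_ids != list(sample_ids):
        surv = surv.subset(list(sample_ids))
    n = len(sample_ids)
    n_test = n - int(np.floor(train_fraction * n))
    # stratification needs at least one test and one train slot per stratum
    counts = np.bincount(surv.event, minlength=2)
    stratify = surv.event if (n_test >= 2 and counts.min() >= 2) else None
    train_ids, test_ids = train_test_split(
        list(sample_ids),
        train_size=train_fraction,
        stratify=stratify,
        random_state=seed,
    )
    return SplitSpec(train_ids=list(train_ids), test_ids=list(test_ids), seed=seed,
                     ratio=train_fraction, stratified_by_event=stratify is not None)


def train_knn(
    X: np.ndarray,
    labels: list[str],
    feature_ids: list[str],
    *,
    n_neighbors: int = 5,
    leaf_size: int = 30,
    minkowski_power: int = 2,
) -> ClassifierModel:
    """Store the training panel matrix and labels; the only 'fit' is the search index."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(labels) or X.shape[1] != len(feature_ids):
        raise ValueError("training matrix must be (n_samples, n_panel_features)")
    if X.shape[0] < n_neighbors:
        raise ValueError(f"need at least {n_neighbors} training samples, have {X.shape[0]}")
    if len(set(labels)) < 2:
        raise ValueError("training labels contain a single class")
    return ClassifierModel(
        train_X=X,
        train_labels=list(labels),
        feature_ids=list(feature_ids),
        n_neighbors=n_neighbors,
        leaf_size=leaf_size,
        minkowski_power=minkowski_power,
    )


def predict(model: ClassifierModel, X: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Majority-vote labels and G2-neighbor-fraction risk scores for new samples.

    Vote ties break toward the lower-risk label (G1 before G1a... before G2).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_ids):
        raise ValueError("prediction needs exactly the panel features, in panel order")
    if model._index is None:
        model._index = NearestNeighbors(
            n_neighbors=model.n_neighbors,
            leaf_size=model.leaf_size,
            p=model.minkowski_power,
        ).fit(model.train_X)
    _, nbr_idx = model._index.kneighbors(X)
    labels_arr = np.asarray(model.train_labels, dtype=object)
    out_labels: list[str] = []
    scores = np.empty(X.shape[0])
    for i, nbrs in enumerate(nbr_idx):
        votes = Counter(labels_arr[nbrs])
        top = max(votes.values())
        winner = min((l for l, c in votes.items() if c == top), key=risk_order)
        out_labels.append(str(winner))
        scores[i] = votes.get("G2", 0) / model.n_neighbors
    return out_labels, scores


def cross_validate(
    X: np.ndarray, labels: list[str], *, folds: int = 10, seed: int = 0, **knn_kwargs
) -> dict:
    """Stratified k-fold CV of the KNN classifier: per-fold accuracy and AUC.

    A minority class smaller than ``folds`` reduces the fold count to that
    class size (warned in the returned dict).  AUC uses the G2-fraction
    score and is only defined on folds containing both classes.
    """
    from .evaluation import roc_auc

    X = np.asarray(X, dtype=float)
    labels_arr = np.asarray(labels, dtype=object)
    counts = Counter(labels)
    minority = min(counts.values())
    notes = []
    if minority < folds:
        notes.append(f"folds reduced from {folds} to minority class size {minority}")
        folds = minority
    if folds < 2:
        raise ValueError("cannot cross-validate with fewer than 2 folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    acc, auc = [], []
    for tr, te in skf.split(X, labels_arr):
        model = train_knn(X[tr], list(labels_arr[tr]), [str(i) for i in range(X.shape[1])],
                          **knn_kwargs)
        pred_labels, pred_scores = predict(model, X[te])
        acc.append(float(np.mean(np.asarray(pred_labels, dtype=object) == labels_arr[te])))
        truth = (labels_arr[te] == "G2").astype(int)
        if len(np.unique(truth)) == 2:
            auc.append(roc_auc(pred_scores, truth))
    return {
        "folds": folds,
        "accuracy": acc,
        "accuracy_mean": float(np.mean(acc)),
        "accuracy_sd": float(np.std(acc, ddof=1)) if len(acc) > 1 else 0.0,
        "auc": auc,
        "auc_mean": float(np.mean(auc)) if auc else None,
        "auc_sd": float(np.std(auc, ddof=1)) if len(auc) > 1 else None,
        "notes": notes,
    }
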