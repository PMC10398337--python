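"""RBF-SVM classification of subjects from cluster-wise dALFF features.

Features are the mean CV per differential cluster.  Evaluation defaults to
leave-one-out over subjects with an inner cross-validated grid search over
powers-of-2 (C, gamma); feature standardization always uses training-fold
statistics only.  A resubstitution mode (train = test) is provided for
comparison but is optimistic by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, LeaveOneOut, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FeatureTable",
    "ClassifierReport",
    "default_grid",
    "extract_roi_features",
    "train_evaluate_svm",
    "permutation_test_classifier",
]


@dataclass
class FeatureTable:
    features: pd.DataFrame  # subjects x clusters, indexed by subject_id
    labels: np.ndarray  # 1 = patient, 0 = control
    cluster_ids: list[int]
    window_length: int | None = None


@dataclass
class ClassifierReport:
    accuracy: float  # percent
    sensitivity: float
    specificity: float
    auc: float
    roc_fpr: list[float]
    roc_tpr: list[float]
    chosen_c: float
    chosen_gamma: float
    scheme: str
    seed: int
    n_subjects: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def default_grid(coarse: bool = False) -> dict[str, list[float]]:
    """LIBSVM-style powers-of-2 grid; the coarse variant steps by 4."""
    step = 4 if coarse else 2
    return {
        "svm__C": [2.0**e for e in range(-5, 16, step)],
        "svm__gamma": [2.0**e for e in range(-15, 4, step)],
    }


def extract_roi_features(
    maps: dict[str, np.ndarray],
    cluster_labels: np.ndarray,
    covariates: pd.DataFrame,
    patient_label: str = "patient",
    window_length: int | None = None,
) -> FeatureTable:
    """Mean map value per labeled cluster per subject.

    Parameters
    ----------
    maps : mapping of subject id -> 3D CV map on the cluster-mask grid.
    cluster_labels : integer-labeled cluster volume (0 = background).
    """
    cluster_labels = np.asarray(cluster_labels)
    ids = sorted(int(c) for c in np.unique(cluster_labels) if c > 0)
    if not ids:
        raise ValueError("cluster mask contains no clusters")
    order = list(covariates["subject_id"])
    rows = {}
    for sid in order:
        if sid not in maps:
            raise ValueError(f"no map supplied for subject {sid}")
        vol = np.asarray(maps[sid], dtype=np.float64)
        if vol.shape != cluster_labels.shape:
            raise ValueError(f"map of {sid} not aligned to cluster mask grid")
        rows[sid] = [vol[cluster_labels == c].mean() for c in ids]
    features = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"cluster{c}" for c in ids]
    ).loc[order]
    if not np.isfinite(features.to_numpy()).all():
        raise ValueError("non-finite feature values")
    labels = (covariates["group"] == patient_label).to_numpy(dtype=int)
    return FeatureTable(features=features, labels=labels, cluster_ids=ids, window_length=window_length)


def _make_search(grid: dict, inner_folds: int, seed: int, n_train: int) -> GridSearchCV:
    folds = min(inner_folds, max(2, n_train // 2))
    pipe = Pipeline([("scale", StandardScaler()), ("svm", SVC(kernel="rbf"))])
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return GridSearchCV(pipe, grid, scoring="accuracy", cv=cv, n_jobs=None)


def fit_predict_fold(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    grid: dict,
    inner_folds: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Grid-search on the training fold only, then predict the held-out rows.

    Exposed separately so leakage can be probed directly: the prediction
    depends only on (train_x, train_y, test_x).
    """
    search = _make_search(grid, inner_folds, seed, len(train_y))
    search.fit(train_x, train_y)
    pred = search.predict(test_x)
    score = search.decision_function(test_x)
    return pred, score, search.best_params_


def train_evaluate_svm(
    table: FeatureTable,
    grid: dict | None = None,
    scheme: str = "loo",
    inner_folds: int = 5,
    seed: int = 0,
) -> ClassifierReport:
    """Evaluate an RBF SVM on the feature table.

    scheme = "loo": leave-one-out outer loop, grid search nested inside each
    training fold.  scheme = "stratified": stratified 5-fold outer loop
    (keeps training folds class-balanced; preferred for permutation nulls,
    where leave-one-out is biased below chance).  scheme = "resubstitution":
    grid search and evaluation on the full sample (optimistic; provided for
    comparison only).
    """
    x = table.features.to_numpy(dtype=np.float64)
    y = np.asarray(table.labels, dtype=int)
    if grid is None:
        grid = default_grid()
    if not grid or not all(len(v) for v in grid.values()):
        raise ValueError("empty parameter grid")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 3:
        raise ValueError("need two classes with >= 3 subjects each")

    if scheme in ("loo", "stratified"):
        if scheme == "loo":
            splits = LeaveOneOut().split(x)
        else:
            outer = StratifiedKFold(n_splits=min(5, int(counts.min())), shuffle=True, random_state=seed)
            splits = outer.split(x, y)
        preds = np.empty_like(y)
        scores = np.empty(len(y), dtype=np.float64)
        params: list[dict] = []
        for train, test in splits:
            pred, score, best = fit_predict_fold(
                x[train], y[train], x[test], grid, inner_folds, seed
            )
            preds[test] = pred
            scores[test] = score
            params.append(best)
        chosen = pd.DataFrame(params).mode().iloc[0].to_dict()
    elif scheme == "resubstitution":
        search = _make_search(grid, inner_folds, seed, len(y))
        search.fit(x, y)
        preds = search.predict(x)
        scores = search.decision_function(x)
        chosen = search.best_params_
    else:
        raise ValueError(f"unknown scheme '{scheme}'")

    tp = int(np.sum((preds == 1) & (y == 1)))
    tn = int(np.sum((preds == 0) & (y == 0)))
    accuracy = 100.0 * np.mean(preds == y)
    sensitivity = tp / max(int(np.sum(y == 1)), 1)
    specificity = tn / max(int(np.sum(y == 0)), 1)
    if len(np.unique(scores)) > 1:
        auc = float(roc_auc_score(y, scores))
        fpr, tpr, _ = roc_curve(y, scores)
    else:
        auc, fpr, tpr = 0.5, np.array([0.0, 1.0]), np.array([0.0, 1.0])
    return ClassifierReport(
        accuracy=float(accuracy),
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        auc=auc,
        roc_fpr=[0.0] + list(map(float, fpr)) + [1.0],
        roc_tpr=[0.0] + list(map(float, tpr)) + [1.0],
        chosen_c=float(chosen["svm__C"]),
        chosen_gamma=float(chosen["svm__gamma"]),
        scheme=scheme,
        seed=seed,
        n_subjects=len(y),
    )


def permutation_test_classifier(
    table: FeatureTable,
    n_perm: int = 100,
    grid: dict | None = None,
    scheme: str = "stratified",
    inner_folds: int = 3,
    seed: int = 0,
) -> dict:
    """Permutation p-value for the observed accuracy.

    p = (1 + #{permuted accuracy >= observed}) / (n_perm + 1).  The default
    stratified outer scheme avoids the below-chance bias of leave-one-out
    under permuted labels.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if grid is None:
        grid = default_grid(coarse=True)
    observed = train_evaluate_svm(table, grid=grid, scheme=scheme, inner_folds=inner_folds, seed=seed)
    rng = np.random.default_rng(seed)
    perm_acc = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = FeatureTable(
            features=table.features,
            labels=rng.permutation(table.labels),
            cluster_ids=table.cluster_ids,
            window_length=table.window_length,
        )
        report = train_evaluate_svm(
            shuffled, grid=grid, scheme=scheme, inner_folds=inner_folds, seed=seed
        )
        perm_acc[b] = report.accuracy
    p = (1 + int(np.sum(perm_acc >= observed.accuracy))) / (n_perm + 1)
    return {
        "observed_accuracy": observed.accuracy,
        "p_value": float(p),
        "permuted_accuracies": perm_acc.tolist(),
    }
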