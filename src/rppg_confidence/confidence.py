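"""Confidence model: labeling, subject folds, classifiers, ROC/AUC.

Window records are turned into a binary problem: an HR estimate whose
absolute error against the reference is below 2 bpm is *reliable* (class 1),
above 6 bpm *unreliable* (class 0), and the ambiguous 2-6 bpm band is
discarded from both training and testing.  A classifier fit on the four
motion features alone emits a continuous reliability score in [0, 1],
evaluated threshold-free through the ROC curve and its AUC.

Cross-validation is subject-stratified: all windows of one subject land in
exactly one fold, so the model can never exploit subject identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .synthetic import FEATURE_NAMES

__all__ = [
    "RELIABLE_BPM", "UNRELIABLE_BPM", "CLASSIFIER_KINDS",
    "ClassifierConfig", "ConfidenceModel", "ROCResult",
    "label_windows", "make_subject_folds", "train_confidence_model",
    "predict_score", "roc_auc", "pearson_correlation", "evaluate",
    "save_model", "load_model",
]

#: Absolute-error thresholds (bpm). Strict inequalities on both: errors of
#: exactly 2.0 or 6.0 fall in the discarded band.
RELIABLE_BPM = 2.0
UNRELIABLE_BPM = 6.0

CLASSIFIER_KINDS = (
    "fine_tree", "lda", "logistic", "naive_bayes", "svm_linear", "svm_rbf",
    "knn1", "boosted_trees", "bagged_trees", "neural_network",
)


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def label_windows(records: pd.DataFrame) -> pd.DataFrame:
    """Attach ``label`` (1 reliable / 0 unreliable / NaN discarded) and
    ``discard_reason`` (``ambiguous_error`` | ``no_reference``) columns.

    Records without an HR estimate or reference HR are discarded with reason
    ``no_reference``; errors in the closed band [2, 6] bpm with reason
    ``ambiguous_error``.
    """
    out = records.copy()
    err = out["abs_err_bpm"].to_numpy(dtype=float)
    label = np.full(err.shape, np.nan)
    label[err < RELIABLE_BPM] = 1.0
    label[err > UNRELIABLE_BPM] = 0.0
    reason = np.where(np.isnan(err), "no_reference",
                      np.where(np.isnan(label), "ambiguous_error", ""))
    out["label"] = label
    out["discard_reason"] = reason
    return out


def label_counts(labeled: pd.DataFrame) -> dict[str, int]:
    lab = labeled["label"]
    return {
        "reliable": int((lab == 1.0).sum()),
        "unreliable": int((lab == 0.0).sum()),
        "discarded": int(lab.isna().sum()),
        "total": int(len(labeled)),
    }


# ---------------------------------------------------------------------------
# subject-stratified folds
# ---------------------------------------------------------------------------

def make_subject_folds(records: pd.DataFrame, k: int = 5, seed: int = 0) -> dict[str, int]:
    """Assign each subject to one of ``k`` folds, greedily balancing record
    counts: subjects are shuffled (seeded), stably sorted by record count
    descending, and each is placed into the currently lightest fold.

    Returns a mapping subject_id -> fold index.  Deterministic given seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = records.groupby("subject_id").size()
    subjects = list(counts.index)
    if len(subjects) < k:
        raise ValueError(f"need at least k={k} distinct subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(subjects)))
    subjects = [subjects[i] for i in order]
    subjects.sort(key=lambda s: -counts[s])  # stable: seeded order breaks ties
    fold_sizes = np.zeros(k, dtype=int)
    assignment: dict[str, int] = {}
    for subj in subjects:
        f = int(np.argmin(fold_sizes))
        assignment[subj] = f
        fold_sizes[f] += counts[subj]
    return assignment


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierConfig:
    """Classifier choice plus overrides.

    The default — bagged trees with 30 learners, each capped at 9 splits
    (10 leaf nodes) — is the configuration that performed best in the study
    this package operationalizes.  ``params`` overrides estimator keyword
    arguments.
    """

    kind: str = "bagged_trees"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; "
                             f"choose from {CLASSIFIER_KINDS}")


def _make_estimator(config: ClassifierConfig, seed: int):
    kind, p = config.kind, dict(config.params)
    if kind == "bagged_trees":
        # "9 maximum splits, 30 learners": a binary tree with s splits has
        # s+1 leaves, hence max_leaf_nodes=10.  max_features=None makes this
        # pure bootstrap aggregation (every split sees all four features).
        return RandomForestClassifier(
            n_estimators=p.pop("n_estimators", 30),
            max_leaf_nodes=p.pop("max_leaf_nodes", 10),
            max_features=p.pop("max_features", None),
            random_state=seed, **p)
    if kind == "boosted_trees":
        base = DecisionTreeClassifier(max_leaf_nodes=p.pop("max_leaf_nodes", 21))
        return AdaBoostClassifier(estimator=base,
                                  n_estimators=p.pop("n_estimators", 30),
                                  learning_rate=p.pop("learning_rate", 0.1),
                                  random_state=seed, **p)
    if kind == "fine_tree":
        return DecisionTreeClassifier(max_leaf_nodes=p.pop("max_leaf_nodes", 101),
                                      criterion="gini", random_state=seed, **p)
    if kind == "lda":
        return LinearDiscriminantAnalysis(**p)
    if kind == "logistic":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", LogisticRegression(max_iter=1000, **p))])
    if kind == "naive_bayes":
        return GaussianNB(**p)
    if kind in ("svm_linear", "svm_rbf"):
        kernel = "linear" if kind == "svm_linear" else "rbf"
        grid = {"clf__C": [0.1, 1.0, 10.0]}
        if kernel == "rbf":
            grid["clf__gamma"] = ["scale", 0.1, 1.0]
        pipe = Pipeline([("scale", StandardScaler()),
                         ("clf", SVC(kernel=kernel, probability=True,
                                     random_state=seed, **p))])
        # hyperparameters tuned on an inner validation split of the training data
        return GridSearchCV(pipe, grid, cv=3, scoring="roc_auc")
    if kind == "knn1":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", KNeighborsClassifier(n_neighbors=p.pop("n_neighbors", 1), **p))])
    if kind == "neural_network":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", MLPClassifier(hidden_layer_sizes=(10, 10, 10),
                                               activation="relu", max_iter=2000,
                                               random_state=seed, **p))])
    raise ValueError(kind)


@dataclass
class ConfidenceModel:
    """Fitted reliability classifier plus its training metadata."""

    estimator: object
    feature_names: tuple[str, ...]
    config: ClassifierConfig
    seed: int
    n_train: int
    method: str = "ALL"

    def score(self, features) -> np.ndarray:
        return predict_score(self, features)


def _feature_matrix(data, feature_names: Sequence[str]) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        x = data.loc[:, list(feature_names)].to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(data, dtype=float))
    if x.shape[1] != len(feature_names):
        raise ValueError(f"expected {len(feature_names)} features, got {x.shape[1]}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    return x


def train_confidence_model(
    records: pd.DataFrame,
    config: ClassifierConfig | None = None,
    seed: int = 0,
    method: str = "ALL",
) -> ConfidenceModel:
    """Fit the configured classifier on the four motion features.

    ``records`` must carry a ``label`` column; discarded (NaN-label) rows are
    excluded.  Raises ``ValueError`` if only one class remains.
    """
    config = config or ClassifierConfig()
    usable = records[records["label"].notna()]
    y = usable["label"].to_numpy(dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both reliable and "
                         "unreliable windows")
    x = _feature_matrix(usable, FEATURE_NAMES)
    est = _make_estimator(config, seed)
    est.fit(x, y)
    return ConfidenceModel(estimator=est, feature_names=FEATURE_NAMES,
                           config=config, seed=seed, n_train=len(usable),
                           method=method)


def predict_score(model: ConfidenceModel, features) -> np.ndarray:
    """Continuous reliability score in [0, 1]; higher means more reliable."""
    x = _feature_matrix(features, model.feature_names)
    est = model.estimator
    proba = est.predict_proba(x)
    classes = est.classes_ if hasattr(est, "classes_") else est.best_estimator_.classes_
    return proba[:, list(classes).index(1)]


def save_model(model: ConfidenceModel, path) -> None:
    joblib.dump({"format_version": 1, "model": model}, path)


def load_model(path) -> ConfidenceModel:
    bundle = joblib.load(path)
    if bundle.get("format_version") != 1:
        raise ValueError("unrecognized model bundle version")
    return bundle["model"]


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve over all score thresholds and its area.

    The trapezoidal area equals the rank (Mann-Whitney) probability that a
    random positive outscores a random negative, with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if np.unique(labels[~np.isnan(labels)]).size < 2:
        raise ValueError("AUC undefined: need both classes")
    fpr, tpr, thr = roc_curve(labels, scores)
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr,
                     auc=float(_trapezoid_auc(fpr, tpr)))


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r between two equal-length samples plus its t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need equal-length samples of size >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# evaluation schemes
# ---------------------------------------------------------------------------

def _fit_score(train: pd.DataFrame, test: pd.DataFrame, config, seed, method):
    model = train_confidence_model(train, config, seed=seed, method=method)
    return predict_score(model, test)


def evaluate(
    records: pd.DataFrame,
    config: ClassifierConfig | None = None,
    scheme: str = "combined",
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Run a full AUC evaluation under one of three schemes.

    * ``within`` — subject-stratified k-fold CV inside each dataset.
    * ``cross`` — train on all-but-one dataset, test on the held-out one.
    * ``combined`` — subject-stratified k-fold CV over the pooled datasets.

    Returns a report dict with, per BVP method (and per dataset where
    applicable), the pooled out-of-fold AUC, per-fold AUCs, and
    reliable/unreliable/discarded tallies.  Train and test subject sets are
    disjoint in every scheme.
    """
    if scheme not in ("within", "cross", "combined"):
        raise ValueError(f"unknown scheme {scheme!r}")
    config = config or ClassifierConfig()
    labeled = records if "label" in records.columns else label_windows(records)
    report: dict = {"scheme": scheme, "classifier": config.kind, "k": k,
                    "seed": seed, "methods": {}}

    datasets = sorted(labeled["dataset_id"].unique())
    if scheme == "cross" and len(datasets) < 2:
        raise ValueError("cross-dataset evaluation needs at least 2 datasets")

    for method in sorted(labeled["method"].unique()):
        mrec = labeled[labeled["method"] == method]
        usable = mrec[mrec["label"].notna()]
        entry: dict = {"counts": label_counts(mrec)}

        if scheme == "combined":
            folds = make_subject_folds(usable, k=k, seed=seed)
            entry.update(_cv_auc(usable, folds, k, config, seed, method))
        elif scheme == "within":
            per_ds = {}
            for ds in datasets:
                dsrec = usable[usable["dataset_id"] == ds]
                folds = make_subject_folds(dsrec, k=k, seed=seed)
                per_ds[ds] = _cv_auc(dsrec, folds, k, config, seed, method)
                per_ds[ds]["counts"] = label_counts(mrec[mrec["dataset_id"] == ds])
            entry["datasets"] = per_ds
            entry["mean_auc"] = float(np.mean([d["auc"] for d in per_ds.values()]))
        else:  # cross
            per_ds = {}
            for ds in datasets:
                train = usable[usable["dataset_id"] != ds]
                test = usable[usable["dataset_id"] == ds]
                train_subj = set(train["subject_id"])
                test_subj = set(test["subject_id"])
                assert not train_subj & test_subj, "subject leakage across datasets"
                labs = test["label"].to_numpy()
                if np.unique(labs).size < 2:
                    # held-out dataset has one class only: AUC undefined there
                    per_ds[ds] = {"auc": None, "n_test": len(test)}
                    continue
                scores = _fit_score(train, test, config, seed, method)
                per_ds[ds] = {"auc": roc_auc(scores, labs).auc, "n_test": len(test)}
            per_ds_auc = [d["auc"] for d in per_ds.values() if d["auc"] is not None]
            if not per_ds_auc:
                raise ValueError("cross-dataset AUC undefined: every held-out "
                                 "dataset has a single class")
            entry["datasets"] = per_ds
            entry["mean_auc"] = float(np.mean(per_ds_auc))
        report["methods"][method] = entry
    return report


def _cv_auc(usable: pd.DataFrame, folds: dict[str, int], k: int,
            config, seed, method) -> dict:
    """Pooled out-of-fold AUC plus per-fold AUCs for one record subset."""
    fold_of = usable["subject_id"].map(folds).to_numpy()
    oof_scores = np.full(len(usable), np.nan)
    per_fold = []
    for f in range(k):
        test_idx = fold_of == f
        train = usable[~test_idx]
        test = usable[test_idx]
        if not len(test):
            continue
        assert not set(train["subject_id"]) & set(test["subject_id"])
        scores = _fit_score(train, test, config, seed, method)
        oof_scores[test_idx] = scores
        labs = test["label"].to_numpy()
        if np.unique(labs).size == 2:
            per_fold.append(roc_auc(scores, labs).auc)
    pooled = roc_auc(oof_scores, usable["label"].to_numpy())
    return {"auc": pooled.auc, "fold_aucs": per_fold, "n_used": int(len(usable))}
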