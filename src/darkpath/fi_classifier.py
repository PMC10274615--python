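"""Functional-interaction classifier.

Reference FIs from curated complexes and reactions serve as positives and
uniformly sampled non-FI gene pairs as negatives; a random-forest ensemble
over the binary feature channels produces a functional-interaction score
in [0, 1] per gene pair, thresholded (>= 0.8 by default) to give the set
of predicted FIs.

:class:`FIClassifier` is a scikit-learn compatible estimator (fit /
predict_proba / get_params) so it composes with sklearn pipelines and model
selection; the module-level functions are thin wrappers that work on the
package's own containers.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedShuffleSplit
from sklearn.utils.validation import check_is_fitted, validate_data

from ._pairs import Pair, all_pairs
from .feature_builder import FeatureChannel, FeatureMatrix, assemble_feature_matrix

MODEL_FORMAT_VERSION = 1

#: hyperparameter grid explored when grid search is requested
DEFAULT_GRID = {
    "class_weight": ["balanced", "balanced_subsample", None],
    "max_depth": [2, 4, 6, 10, None],
    "max_features": ["sqrt", "log2", None],
    "min_samples_leaf": [1, 2, 4],
    "min_samples_split": [2, 4, 10],
    "n_estimators": [100, 200, 500, 1000],
}


class FIClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest functional-interaction classifier.

    Defaults are the production configuration: 200 trees, depth 10,
    balanced class weights, fixed random_state 42. ``extra_params`` passes
    any further ensemble keyword arguments through to the forest.

    Attributes set by :meth:`fit` (sklearn convention): ``classes_``,
    ``n_features_in_``, ``feature_importances_``, ``forest_``.
    """

    def __init__(
        self,
        n_estimators: int = 200,
        max_depth: int | None = 10,
        class_weight: str | dict | None = "balanced",
        min_samples_split: int = 2,
        min_samples_leaf: int = 1,
        random_state: int = 42,
        extra_params: dict | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.class_weight = class_weight
        self.min_samples_split = min_samples_split
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state
        self.extra_params = extra_params

    def _make_forest(self) -> RandomForestClassifier:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            class_weight=self.class_weight,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
            **(self.extra_params or {}),
        )

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training set contains a single class")
        self.forest_ = self._make_forest().fit(X, y)
        self.classes_ = self.forest_.classes_
        self.feature_importances_ = self.forest_.feature_importances_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        X = validate_data(self, X, reset=False)
        return self.forest_.predict_proba(X)

    def predict(self, X):
        check_is_fitted(self, "forest_")
        X = validate_data(self, X, reset=False)
        return self.forest_.predict(X)

    def decision_scores(self, X) -> np.ndarray:
        """Probability of the positive class, the FI score in [0, 1]."""
        proba = self.predict_proba(X)
        return proba[:, list(self.classes_).index(1)]


@dataclass
class TrainingSet:
    """Labelled feature matrix plus the positive / negative pair sets behind it."""

    matrix: FeatureMatrix
    positives: set[Pair]
    negatives: set[Pair]
    seed: int

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")


@dataclass
class EvalReport:
    """Held-out performance averaged over repeated stratified splits."""

    auc: float
    precision: float
    recall: float
    f1: float
    per_fold: dict[str, list[float]] = field(default_factory=dict)


class FIScoreTable(dict):
    """Canonical gene pair -> FI score in [0, 1]."""

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("geneA\tgeneB\tscore\n")
            for (a, b) in sorted(self):
                fh.write(f"{a}\t{b}\t{self[(a, b)]:.9f}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "FIScoreTable":
        out = cls()
        with open(path) as fh:
            next(fh)
            for line in fh:
                a, b, s = line.rstrip("\n").split("\t")
                out[(a, b)] = float(s)
        return out


def build_training_set(
    fis: set[Pair],
    gene_universe: set[str],
    channels: list[FeatureChannel],
    neg_ratio: int = 100,
    seed: int = 42,
) -> TrainingSet:
    """Positives = reference FIs; negatives = random non-FI pairs.

    Negatives are drawn uniformly without replacement from the canonical
    non-FI pairs over ``gene_universe``, ``neg_ratio`` per positive. Raises
    with the maximum attainable ratio when the universe is too small.
    """
    if neg_ratio < 1:
        raise ValueError("neg_ratio must be >= 1")
    gene_universe = {g.upper() for g in gene_universe}
    positives = sorted(p for p in fis if p[0] in gene_universe and p[1] in gene_universe)
    if not positives:
        raise ValueError("no positives fall inside the gene universe")
    non_fi = [p for p in all_pairs(gene_universe) if p not in fis]
    wanted = neg_ratio * len(positives)
    if wanted > len(non_fi):
        raise ValueError(
            f"not enough non-FI pairs for neg_ratio={neg_ratio}: "
            f"maximum attainable ratio is {len(non_fi) // len(positives)}"
        )
    rng = random.Random(seed)
    negatives = sorted(rng.sample(non_fi, wanted))
    pair_index = sorted(set(positives) | set(negatives))
    matrix = assemble_feature_matrix(pair_index, channels)
    pos_set = set(positives)
    matrix.labels = np.array([1 if p in pos_set else 0 for p in matrix.pair_index],
                             dtype=np.uint8)
    return TrainingSet(matrix, pos_set, set(negatives), seed)


def train_and_evaluate(
    ts: TrainingSet,
    clf: FIClassifier | None = None,
    holdout: float = 0.25,
    repeats: int = 10,
    grid_search: bool = False,
) -> tuple[FIClassifier, EvalReport]:
    """Repeated stratified holdout evaluation, then refit on all data.

    Each repeat splits the labelled pairs (default 75% train / 25%
    validation); AUC, precision, recall and F1 are averaged over repeats
    and the per-fold values kept. When ``grid_search`` is on, the
    production hyperparameter grid is explored by cross-validated AUC
    before the final refit.
    """
    if ts.matrix.labels is None:
        raise ValueError("training set has no labels")
    clf = clf if clf is not None else FIClassifier()
    X = ts.matrix.values.astype(float)
    y = ts.matrix.labels.astype(int)
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    splitter = StratifiedShuffleSplit(
        n_splits=repeats, test_size=holdout, random_state=clf.random_state
    )
    folds: dict[str, list[float]] = {"auc": [], "precision": [], "recall": [], "f1": []}
    for train_idx, test_idx in splitter.split(X, y):
        fold_clf = FIClassifier(**clf.get_params()).fit(X[train_idx], y[train_idx])
        scores = fold_clf.decision_scores(X[test_idx])
        pred = (scores >= 0.5).astype(int)
        folds["auc"].append(float(roc_auc_score(y[test_idx], scores)))
        folds["precision"].append(float(precision_score(y[test_idx], pred, zero_division=0)))
        folds["recall"].append(float(recall_score(y[test_idx], pred, zero_division=0)))
        folds["f1"].append(float(f1_score(y[test_idx], pred, zero_division=0)))
    report = EvalReport(
        auc=float(np.mean(folds["auc"])),
        precision=float(np.mean(folds["precision"])),
        recall=float(np.mean(folds["recall"])),
        f1=float(np.mean(folds["f1"])),
        per_fold=folds,
    )
    if grid_search:
        search = GridSearchCV(
            FIClassifier(random_state=clf.random_state),
            DEFAULT_GRID, scoring="roc_auc", cv=5, n_jobs=1,
        ).fit(X, y)
        clf = FIClassifier(**search.best_params_, random_state=clf.random_state)
    clf.fit(X, y)
    clf.channel_names_ = list(ts.matrix.channels)
    return clf, report


def predict_scores(
    clf: FIClassifier, pairs: list[Pair], features: FeatureMatrix
) -> FIScoreTable:
    """Score the requested pairs; feature columns must match training columns."""
    trained = getattr(clf, "channel_names_", None)
    if trained is not None and trained != features.channels:
        missing = [c for c in trained if c not in features.channels]
        extra = [c for c in features.channels if c not in trained]
        raise ValueError(f"feature channel mismatch: missing={missing} extra={extra}")
    row = {p: i for i, p in enumerate(features.pair_index)}
    idx = []
    for p in pairs:
        if p not in row:
            raise KeyError(f"pair {p} absent from the feature matrix")
        idx.append(row[p])
    scores = clf.decision_scores(features.values[idx].astype(float))
    return FIScoreTable(zip(pairs, (float(s) for s in scores)))


def threshold_predictions(table: FIScoreTable, cutoff: float = 0.8) -> set[Pair]:
    """Pairs with score >= cutoff (the cutoff is inclusive)."""
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be in [0, 1]")
    return {p for p, s in table.items() if s >= cutoff}


def feature_importance(clf: FIClassifier,
                       channel_names: list[str] | None = None) -> list[tuple[str, float]]:
    """Per-channel impurity importances, descending; they sum to 1."""
    check_is_fitted(clf, "forest_")
    names = channel_names if channel_names is not None else clf.channel_names_
    if len(names) != len(clf.feature_importances_):
        raise ValueError("channel name count does not match feature count")
    ranked = sorted(zip(names, clf.feature_importances_),
                    key=lambda t: (-t[1], t[0]))
    return [(n, float(v)) for n, v in ranked]


def save_model(clf: FIClassifier, path: str) -> None:
    """Persist the trained model with its channel names and a format version."""
    check_is_fitted(clf, "forest_")
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "channel_names": getattr(clf, "channel_names_", None),
            "estimator": clf,
        },
        path,
    )


def load_model(path: str, expect_channels: list[str] | None = None) -> FIClassifier:
    blob = joblib.load(path)
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {blob.get('format_version')!r}")
    if expect_channels is not None and blob["channel_names"] != expect_channels:
        raise ValueError(
            f"channel mismatch: model has {blob['channel_names']}, "
            f"expected {expect_channels}"
        )
    return blob["estimator"]
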