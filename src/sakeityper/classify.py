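"""The four classifiers compared on the binned-peak feature matrix.

* **PLS-DA** — PLS2 regression of a one-hot class matrix on the features;
  a sample is assigned the class with the largest predicted score.
* **PCA-KNN** — projection onto the fewest leading principal components whose
  cumulative explained variance reaches 95%, then a k = 9 nearest-neighbour
  majority vote (Euclidean; ties go to the smallest class index).
* **SVM-RBF** — C = 1.0, gamma = "scale" (1 / (p * Var(X_train))).
* **RF** — 100 trees, min_samples_split = 2, sqrt(p) features per split
  (the classifier-convention reading of "auto").

Features are standardized (training statistics only) for PLS-DA, PCA-KNN and
SVM; the random forest sees raw intensities.  Data are split 80/20,
stratified by class by default; a group-by-strain mode keeps all four spectra
of a strain on one side of the split to avoid replicate leakage.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)

MODEL_NAMES = ("plsda", "pcaknn", "svm", "rf")


@dataclass(frozen=True)
class SplitSpec:
    """80/20 train/test split, stratified by class unless grouped by strain."""

    train_fraction: float = 0.80
    stratified: bool = True
    group_by_strain: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


@dataclass(frozen=True)
class ModelSpec:
    """A model name plus hyperparameter overrides on top of the defaults."""

    name: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")


DEFAULT_HYPERPARAMETERS: dict[str, dict[str, object]] = {
    "plsda": {"n_components": 10},
    "pcaknn": {"variance_retained": 0.95, "k": 9},
    "svm": {"C": 1.0, "gamma": "scale"},
    "rf": {"n_trees": 100, "min_samples_split": 2, "max_features": "sqrt"},
}


@dataclass
class TrainedModel:
    """A fitted estimator plus the metadata needed to apply it safely."""

    spec: ModelSpec
    estimator: BaseEstimator
    classes: tuple[str, ...]
    columns: tuple[float, ...]
    seed: int

    def describe(self) -> dict[str, object]:
        return {
            "model": self.spec.name,
            "hyperparameters": dict(self.spec.hyperparameters),
            "classes": list(self.classes),
            "n_features": len(self.columns),
            "seed": self.seed,
        }


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """PLS2 regression on a one-hot class matrix; predict by score argmax.

    ``n_components`` is capped at min(n_samples - 1, n_features) with a
    warning when the requested count exceeds the data rank.
    """

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        Y = np.eye(len(self.classes_))[y_idx]
        cap = min(X.shape[0] - 1, X.shape[1])
        n_comp = self.n_components
        if n_comp > cap:
            warnings.warn(
                f"PLS-DA n_components reduced from {n_comp} to {cap} "
                "(limited by sample/feature count)",
                stacklevel=2,
            )
            n_comp = cap
        self.pls_ = PLSRegression(n_components=n_comp, scale=False)
        self.pls_.fit(X, Y)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "pls_")
        return self.pls_.predict(np.asarray(X, dtype=float))

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


def make_estimator(spec: ModelSpec, seed: int = 0) -> BaseEstimator:
    """Build the (unfitted) sklearn estimator for a model spec."""
    hp = {**DEFAULT_HYPERPARAMETERS[spec.name], **dict(spec.hyperparameters)}
    if spec.name == "plsda":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("plsda", PLSDAClassifier(n_components=int(hp["n_components"]))),
            ]
        )
    if spec.name == "pcaknn":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("pca", PCA(n_components=float(hp["variance_retained"]), svd_solver="full")),
                ("knn", KNeighborsClassifier(n_neighbors=int(hp["k"]), metric="euclidean")),
            ]
        )
    if spec.name == "svm":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svm",
                    SVC(
                        C=float(hp["C"]),
                        kernel="rbf",
                        gamma=hp["gamma"],
                        decision_function_shape="ovr",
                        random_state=seed,
                    ),
                ),
            ]
        )
    if spec.name == "rf":
        return RandomForestClassifier(
            n_estimators=int(hp["n_trees"]),
            min_samples_split=int(hp["min_samples_split"]),
            max_features=hp["max_features"],
            random_state=seed,
            n_jobs=1,
        )
    raise AssertionError(spec.name)


def split_data(
    features: FeatureMatrix,
    spec: SplitSpec = SplitSpec(),
    manifest: pd.DataFrame | None = None,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Split a labelled feature matrix into disjoint, exhaustive train/test sets.

    Train size is ``floor(train_fraction * n)``; stratification keeps
    per-class test counts within one of the global fraction.  With
    ``group_by_strain`` the split is over strains (manifest required), so all
    spectra of a strain land on the same side.
    """
    if features.labels is None:
        raise ValueError("feature matrix must carry class labels to be split")
    labels = features.labels
    if spec.stratified and labels.value_counts().min() < 2:
        raise ValueError("stratified split needs at least 2 samples per class")

    if spec.group_by_strain:
        if manifest is None:
            raise ValueError("group_by_strain requires the cohort manifest")
        strain_of = manifest.set_index("spectrum_id")["strain_id"].reindex(labels.index)
        strains = strain_of.drop_duplicates()
        strain_class = labels.groupby(strain_of).agg(lambda x: x.iloc[0])
        train_strains, _ = train_test_split(
            strain_class.index.to_numpy(),
            train_size=spec.train_fraction,
            stratify=strain_class.to_numpy() if spec.stratified else None,
            random_state=spec.seed,
        )
        in_train = strain_of.isin(set(train_strains))
        train_ids = list(labels.index[in_train])
        test_ids = list(labels.index[~in_train])
    else:
        train_ids, test_ids = train_test_split(
            labels.index.to_numpy(),
            train_size=spec.train_fraction,
            stratify=labels.to_numpy() if spec.stratified else None,
            random_state=spec.seed,
        )
        train_ids, test_ids = list(train_ids), list(test_ids)
    return features.subset(train_ids), features.subset(test_ids)


def train_model(
    train: FeatureMatrix, spec: ModelSpec | str, seed: int = 0
) -> TrainedModel:
    """Fit one of the four models on a labelled training feature matrix."""
    if isinstance(spec, str):
        spec = ModelSpec(spec)
    if train.labels is None:
        raise ValueError("training feature matrix must carry class labels")
    labels = train.labels.to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    est = make_estimator(spec, seed)
    est.fit(train.intensities.to_numpy(), labels)
    classes = _fitted_classes(est)
    logger.info("trained %s on %d x %d", spec.name, *train.intensities.shape)
    return TrainedModel(
        spec=spec,
        estimator=est,
        classes=tuple(classes),
        columns=tuple(float(c) for c in train.intensities.columns),
        seed=seed,
    )


def _fitted_classes(est: BaseEstimator) -> np.ndarray:
    final = est.steps[-1][1] if isinstance(est, Pipeline) else est
    return final.classes_


def _check_columns(model: TrainedModel, features: FeatureMatrix) -> None:
    cols = tuple(float(c) for c in features.intensities.columns)
    if cols != model.columns:
        missing = sorted(set(model.columns) - set(cols))
        extra = sorted(set(cols) - set(model.columns))
        raise ValueError(
            "feature columns do not match training columns; "
            f"missing bins: {[f'{m:.1f}' for m in missing[:5]]}, "
            f"extra bins: {[f'{e:.1f}' for e in extra[:5]]}"
        )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict(
    model: TrainedModel, features: FeatureMatrix
) -> tuple[np.ndarray, pd.DataFrame]:
    """Predict class labels and per-class continuous scores.

    Scores follow each model's convention: predicted one-hot regression
    scores for PLS-DA, neighbour vote fractions for PCA-KNN, a softmax over
    one-vs-rest decision values for the SVM (a ranking convention, not a
    probability), and tree vote fractions for the RF.  For vote/probability
    models each row sums to 1, and for every model the argmax of the scores
    equals the predicted label.
    """
    _check_columns(model, features)
    X = features.intensities.to_numpy()
    est = model.estimator
    name = model.spec.name
    if name in ("pcaknn", "rf"):
        scores = est.predict_proba(X)
        labels = model.estimator.classes_ if name == "rf" else _fitted_classes(est)
        pred = np.asarray(labels)[np.argmax(scores, axis=1)]
    elif name == "svm":
        d = est.decision_function(X)
        if d.ndim == 1:  # binary: single margin column
            d = np.column_stack([-d, d])
        scores = _softmax(d)
        pred = np.asarray(_fitted_classes(est))[np.argmax(scores, axis=1)]
    else:  # plsda
        scores = est.decision_function(X)
        pred = np.asarray(_fitted_classes(est))[np.argmax(scores, axis=1)]
    score_df = pd.DataFrame(
        scores, index=features.intensities.index, columns=list(model.classes)
    )
    return pred, score_df


@dataclass(frozen=True)
class ImportanceRanking:
    """Top-ranked RF features by mean impurity decrease.

    ``ranking`` maps bin m/z -> importance score, in rank order (descending
    score, ties broken by ascending m/z); ``scores`` keeps the full
    importance vector over all features.
    """

    ranking: tuple[tuple[float, float], ...]
    scores: pd.Series
    top_fraction: float

    def top_mz(self) -> list[float]:
        return [mz for mz, _ in self.ranking]


def rf_importance(model: TrainedModel, top_fraction: float = 0.10) -> ImportanceRanking:
    """Rank RF features by impurity importance; keep ceil(top_fraction * p)."""
    if model.spec.name != "rf":
        raise ValueError("variable importance is defined for the RF model only")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    imp = np.asarray(model.estimator.feature_importances_, dtype=float)
    mz = np.asarray(model.columns, dtype=float)
    order = np.lexsort((mz, -imp))
    n_top = math.ceil(top_fraction * imp.size)
    ranking = tuple((float(mz[i]), float(imp[i])) for i in order[:n_top])
    return ImportanceRanking(
        ranking=ranking,
        scores=pd.Series(imp, index=mz),
        top_fraction=top_fraction,
    )
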