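"""Staged binary classification and probability-summing ensemble.

The cohort's three-way staging problem is decomposed into three binary
experiments — control vs Parkinson, control vs prodromal, and Parkinson
vs prodromal.  Within each experiment a seeded random forest first votes
for the most informative features; the sub-cohort is then split into a
stratified 70/30 train/test partition, and logistic regression, random
forest and an RBF support-vector classifier are each tuned by exhaustive
grid search with stratified cross-validation (accuracy objective) and
evaluated on the held-out test set.  Finally the three best binary
models are aggregated: for a new subject each class receives the sum of
the probabilities assigned to it by the two binary models in which it
participates, the predicted class is the argmax, and a confidence tier
is derived from the margin between the two largest normalised scores.

:class:`StagedEnsembleClassifier` packages the whole workflow as a
scikit-learn estimator (``fit`` on a feature table and group labels,
``predict``/``predict_proba`` for three-way staging); the module-level
functions are the individual pipeline stages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .registry import GROUPS

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("LR", "RF", "SVC")

# The three binary experiments, in reporting order.
TASKS: Tuple[Tuple[str, str], ...] = (
    ("CONTROL", "PARKINSON"),
    ("CONTROL", "PRODROMAL"),
    ("PARKINSON", "PRODROMAL"),
)

# Confidence tiers from the margin between the top two normalised
# aggregated scores.  Cutoffs are configurable package choices.
TIER_THRESHOLDS: Tuple[Tuple[str, float], ...] = (
    ("high", 0.5),
    ("moderate", 0.25),
    ("low", 0.1),
)


def default_grids() -> Dict[str, Dict[str, list]]:
    """Hyperparameter grids per model family (accuracy-objective search)."""
    return {
        "LR": {"C": [0.1, 1.0], "max_iter": [100]},
        "RF": {
            "n_estimators": [50, 75, 100],
            "max_depth": [3, 5],
            "min_samples_leaf": [2, 3, 4],
            "min_samples_split": [2, 4],
        },
        "SVC": {"C": [0.1, 1.0, 10.0], "gamma": [0.01, 0.1, "scale"]},
    }


def _base_estimator(family: str, seed: Optional[int]) -> BaseEstimator:
    # LR and SVC sit behind a standardiser: the feature table mixes
    # millimetre distances with unit-scale volume ratios, and both models
    # are scale-sensitive.  RF is scale-invariant and stays raw.
    if family == "LR":
        return Pipeline([("scale", StandardScaler()), ("clf", LogisticRegression(random_state=seed))])
    if family == "RF":
        return RandomForestClassifier(random_state=seed)
    if family == "SVC":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            svc = SVC(probability=True, random_state=seed)
        return Pipeline([("scale", StandardScaler()), ("clf", svc)])
    raise ValueError(f"unknown model family {family!r}; expected one of {MODEL_FAMILIES}")


def _expand_grid(family: str, grid: Dict[str, list]) -> Dict[str, list]:
    """Map plain hyperparameter names onto the pipeline step for LR/SVC."""
    if family in ("LR", "SVC"):
        return {f"clf__{k}": v for k, v in grid.items()}
    return grid


class ImportanceVoteSelector(SelectorMixin, BaseEstimator):
    """Random-forest feature voting.

    Fits a seeded forest and keeps the features whose impurity-based
    importance is at least the mean importance (``policy="mean"``), or
    the ``k`` highest-ranked features (``policy=k``).

    Attributes
    ----------
    importances_ : ndarray
        Impurity-based importances, in input column order.
    ranking_ : ndarray
        Column indices sorted by decreasing importance.
    """

    def __init__(self, policy: object = "mean", n_estimators: int = 200, random_state: Optional[int] = 0):
        self.policy = policy
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("feature voting requires at least two classes")
        if np.shape(X)[1] < 2:
            raise ValueError("feature voting requires at least two features")
        forest = RandomForestClassifier(n_estimators=self.n_estimators, random_state=self.random_state)
        forest.fit(X, y)
        self.importances_ = forest.feature_importances_
        self.ranking_ = np.argsort(-self.importances_, kind="stable")
        self.n_features_in_ = forest.n_features_in_
        if hasattr(forest, "feature_names_in_"):
            self.feature_names_in_ = forest.feature_names_in_
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "importances_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        if self.policy == "mean":
            mask[self.importances_ >= self.importances_.mean()] = True
        else:
            k = int(self.policy)
            if k < 1:
                raise ValueError("top-k policy requires k >= 1")
            mask[self.ranking_[: min(k, self.n_features_in_)]] = True
        return mask


def rf_feature_vote(
    X: pd.DataFrame,
    y: Sequence[str],
    policy: object = "mean",
    seed: Optional[int] = 0,
) -> Tuple[pd.DataFrame, List[str]]:
    """Rank features by forest importance and select a subset.

    Returns the full ranking (feature, importance, selected flag) and
    the selected feature names in ranking order.
    """
    selector = ImportanceVoteSelector(policy=policy, random_state=seed).fit(X, y)
    mask = selector.get_support()
    order = selector.ranking_
    ranking = pd.DataFrame(
        {
            "feature": X.columns[order],
            "importance": selector.importances_[order],
            "selected": mask[order],
        }
    )
    selected = [c for c in ranking.loc[ranking["selected"], "feature"]]
    return ranking, selected


def split_train_test(
    table: pd.DataFrame,
    test_fraction: float = 0.3,
    stratify_col: str = "group",
    seed: Optional[int] = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test partition of a cohort table (70/30 default)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be strictly between 0 and 1")
    counts = table[stratify_col].value_counts()
    if counts.min() < 2:
        raise ValueError("every class needs at least two members to stratify")
    train, test = train_test_split(
        table, test_size=test_fraction, stratify=table[stratify_col], random_state=seed
    )
    return train, test


def grid_search_fit(
    family: str,
    X_train: pd.DataFrame | np.ndarray,
    y_train: Sequence[str],
    grid: Optional[Dict[str, list]] = None,
    cv_folds: int = 5,
    seed: Optional[int] = 0,
):
    """Exhaustive grid search with stratified CV; returns (model, params).

    Ties on CV accuracy are broken by first-in-grid order.  If the
    smallest class cannot populate ``cv_folds`` folds the fold count is
    reduced with a warning.
    """
    if grid is None:
        grid = default_grids()[family]
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyperparameter grid")
    y_arr = np.asarray(y_train)
    classes, counts = np.unique(y_arr, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    k = min(cv_folds, int(counts.min()))
    if k < 2:
        raise ValueError("smallest class too small for cross-validation")
    if k < cv_folds:
        warnings.warn(f"reducing CV folds from {cv_folds} to {k} (small class)", stacklevel=2)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    search = GridSearchCV(
        _base_estimator(family, seed), _expand_grid(family, grid), scoring="accuracy", cv=cv, refit=True
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*converge.*")
        warnings.simplefilter("ignore", FutureWarning)
        search.fit(np.asarray(X_train, dtype=float), y_arr)
    params = {k.removeprefix("clf__"): v for k, v in search.best_params_.items()}
    return search.best_estimator_, params


def metrics_from_confusion(cm: np.ndarray) -> Dict[str, float]:
    """Accuracy and support-weighted precision/recall/F1 from confusion counts.

    Rows are true classes, columns predicted.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    diag = np.diag(cm)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted > 0, diag / predicted, 0.0)
        recall = np.where(support > 0, diag / support, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    w = support / total
    return {
        "accuracy": float(diag.sum() / total),
        "precision": float(np.sum(w * precision)),
        "recall": float(np.sum(w * recall)),
        "f1": float(np.sum(w * f1)),
    }


@dataclass
class ModelReport:
    """Held-out evaluation of one fitted model."""

    family: str
    params: Dict[str, object]
    labels: List[str]  # confusion row/column order
    confusion: np.ndarray
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_fpr: Optional[np.ndarray] = None
    roc_tpr: Optional[np.ndarray] = None
    auc: Optional[float] = None
    selected_features: List[str] = field(default_factory=list)
    seed: Optional[int] = None

    def to_dict(self) -> Dict[str, object]:
        return {
            "family": self.family,
            "params": {k: (v if not isinstance(v, np.generic) else v.item()) for k, v in self.params.items()},
            "labels": self.labels,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "selected_features": list(self.selected_features),
            "seed": self.seed,
        }


def evaluate(
    model,
    X_test: pd.DataFrame | np.ndarray,
    y_test: Sequence[str],
    family: str = "",
    params: Optional[Dict[str, object]] = None,
    positive: Optional[str] = None,
) -> ModelReport:
    """Confusion counts, weighted metrics and ROC/AUC on held-out data.

    ROC uses the predicted probability of the positive class (the second
    model class by default); it is omitted with a warning when the model
    exposes no probabilities.
    """
    y_arr = np.asarray(y_test)
    if len(y_arr) == 0:
        raise ValueError("empty test set")
    X_arr = np.asarray(X_test, dtype=float)
    labels = list(getattr(model, "classes_", np.unique(y_arr)))
    pred = model.predict(X_arr)
    cm = confusion_matrix(y_arr, pred, labels=labels)
    m = metrics_from_confusion(cm)

    fpr = tpr = None
    roc_auc = None
    if hasattr(model, "predict_proba"):
        pos = positive if positive is not None else labels[-1]
        scores = model.predict_proba(X_arr)[:, labels.index(pos)]
        if len(np.unique(y_arr)) == 2:
            fpr, tpr, _ = roc_curve(y_arr, scores, pos_label=pos)
            roc_auc = float(auc(fpr, tpr))
    else:
        warnings.warn(f"model {family or type(model).__name__} exposes no probabilities; ROC omitted", stacklevel=2)

    return ModelReport(
        family=family or type(model).__name__,
        params=params or {},
        labels=[str(l) for l in labels],
        confusion=cm,
        accuracy=m["accuracy"],
        precision=m["precision"],
        recall=m["recall"],
        f1=m["f1"],
        roc_fpr=fpr,
        roc_tpr=tpr,
        auc=roc_auc,
    )


@dataclass
class ExperimentResult:
    """One binary experiment: selection, per-family reports, best model."""

    task: Tuple[str, str]
    selected_features: List[str]
    ranking: pd.DataFrame
    reports: Dict[str, ModelReport]
    best_family: str
    best_model: object
    seed: Optional[int]


def run_experiment(
    table: pd.DataFrame,
    task: Tuple[str, str],
    feature_cols: Sequence[str],
    policy: object = "mean",
    test_fraction: float = 0.3,
    cv_folds: int = 5,
    grids: Optional[Dict[str, Dict[str, list]]] = None,
    families: Sequence[str] = MODEL_FAMILIES,
    seed: Optional[int] = 0,
    group_col: str = "group",
    select_on: str = "all",
) -> ExperimentResult:
    """One binary experiment end to end.

    ``select_on="all"`` votes features on the full two-group sub-cohort
    (the replicated workflow — note this lets the held-out rows influence
    the selection); ``select_on="train"`` restricts the vote to the
    training partition, which is the leakage-free variant used for
    calibration checks.
    """
    g1, g2 = task
    sub = table[table[group_col].isin(task)]
    if sub[group_col].nunique() != 2:
        raise ValueError(f"cohort lacks one of the task groups {task}")
    train, test = split_train_test(sub, test_fraction=test_fraction, stratify_col=group_col, seed=seed)
    vote_frame = sub if select_on == "all" else train
    ranking, selected = rf_feature_vote(vote_frame[list(feature_cols)], vote_frame[group_col], policy=policy, seed=seed)

    grids = grids if grids is not None else default_grids()
    reports: Dict[str, ModelReport] = {}
    models: Dict[str, object] = {}
    for family in families:
        model, params = grid_search_fit(
            family, train[selected], train[group_col], grid=grids.get(family), cv_folds=cv_folds, seed=seed
        )
        rep = evaluate(model, test[selected], test[group_col], family=family, params=params, positive=g2)
        rep.selected_features = list(selected)
        rep.seed = seed
        reports[family] = rep
        models[family] = model
    best_family = max(families, key=lambda f: reports[f].accuracy)  # ties: first in `families`
    return ExperimentResult(
        task=task,
        selected_features=list(selected),
        ranking=ranking,
        reports=reports,
        best_family=best_family,
        best_model=models[best_family],
        seed=seed,
    )


def run_three_experiments(
    table: pd.DataFrame,
    feature_cols: Optional[Sequence[str]] = None,
    policy: object = "mean",
    seed: Optional[int] = 0,
    group_col: str = "group",
    **kwargs,
) -> Dict[Tuple[str, str], ExperimentResult]:
    """All three binary experiments on a three-group cohort table."""
    present = set(table[group_col].unique())
    missing = {g for t in TASKS for g in t} - present
    if missing:
        raise ValueError(f"cohort lacks groups {sorted(missing)}")
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c != group_col]
    return {
        task: run_experiment(table, task, feature_cols, policy=policy, seed=seed, group_col=group_col, **kwargs)
        for task in TASKS
    }


@dataclass
class EnsembleOutput:
    """Aggregated three-way prediction for one subject."""

    probabilities: Dict[str, float]  # normalised aggregated scores
    predicted: str
    tier: str
    margin: float


def _tier(margin: float) -> str:
    for name, cutoff in TIER_THRESHOLDS:
        if margin >= cutoff:
            return name
    return "extremely low"


def ensemble_predict(
    models: Mapping[Tuple[str, str], Tuple[object, Sequence[str]]],
    features: pd.DataFrame,
    class_order: Sequence[str] = GROUPS,
) -> List[EnsembleOutput]:
    """Aggregate the three binary models into a three-way prediction.

    ``models`` maps each task to its fitted binary model and the feature
    names it was trained on.  Each class's aggregated score is the sum of
    the probabilities assigned to it by the two binary models in which it
    participates; scores are normalised to sum to one, the predicted
    class is the argmax, and exact ties fall back to the first class in
    ``class_order`` with the tier forced to "extremely low".
    """
    raw = {c: np.zeros(len(features)) for c in class_order}
    n_models = 0
    for task, (model, cols) in models.items():
        missing = [c for c in cols if c not in features.columns]
        if missing:
            raise ValueError(f"features for task {task} missing columns {missing}")
        proba = model.predict_proba(np.asarray(features[list(cols)], dtype=float))
        for j, cls in enumerate(model.classes_):
            if cls not in raw:
                raise ValueError(f"model class {cls!r} not in class order {class_order}")
            raw[cls] += proba[:, j]
        n_models += 1

    outputs: List[EnsembleOutput] = []
    for i in range(len(features)):
        scores = np.array([raw[c][i] for c in class_order])
        norm = scores / scores.sum()
        order = np.argsort(-norm, kind="stable")  # stable: ties keep class_order
        margin = float(norm[order[0]] - norm[order[1]])
        if margin == 0.0:
            predicted = class_order[min(order[0], order[1])]
            tier = "extremely low"
        else:
            predicted = class_order[order[0]]
            tier = _tier(margin)
        outputs.append(
            EnsembleOutput(
                probabilities={c: float(v) for c, v in zip(class_order, norm)},
                predicted=predicted,
                tier=tier,
                margin=margin,
            )
        )
    return outputs


class StagedEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Three-way stage classifier built from the three binary experiments.

    ``fit`` expects a feature DataFrame (named columns) and the group
    label per subject; it runs feature voting, the stratified split,
    grid search and evaluation for every task, keeps each task's best
    model, and predicts by probability-summing aggregation.

    Parameters
    ----------
    policy :
        Feature-selection policy: ``"mean"`` (importance above the mean)
        or an integer top-k.
    test_fraction, cv_folds :
        Split and cross-validation settings of each binary experiment.
    select_on :
        ``"all"`` (replicated workflow) or ``"train"`` (leakage-free
        selection).
    random_state :
        Seed for every stochastic stage.
    """

    def __init__(
        self,
        policy: object = "mean",
        test_fraction: float = 0.3,
        cv_folds: int = 5,
        families: Sequence[str] = MODEL_FAMILIES,
        select_on: str = "all",
        random_state: Optional[int] = 0,
    ):
        self.policy = policy
        self.test_fraction = test_fraction
        self.cv_folds = cv_folds
        self.families = families
        self.select_on = select_on
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y: Sequence[str]):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with named feature columns")
        table = X.copy()
        table["group"] = np.asarray(y)
        self.experiments_ = run_three_experiments(
            table,
            feature_cols=list(X.columns),
            policy=self.policy,
            seed=self.random_state,
            test_fraction=self.test_fraction,
            cv_folds=self.cv_folds,
            families=self.families,
            select_on=self.select_on,
        )
        self.classes_ = np.unique(np.asarray(y))
        self.class_order_ = tuple(g for g in GROUPS if g in set(self.classes_))
        return self

    def _models(self) -> Dict[Tuple[str, str], Tuple[object, Sequence[str]]]:
        check_is_fitted(self, "experiments_")
        return {t: (r.best_model, r.selected_features) for t, r in self.experiments_.items()}

    def predict_detail(self, X: pd.DataFrame) -> List[EnsembleOutput]:
        return ensemble_predict(self._models(), X, class_order=self.class_order_)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.array([o.predicted for o in self.predict_detail(X)])

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        detail = self.predict_detail(X)
        order = list(self.classes_)
        return np.array([[o.probabilities[c] for c in order] for o in detail])
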