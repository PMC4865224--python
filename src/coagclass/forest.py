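"""Random-forest classification with out-of-bag accuracy and Gini importances.

The classifier contract: an ensemble of 501 decision trees, each grown to
purity on a bootstrap resample of the cohort, with a random subset of
``floor(sqrt(p))`` features tried at every split and the Gini impurity as
split criterion.  Accuracy is estimated internally from out-of-bag (OOB)
votes — each sample is classified by the majority vote of the trees whose
bootstrap excluded it — and reported as a percentage.  Because single-forest
accuracies fluctuate with the bootstrap draw, results are reported as the
mean and sample SD over 50 independently seeded runs.

Feature significance is the mean decrease in Gini impurity (MDGini): for
each feature, the impurity decrease of every split made on it, weighted by
the fraction of samples reaching the split, summed within a tree and
averaged over trees.  A feature never used in any split scores exactly 0.
An OOB permutation-based importance is available behind a flag for
comparison, but MDGini is the primary measure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ForestConfig",
    "ClassifierReport",
    "ImportanceTable",
    "train_forest",
    "oob_accuracy",
    "repeated_accuracy",
    "mdgini",
    "repeated_importances",
]


@dataclass(frozen=True)
class ForestConfig:
    """Ensemble hyper-parameters.

    ``n_trees`` is odd to avoid vote ties in the two-class majority vote.
    ``mtry`` is the number of features tried per split; None means the
    classification default floor(sqrt(p)).
    """

    n_trees: int = 501
    mtry: int | None = None
    n_runs: int = 50
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_trees % 2 == 0:
            raise ValueError("n_trees must be odd (avoids vote ties)")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    def resolve_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else max(1, int(math.isqrt(p)))
        if m > p:
            raise ValueError(f"mtry={m} exceeds feature count p={p}")
        return m


@dataclass
class ClassifierReport:
    """Per-run OOB accuracies (%) with their mean and sample SD."""

    feature_set: str
    n_features: int
    runs: list[float]
    config: ForestConfig

    @property
    def mean(self) -> float:
        return float(np.mean(self.runs))

    @property
    def sd(self) -> float:
        return float(np.std(self.runs, ddof=1)) if len(self.runs) > 1 else 0.0

    def formatted(self) -> str:
        return f"{self.mean:.2f} ({self.sd:.2f})"

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "n_features": self.n_features,
            "runs": [float(r) for r in self.runs],
            "mean": self.mean,
            "sd": self.sd,
            "config": {
                "n_trees": self.config.n_trees,
                "mtry": self.config.mtry,
                "n_runs": self.config.n_runs,
                "base_seed": self.config.base_seed,
            },
        }


@dataclass
class ImportanceTable:
    """Per-feature MDGini values, one column per run plus the run average."""

    feature_labels: list[str]
    per_run: np.ndarray  # (n_features, n_runs)

    def __post_init__(self) -> None:
        self.per_run = np.atleast_2d(np.asarray(self.per_run, dtype=float))
        if self.per_run.shape[0] != len(self.feature_labels):
            raise ValueError("per_run rows must match feature_labels")
        if np.any(self.per_run < 0):
            raise ValueError("MDGini values must be non-negative")

    @property
    def run_mean(self) -> np.ndarray:
        return self.per_run.mean(axis=1)

    def to_frame(self, per_run: bool = False) -> pd.DataFrame:
        df = pd.DataFrame({
            "feature": self.feature_labels,
            "run_mean_mdgini": self.run_mean,
        })
        if per_run:
            for r in range(self.per_run.shape[1]):
                df[f"run{r:02d}"] = self.per_run[:, r]
        return df

    def as_series(self) -> pd.Series:
        return pd.Series(self.run_mean, index=self.feature_labels)


def _validate(X: FeatureMatrix) -> None:
    n, p = X.shape
    if p < 1:
        raise ValueError("feature matrix has no features")
    classes, counts = np.unique(X.group_labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")


def train_forest(
    X: FeatureMatrix, config: ForestConfig, seed: int
) -> RandomForestClassifier:
    """Grow the bootstrap ensemble with OOB tracking; deterministic per seed."""
    _validate(X)
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        max_features=config.resolve_mtry(X.shape[1]),
        bootstrap=True,
        oob_score=True,
        random_state=int(seed),
        n_jobs=1,
    )
    clf.fit(X.values, X.group_labels)
    return clf


def oob_accuracy(clf: RandomForestClassifier, X: FeatureMatrix) -> float:
    """Percent of samples whose OOB majority vote matches their label.

    Samples that were in-bag for every tree (vanishingly rare at 501 trees)
    carry no OOB vote and are excluded with a warning.
    """
    votes = clf.oob_decision_function_
    has_vote = ~np.isnan(votes).all(axis=1)
    if not has_vote.all():
        logger.warning(
            "%d sample(s) were never out-of-bag and are excluded from the "
            "OOB accuracy", int((~has_vote).sum()),
        )
    pred = clf.classes_[np.nanargmax(votes[has_vote], axis=1)]
    truth = np.asarray(X.group_labels)[has_vote]
    return 100.0 * float(np.mean(pred == truth))


def mdgini(clf: RandomForestClassifier) -> np.ndarray:
    """Mean decrease in Gini impurity per feature, averaged over trees.

    Per tree, each feature's score is the sum over its splits of the
    sample-weighted Gini-impurity decrease, scaled by the training-set size
    so the values are in "Gini units" comparable across forests; the tree
    scores are then averaged over the ensemble.  Unlike scikit-learn's
    ``feature_importances_`` the values are not normalized to sum to 1.
    """
    n_train = clf.estimators_[0].tree_.weighted_n_node_samples[0]
    per_tree = np.array([
        est.tree_.compute_feature_importances(normalize=False)
        for est in clf.estimators_
    ])
    return per_tree.mean(axis=0) * n_train


def oob_permutation_importance(
    clf: RandomForestClassifier, X: FeatureMatrix, seed: int = 0,
    n_repeats: int = 5,
) -> np.ndarray:
    """Permutation importance (accuracy drop) as an alternative measure."""
    from sklearn.inspection import permutation_importance

    res = permutation_importance(
        clf, X.values, X.group_labels, n_repeats=n_repeats,
        random_state=seed, n_jobs=1,
    )
    return res.importances_mean


def repeated_accuracy(
    X: FeatureMatrix, config: ForestConfig, feature_set: str = "",
) -> ClassifierReport:
    """Mean/SD OOB accuracy over ``config.n_runs`` independently seeded runs.

    Run r uses seed ``base_seed + r`` so every forest is reproducible from
    the base seed alone.
    """
    runs = []
    for r in range(config.n_runs):
        clf = train_forest(X, config, seed=config.base_seed + r)
        runs.append(oob_accuracy(clf, X))
    return ClassifierReport(feature_set, X.shape[1], runs, config)


def repeated_importances(
    X: FeatureMatrix, config: ForestConfig,
) -> ImportanceTable:
    """MDGini per feature for each of the ``n_runs`` seeded forests."""
    cols = []
    for r in range(config.n_runs):
        clf = train_forest(X, config, seed=config.base_seed + r)
        cols.append(mdgini(clf))
    return ImportanceTable(list(X.feature_labels), np.column_stack(cols))


def repeated_run(
    X: FeatureMatrix, config: ForestConfig, feature_set: str = "",
) -> tuple[ClassifierReport, ImportanceTable]:
    """Accuracies and importances from the same ``n_runs`` seeded forests."""
    runs, cols = [], []
    for r in range(config.n_runs):
        clf = train_forest(X, config, seed=config.base_seed + r)
        runs.append(oob_accuracy(clf, X))
        cols.append(mdgini(clf))
    report = ClassifierReport(feature_set, X.shape[1], runs, config)
    table = ImportanceTable(list(X.feature_labels), np.column_stack(cols))
    return report, table
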