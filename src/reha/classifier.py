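"""Scikit-learn-style estimator facade for the evolutionary tree inducer.

:class:`RehaClassifier` is the primary user-facing API: a binary classifier
over samples-by-proteins matrices (NaN = missing) that composes with sklearn
pipelines and model selection.  Matrix-level adapters for the cross-validation
harness and sklearn baseline classifiers live here too.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted

from .evolution import EvolutionConfig, run_evolution
from .io_model import ExpressionMatrix, SampleLabels, ValidationError, per_dataset_standardize
from .tree import predict_matrix, predict_proba_matrix, tree_summary


class RehaClassifier(ClassifierMixin, BaseEstimator):
    """Evolutionary decision tree over relative-expression multi-tests.

    Node tests compare the within-sample order of protein pairs, so
    predictions are invariant to strictly increasing per-sample transforms of
    the input and missing values make individual tests abstain rather than
    fail.  Training runs a generational evolutionary search with
    linear-ranking selection, elitism, subtree crossover and a two-level
    mutation, optimizing accuracy + cluster consistency + protein
    discrimination rank - complexity.

    Parameters mirror :class:`~reha.evolution.EvolutionConfig`;
    ``random_state`` seeds every stochastic step.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Class labels; ``classes_[1]`` is the positive class for scores.
    tree_ : RehaTree
        The fitted (pruned) multi-test tree.
    best_individual_ : Individual
        Fitness record of the returned tree.
    ranking_ : ProteinRanking
        ReliefF discrimination weights used during the search.
    """

    def __init__(self, population_size=64, max_generations=200, stall_generations=30,
                 elitism_count=1, crossover_prob=0.8, mutation_prob=0.2,
                 selection_pressure=1.8, candidate_pool_size=200, max_surrogates=3,
                 theta=0.8, w_acc=1.0, w_cons=0.1, w_rank=0.1, w_comp=0.02,
                 max_depth=4, relief_k=10, random_state=0):
        self.population_size = population_size
        self.max_generations = max_generations
        self.stall_generations = stall_generations
        self.elitism_count = elitism_count
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.selection_pressure = selection_pressure
        self.candidate_pool_size = candidate_pool_size
        self.max_surrogates = max_surrogates
        self.theta = theta
        self.w_acc = w_acc
        self.w_cons = w_cons
        self.w_rank = w_rank
        self.w_comp = w_comp
        self.max_depth = max_depth
        self.relief_k = relief_k
        self.random_state = random_state

    def _config(self) -> EvolutionConfig:
        return EvolutionConfig(
            population_size=self.population_size,
            max_generations=self.max_generations,
            stall_generations=self.stall_generations,
            elitism_count=self.elitism_count,
            crossover_prob=self.crossover_prob,
            mutation_prob=self.mutation_prob,
            selection_pressure=self.selection_pressure,
            seed=int(self.random_state),
            candidate_pool_size=self.candidate_pool_size,
            max_surrogates=self.max_surrogates,
            theta=self.theta,
            w_acc=self.w_acc, w_cons=self.w_cons,
            w_rank=self.w_rank, w_comp=self.w_comp,
            max_depth=self.max_depth,
            relief_k=self.relief_k,
        )

    def _to_matrix(self, X, sample_prefix="S") -> ExpressionMatrix:
        if isinstance(X, pd.DataFrame):
            feature_names = [str(c) for c in X.columns]
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            if values.ndim != 2:
                raise ValidationError("X must be a 2-D samples x proteins array")
            feature_names = getattr(self, "feature_names_in_", None)
            if feature_names is None:
                feature_names = [f"F{i}" for i in range(values.shape[1])]
            else:
                feature_names = list(feature_names)
        if hasattr(self, "n_features_in_") and values.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {values.shape[1]} features, expected {self.n_features_in_}"
            )
        sample_ids = [f"{sample_prefix}{i}" for i in range(values.shape[0])]
        return ExpressionMatrix(
            protein_ids=list(feature_names),
            sample_ids=sample_ids,
            values=values.T,
            missing_mask=np.isnan(values.T),
        )

    def fit(self, X, y):
        """Fit on a samples x proteins matrix (NaN = missing) and binary labels."""
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValidationError(f"binary task required, got classes {classes}")
        self.classes_ = classes
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray([str(c) for c in X.columns], dtype=object)
            self.n_features_in_ = X.shape[1]
        else:
            X = np.asarray(X, dtype=float)
            self.n_features_in_ = X.shape[1]
        m = self._to_matrix(X)
        labels = SampleLabels(
            labels={s: str(y[i]) for i, s in enumerate(m.sample_ids)},
            classes=tuple(str(c) for c in classes),
        )
        self.best_individual_ = run_evolution(m, labels, self._config())
        self.tree_ = self.best_individual_.tree
        return self

    def predict(self, X):
        check_is_fitted(self, "tree_")
        m = self._to_matrix(X, sample_prefix="Q")
        pred = predict_matrix(self.tree_, m)
        lut = {str(c): c for c in self.classes_}
        return np.asarray([lut[p] for p in pred])

    def predict_proba(self, X):
        check_is_fitted(self, "tree_")
        m = self._to_matrix(X, sample_prefix="Q")
        return predict_proba_matrix(self.tree_, m)

    def selected_proteins(self):
        check_is_fitted(self, "tree_")
        return set(tree_summary(self.tree_).distinct_proteins)


# ---------------------------------------------------------------------------
# matrix-level adapters for the cross-validation harness


class RehaModel:
    """ExpressionMatrix-facing adapter around :func:`run_evolution`."""

    def __init__(self, cfg: EvolutionConfig):
        self.cfg = cfg
        self.tree_ = None

    def fit(self, m: ExpressionMatrix, y: SampleLabels):
        self.classes_ = y.classes
        self.best_individual_ = run_evolution(m, y, self.cfg)
        self.tree_ = self.best_individual_.tree
        return self

    def predict(self, m: ExpressionMatrix):
        return predict_matrix(self.tree_, m)

    def predict_proba(self, m: ExpressionMatrix):
        return predict_proba_matrix(self.tree_, m)

    def selected_proteins(self):
        return set(tree_summary(self.tree_).distinct_proteins)


class SklearnBaseline:
    """Adapter running an sklearn classifier on standardized, imputed values.

    Absolute-intensity methods need per-dataset standardization and median
    imputation; both are fitted on the training split only.  Used purely as
    comparison plumbing in benchmark tables.
    """

    def __init__(self, estimator, standardize: bool = True):
        self.estimator = clone(estimator)
        self.standardize = standardize

    def _design(self, m: ExpressionMatrix, fit: bool) -> np.ndarray:
        if self.standardize:
            m = per_dataset_standardize(m)
        X = m.values.T.copy()
        if fit:
            med = np.nanmedian(X, axis=0)
            self._medians = np.nan_to_num(med, nan=0.0)
        inds = np.where(np.isnan(X))
        X[inds] = np.take(self._medians, inds[1])
        return X

    def fit(self, m: ExpressionMatrix, y: SampleLabels):
        self.classes_ = y.classes
        X = self._design(m, fit=True)
        yv = [y.labels[s] for s in m.sample_ids]
        self.estimator.fit(X, yv)
        return self

    def predict(self, m: ExpressionMatrix):
        return list(self.estimator.predict(self._design(m, fit=False)))

    def predict_proba(self, m: ExpressionMatrix):
        proba = self.estimator.predict_proba(self._design(m, fit=False))
        order = [list(self.estimator.classes_).index(c) for c in self.classes_]
        return proba[:, order]


def baseline_factory(name: str, seed: int) -> SklearnBaseline:
    """Named baseline classifiers used in comparison tables."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    name = name.lower()
    if name == "cart":
        est = DecisionTreeClassifier(random_state=seed)
    elif name == "j48":
        est = DecisionTreeClassifier(criterion="entropy", random_state=seed)
    elif name == "rf":
        est = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif name == "svm":
        est = SVC(probability=True, random_state=seed)
    elif name == "nb":
        est = GaussianNB()
    else:
        raise ValidationError(f"unknown baseline {name!r}")
    return SklearnBaseline(est)
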