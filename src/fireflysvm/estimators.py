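"""Scikit-learn-style estimators wrapping the functional layer.

``FireflySVC`` and ``PSOSVC`` train the penalty parameter C, the RBF
width gamma and all Lagrange multipliers jointly by maximizing the dual
objective with a swarm metaheuristic; ``GridSearchSVC`` is the classical
baseline (exponential (C, gamma) grid scored by inner CV, multipliers
from the exact SMO solver) and ``SMOSVC`` the plain exact solver at fixed
hyperparameters.  All four handle k > 2 classes by one-against-all
aggregation and compose with sklearn pipelines and model selection, as do
the ``RangeScaler`` and ``MutualInfoSelector`` transformers.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import core, firefly, preprocessing, pso
from .multiclass import OAAModel, oaa_predict
from .types import Dataset, SVMModel

__all__ = [
    "FireflySVC",
    "PSOSVC",
    "SMOSVC",
    "GridSearchSVC",
    "RangeScaler",
    "MutualInfoSelector",
]


class _BaseSVC(ClassifierMixin, BaseEstimator):
    """Shared fit/predict plumbing: label encoding, binary vs OAA routing."""

    def _train_binary(self, data: Dataset, seed_offset: int) -> SVMModel:
        raise NotImplementedError

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        if len(self.classes_) == 2:
            y_signed = np.where(y == self.classes_[1], 1, -1)
            self.model_ = self._train_binary(Dataset(X, y_signed), 0)
        else:
            machines = []
            for i, tag in enumerate(self.classes_):
                y_signed = np.where(y == tag, 1, -1)
                machines.append(self._train_binary(Dataset(X, y_signed), i))
            self.oaa_model_ = OAAModel(
                class_tags=self.classes_, machines=machines
            )
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "classes_")
        X = check_array(X)
        if len(self.classes_) == 2:
            return core.decision_values(self.model_, X)
        return np.stack(
            [core.decision_values(m, X) for m in self.oaa_model_.machines],
            axis=1,
        )

    def predict(self, X):
        check_is_fitted(self, "classes_")
        X = check_array(X)
        if len(self.classes_) == 2:
            signed = core.predict_many(self.model_, X)
            return np.where(signed == 1, self.classes_[1], self.classes_[0])
        return oaa_predict(self.oaa_model_, X)


class FireflySVC(_BaseSVC):
    """SVM trained end-to-end by the firefly algorithm.

    Parameters
    ----------
    population_m : int, default 20
        Number of fireflies.
    max_iter : int, default 200
        Iterations of the swarm loop.
    absorption : float, default 1.0
        Light absorption coefficient: decay rate of attractiveness with
        normalized distance.
    walk_frac : float or None, default None
        None selects a literal random-walk half-width of 1 in every
        dimension; a float sets the half-width as that fraction of each
        dimension's range instead.
    random_state : int, default 0
        Seed for the single generator driving the whole run.

    Attributes
    ----------
    model_ : SVMModel (binary) — the trained machine.
    oaa_model_ : OAAModel (k > 2) — one machine per class.
    history_ : DataFrame or list of DataFrame — per-iteration best
        brightness and training CCR.
    """

    def __init__(self, population_m=20, max_iter=200, absorption=1.0,
                 walk_frac=None, random_state=0):
        self.population_m = population_m
        self.max_iter = max_iter
        self.absorption = absorption
        self.walk_frac = walk_frac
        self.random_state = random_state

    def _config(self, seed_offset: int) -> firefly.FAConfig:
        return firefly.FAConfig(
            population_m=self.population_m,
            max_iter=self.max_iter,
            absorption=self.absorption,
            walk_frac=self.walk_frac,
            seed=(self.random_state or 0) + seed_offset,
        )

    def _train_binary(self, data: Dataset, seed_offset: int) -> SVMModel:
        model, history = firefly.train_firefly_svm(data, self._config(seed_offset))
        if seed_offset == 0:
            self.history_ = history
        else:
            if not isinstance(getattr(self, "history_", None), list):
                self.history_ = [self.history_]
            self.history_.append(history)
        return model


class PSOSVC(FireflySVC):
    """Particle-swarm baseline over the identical solution-string encoding
    and dual-objective fitness."""

    def __init__(self, population_m=20, max_iter=200, inertia=0.72,
                 cognitive=1.49, social=1.49, walk_frac=None, random_state=0):
        self.population_m = population_m
        self.max_iter = max_iter
        self.inertia = inertia
        self.cognitive = cognitive
        self.social = social
        self.walk_frac = walk_frac
        self.random_state = random_state

    def _config(self, seed_offset: int) -> pso.PSOConfig:
        return pso.PSOConfig(
            population_m=self.population_m,
            max_iter=self.max_iter,
            inertia=self.inertia,
            cognitive=self.cognitive,
            social=self.social,
            walk_frac=self.walk_frac,
            seed=(self.random_state or 0) + seed_offset,
        )

    def _train_binary(self, data: Dataset, seed_offset: int) -> SVMModel:
        model, history = pso.train_pso_svm(data, self._config(seed_offset))
        if seed_offset == 0:
            self.history_ = history
        else:
            if not isinstance(getattr(self, "history_", None), list):
                self.history_ = [self.history_]
            self.history_.append(history)
        return model


class SMOSVC(_BaseSVC):
    """Exact dual solver at fixed (C, gamma) — the convex baseline."""

    def __init__(self, C=1.0, gamma=1.0, tol=1e-8):
        self.C = C
        self.gamma = gamma
        self.tol = tol

    def _train_binary(self, data: Dataset, seed_offset: int) -> SVMModel:
        sol = core.smo_solve(data, self.C, self.gamma, tol=self.tol)
        return core.build_model(sol, data)


class GridSearchSVC(_BaseSVC):
    """Exhaustive exponential grid over C in [2^-15, 2^15] and gamma in
    [2^-5, 2^5] (step 2^1, 341 points), each pair scored by inner-CV CCR
    with the exact SMO solver; the winner is refit on all data."""

    def __init__(self, folds=5, random_state=0):
        self.folds = folds
        self.random_state = random_state

    def _train_binary(self, data: Dataset, seed_offset: int) -> SVMModel:
        C, gamma, cv_ccr = core.grid_search(
            data, folds=self.folds, seed=(self.random_state or 0) + seed_offset
        )
        if seed_offset == 0:
            self.C_, self.gamma_, self.cv_ccr_ = C, gamma, cv_ccr
        sol = core.smo_solve(data, C, gamma)
        return core.build_model(sol, data)


class RangeScaler(TransformerMixin, BaseEstimator):
    """Column-wise linear scaling into [-1, 1] fitted on the training
    partition; constant columns map to 0 and test points may exceed the
    range."""

    def fit(self, X, y=None):
        X = check_array(X)
        self.col_min_ = X.min(axis=0)
        self.col_max_ = X.max(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def _state(self) -> preprocessing.ScalerState:
        return preprocessing.ScalerState(self.col_min_, self.col_max_)

    def transform(self, X):
        check_is_fitted(self, "col_min_")
        X = check_array(X)
        span = self.col_max_ - self.col_min_
        ok = span > 0
        out = np.zeros_like(X, dtype=float)
        out[:, ok] = 2.0 * (X[:, ok] - self.col_min_[ok]) / span[ok] - 1.0
        return out

    def inverse_transform(self, X):
        check_is_fitted(self, "col_min_")
        X = check_array(X)
        span = self.col_max_ - self.col_min_
        ok = span > 0
        out = np.tile(self.col_min_, (X.shape[0], 1))
        out[:, ok] = (X[:, ok] + 1.0) / 2.0 * span[ok] + self.col_min_[ok]
        return out


class MutualInfoSelector(TransformerMixin, BaseEstimator):
    """Keep the k features with the highest plug-in mutual information
    (equal-frequency binning) with the label."""

    def __init__(self, k=10, n_bins=10):
        self.k = k
        self.n_bins = n_bins

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.k > X.shape[1]:
            raise ValueError(
                f"k={self.k} exceeds the number of features d={X.shape[1]}"
            )
        self.ranking_ = preprocessing.mi_rank(Dataset(X, y), n_bins=self.n_bins)
        self.support_ = np.sort(
            self.ranking_["feature"].to_numpy()[: self.k]
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X)
        return X[:, self.support_]
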