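"""Core value types shared across the package.

The training state of the metaheuristic lives in :class:`SolutionString`
(one firefly / particle: all Lagrange multipliers plus the two SVM
hyperparameters on a log2 scale), and a trained binary machine lives in
:class:`SVMModel` (the support-vector expansion of the decision function).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Search box for the two hyperparameters, on the log2 scale.
LOG2C_RANGE = (-15.0, 15.0)
LOG2GAMMA_RANGE = (-5.0, 5.0)


class DegenerateModelError(ValueError):
    """Raised when no multiplier exceeds the support-vector threshold."""


@dataclass
class Dataset:
    """A labeled tabular sample.

    Parameters
    ----------
    X : ndarray of shape (n, d)
        Feature matrix; unitless after scaling.
    y : ndarray of shape (n,)
        Labels: {-1, +1} for binary problems, integer class ids otherwise.
    scaled : bool
        Whether features have been scaled into [-1, 1] column-wise.
    """

    X: np.ndarray
    y: np.ndarray
    scaled: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match the number of rows of X")
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def is_binary(self) -> bool:
        return set(np.unique(self.y).tolist()) <= {-1, 1}

    def require_binary(self) -> None:
        labels = set(np.unique(self.y).tolist())
        if labels != {-1, 1}:
            raise ValueError(
                "binary training requires labels {-1,+1} with both present; "
                f"got {sorted(labels)}"
            )


@dataclass
class SolutionString:
    """One candidate solution: (alpha_1..alpha_n, log2 C, log2 gamma).

    ``brightness`` caches the dual-objective fitness of the string.
    """

    alpha: np.ndarray
    log2C: float
    log2gamma: float
    brightness: float = -np.inf

    @property
    def C(self) -> float:
        return float(2.0 ** self.log2C)

    @property
    def gamma(self) -> float:
        return float(2.0 ** self.log2gamma)

    @property
    def dim(self) -> int:
        return self.alpha.size + 2

    def as_vector(self) -> np.ndarray:
        """Flatten to the (n+2)-dimensional search-space vector."""
        return np.concatenate([self.alpha, [self.log2C, self.log2gamma]])

    @classmethod
    def from_vector(cls, v: np.ndarray, brightness: float = -np.inf) -> "SolutionString":
        v = np.asarray(v, dtype=float)
        return cls(alpha=v[:-2].copy(), log2C=float(v[-2]),
                   log2gamma=float(v[-1]), brightness=brightness)

    def copy(self) -> "SolutionString":
        return SolutionString(self.alpha.copy(), self.log2C,
                              self.log2gamma, self.brightness)


@dataclass
class SVMModel:
    """A trained binary RBF support vector machine.

    Only points with multiplier above the support-vector threshold are
    retained; the decision function is
    ``f(x) = sum_i alpha_i y_i K(x_i, x) + b`` with ``K`` the RBF kernel.
    """

    sv_features: np.ndarray
    sv_alpha: np.ndarray
    sv_labels: np.ndarray
    bias: float
    gamma_kernel: float
    C: float

    @property
    def n_sv(self) -> int:
        return self.sv_alpha.size

    @property
    def d(self) -> int:
        return self.sv_features.shape[1]


@dataclass
class ConfusionCounts:
    """Binary confusion-matrix counts: the substrate for every metric."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn
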