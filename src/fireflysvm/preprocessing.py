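"""Feature scaling to [-1, 1] and mutual-information feature ranking.

Scaling is the linear map x' = 2 (x - min) / (max - min) - 1 with the
column minima and maxima taken from the training partition only (test
points may land outside [-1, 1]); a constant column maps to 0.  Feature
relevance is scored by the plug-in mutual information (natural log)
between the label and the feature discretized into equal-frequency bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from .types import Dataset

__all__ = [
    "ScalerState",
    "fit_scaler",
    "apply_scaler",
    "inverse_scale",
    "mi_rank",
    "select_top",
]


@dataclass
class ScalerState:
    """Per-feature training-partition minima and maxima."""

    col_min: np.ndarray
    col_max: np.ndarray

    @property
    def span(self) -> np.ndarray:
        return self.col_max - self.col_min


def fit_scaler(train: Dataset) -> ScalerState:
    return ScalerState(
        col_min=train.X.min(axis=0), col_max=train.X.max(axis=0)
    )


def apply_scaler(state: ScalerState, data: Dataset) -> Dataset:
    span = state.span
    ok = span > 0
    X = np.zeros_like(data.X)
    X[:, ok] = 2.0 * (data.X[:, ok] - state.col_min[ok]) / span[ok] - 1.0
    return Dataset(X, data.y, scaled=True)


def inverse_scale(state: ScalerState, data: Dataset) -> Dataset:
    """Undo the [-1, 1] map; constant columns are restored to their
    training value."""
    span = state.span
    ok = span > 0
    X = np.tile(state.col_min, (data.n, 1))
    X[:, ok] = (data.X[:, ok] + 1.0) / 2.0 * span[ok] + state.col_min[ok]
    return Dataset(X, data.y, scaled=False)


def _equal_frequency_codes(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize a feature into (at most) n_bins equal-frequency bins."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="right")


def mi_rank(data: Dataset, n_bins: int = 10) -> pd.DataFrame:
    """Rank features by mutual information with the label (nats).

    The estimate is the plug-in MI of the label against the equal-frequency
    binned feature; ties are broken by feature index.  Returns a frame with
    columns (feature, mi, rank) sorted by rank.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mis = np.array(
        [
            mutual_info_score(data.y, _equal_frequency_codes(data.X[:, j], n_bins))
            for j in range(data.d)
        ]
    )
    order = np.lexsort((np.arange(data.d), -mis))  # descending MI, ties by index
    frame = pd.DataFrame(
        {"feature": order, "mi": mis[order], "rank": np.arange(1, data.d + 1)}
    )
    return frame


def select_top(data: Dataset, k: int, n_bins: int = 10) -> Dataset:
    """Keep the k features with the highest mutual information."""
    if k > data.d:
        raise ValueError(f"k={k} exceeds the number of features d={data.d}")
    ranking = mi_rank(data, n_bins=n_bins)
    keep = ranking["feature"].to_numpy()[:k]
    return Dataset(data.X[:, keep], data.y, scaled=data.scaled)
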