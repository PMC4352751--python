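"""One-against-all aggregation of binary machines for k-class problems.

For k classes, k binary machines are trained (each class against the rest
pooled together); a point is assigned to the class whose machine returns
the largest decision value, ties going to the lowest class tag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .core import decision_values
from .firefly import FAConfig, train_firefly_svm
from .types import Dataset, SVMModel

__all__ = ["OAAModel", "oaa_train", "oaa_predict"]


@dataclass
class OAAModel:
    """k one-vs-rest binary machines plus their class tags."""

    class_tags: np.ndarray
    machines: list[SVMModel]

    @property
    def k(self) -> int:
        return len(self.machines)


def oaa_train(
    data: Dataset,
    config: FAConfig | None = None,
    trainer: Callable[[Dataset, FAConfig], tuple[SVMModel, object]] | None = None,
) -> OAAModel:
    """Train one firefly-SVM per class (class -> +1, rest -> -1).

    A different binary trainer with the same signature may be supplied;
    per-machine seeds are offset from ``config.seed`` so the k searches
    are independent.
    """
    if config is None:
        config = FAConfig()
    if trainer is None:
        trainer = train_firefly_svm
    tags, counts = np.unique(data.y, return_counts=True)
    if len(tags) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    machines = []
    for i, tag in enumerate(tags):
        y_bin = np.where(data.y == tag, 1, -1)
        sub_cfg = replace(config, seed=config.seed + i)
        model, _ = trainer(Dataset(data.X, y_bin, scaled=data.scaled), sub_cfg)
        machines.append(model)
    return OAAModel(class_tags=tags, machines=machines)


def oaa_predict(model: OAAModel, X: np.ndarray) -> np.ndarray:
    """Assign each row of X to the class with maximal decision value."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.machines[0].d:
        raise ValueError("dimension mismatch with the trained machines")
    # sort machines by tag so argmax tie-breaks toward the lowest tag
    order = np.argsort(model.class_tags, kind="stable")
    scores = np.stack(
        [decision_values(model.machines[i], X) for i in order], axis=1
    )
    return model.class_tags[order][np.argmax(scores, axis=1)]
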