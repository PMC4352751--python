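"""Global-best particle swarm optimization over the same solution-string
encoding and dual-objective fitness as the firefly search — the comparison
baseline.  Shares the feasibility repair and the elitist best record."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import build_model, squared_distances
from .firefly import FAConfig, _dual, _propose, _train_ccr, init_population
from .types import Dataset, SVMModel

__all__ = ["PSOConfig", "train_pso_svm"]


@dataclass
class PSOConfig(FAConfig):
    """PSO settings on top of the shared swarm fields.

    Standard constriction-style defaults: inertia 0.72, cognitive and
    social coefficients 1.49; velocities are clamped per dimension to half
    the parameter range.
    """

    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49


def train_pso_svm(
    data: Dataset,
    config: PSOConfig | None = None,
) -> tuple[SVMModel, "pd.DataFrame"]:
    """Global-best PSO run over solution strings; same contract and history
    format as the firefly trainer."""
    import pandas as pd

    if config is None:
        config = PSOConfig()
    data.require_binary()
    rng = np.random.default_rng(config.seed)
    sqdist = squared_distances(data.X)
    state = init_population(data, config, rng, sqdist)
    m, n = config.population_m, data.n
    dim = n + 2
    y = data.y.astype(float)

    positions = np.stack([s.as_vector() for s in state.population])
    velocities = np.zeros((m, dim))
    pbest = positions.copy()
    pbest_fit = np.array([s.brightness for s in state.population])
    gbest = state.best.as_vector()
    gbest_fit = state.best.brightness

    # velocity clamp: half of each dimension's range
    vmax = np.empty(dim)
    vmax[:n] = 0.5 * (2.0 ** 15)
    vmax[n] = 15.0
    vmax[n + 1] = 5.0

    records = [(0, gbest_fit, _train_ccr(state.best, data))]
    for t in range(1, config.max_iter + 1):
        r1 = rng.uniform(size=(m, dim))
        r2 = rng.uniform(size=(m, dim))
        velocities = (
            config.inertia * velocities
            + config.cognitive * r1 * (pbest - positions)
            + config.social * r2 * (gbest - positions)
        )
        np.clip(velocities, -vmax, vmax, out=velocities)
        positions = positions + velocities
        for i in range(m):
            p = positions[i]
            s = _propose(p[:n], p[n], p[n + 1], y, config, rng)
            s.brightness = _dual(s.alpha, s.gamma, y, sqdist)
            positions[i] = s.as_vector()
            state.population[i] = s
            if s.brightness > pbest_fit[i]:
                pbest_fit[i] = s.brightness
                pbest[i] = positions[i]
            if s.brightness > gbest_fit:
                gbest_fit = s.brightness
                gbest = positions[i].copy()
                state.best = s.copy()
        state.iteration = t
        records.append((t, gbest_fit, _train_ccr(state.best, data)))
    history = pd.DataFrame(
        records, columns=["iteration", "best_brightness", "train_ccr"]
    )
    model = build_model(state.best, data)
    return model, history
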