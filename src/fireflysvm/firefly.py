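"""The firefly algorithm over SVM solution strings.

Each firefly encodes a complete candidate machine — all n Lagrange
multipliers plus log2 C and log2 gamma — and its brightness is the value
of the kernelized dual objective.  Every iteration scans the population
in order: each firefly moves toward every brighter member of the current
(already-updated) population with an attractiveness that decays
exponentially in their normalized distance, after which the brightest
firefly performs an elitist random walk.  Every proposal is repaired onto
the constraint set {0 <= alpha_i <= C, sum alpha_i y_i = 0} by
alternating projection, so the population stays feasible throughout and
the best-brightness trace is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    build_model,
    dual_objective,
    predict_many,
    project_feasible,
    squared_distances,
)
from .metrics import ccr
from .types import (
    LOG2C_RANGE,
    LOG2GAMMA_RANGE,
    Dataset,
    DegenerateModelError,
    SolutionString,
    SVMModel,
)

__all__ = [
    "FAConfig",
    "SwarmState",
    "init_population",
    "distance",
    "attractiveness",
    "move_toward",
    "best_random_walk",
    "train_firefly_svm",
]

#: floor applied to the summed-brightness term before squashing, so that
#: early populations with negative dual values still produce a pull
BETA_FLOOR = 1e-3

_LOG2C_SPAN = LOG2C_RANGE[1] - LOG2C_RANGE[0]
_LOG2G_SPAN = LOG2GAMMA_RANGE[1] - LOG2GAMMA_RANGE[0]


@dataclass
class FAConfig:
    """Firefly-search settings.

    ``absorption`` is the light absorption coefficient (decay rate of
    attractiveness with distance) — distinct from the RBF kernel width,
    although the field literature reuses the symbol gamma for both.
    ``walk_frac`` controls the uniform random-walk half-width per
    dimension.  The default ``None`` uses a literal half-width of 1.0 in
    every dimension, which keeps the multiplier kicks fine enough to
    refine alpha even when the box [0, C] is wide; a float instead sets
    the half-width as that fraction of each dimension's range ([0, C]
    for each multiplier, 30 for log2 C, 10 for log2 gamma).
    """

    population_m: int = 20
    max_iter: int = 200
    absorption: float = 1.0
    walk_frac: float | None = None
    seed: int = 0
    feas_tol_factor: float = 1e-8

    def __post_init__(self) -> None:
        if self.population_m < 2:
            raise ValueError("population_m must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.absorption < 0:
            raise ValueError("absorption must be nonnegative")

    def feas_tol(self, n: int, C: float) -> float:
        return self.feas_tol_factor * n * C

    def walk_halfwidths(self, n: int, C: float) -> np.ndarray:
        """Per-dimension half-widths for the uniform random walk."""
        if self.walk_frac is None:
            return np.ones(n + 2)
        hw = np.empty(n + 2)
        hw[:n] = self.walk_frac * C
        hw[n] = self.walk_frac * _LOG2C_SPAN
        hw[n + 1] = self.walk_frac * _LOG2G_SPAN
        return hw


@dataclass
class SwarmState:
    """Population plus the elitist best-so-far record."""

    population: list[SolutionString]
    best: SolutionString
    iteration: int = 0


# ---------------------------------------------------------------------------
# lean inner-loop helpers: same arithmetic as the public operations, with
# input validation hoisted out of the per-move path

def _dual(alpha: np.ndarray, gamma: float, y: np.ndarray, sqdist: np.ndarray) -> float:
    ay = alpha * y
    K = np.exp(-gamma * sqdist)
    return float(alpha.sum() - 0.5 * (ay @ (K @ ay)))


def _repair(alpha: np.ndarray, C: float, y: np.ndarray, tol: float,
            max_sweeps: int = 200) -> np.ndarray:
    a = np.minimum(np.maximum(alpha, 0.0), C)
    n = a.size
    for _ in range(max_sweeps):
        gap = float(a @ y)
        if abs(gap) <= tol:
            return a
        a = np.minimum(np.maximum(a - (gap / n) * y, 0.0), C)
    if abs(float(a @ y)) <= tol:
        return a
    return np.zeros_like(a)


def _distance_arrays(alpha_i, log2C_i, log2g_i, alpha_j, log2C_j, log2g_j) -> float:
    alpha_scale = 2.0 ** max(log2C_i, log2C_j)
    da = (alpha_i - alpha_j) / alpha_scale
    dc = (log2C_i - log2C_j) / _LOG2C_SPAN
    dg = (log2g_i - log2g_j) / _LOG2G_SPAN
    return float(np.sqrt(da @ da + dc * dc + dg * dg))


def _beta(brightness_i: float, brightness_j: float, r: float, absorption: float) -> float:
    beta_d = max(brightness_i + brightness_j, BETA_FLOOR)
    beta_raw = beta_d * np.exp(-absorption * r)
    return float(beta_raw / (1.0 + beta_raw))


def _propose(vec_alpha, log2C, log2gamma, y, config, rng_walk) -> SolutionString:
    """Clip hyperparameters, re-clip the multipliers to the (possibly new)
    box, and repair the equality constraint."""
    log2C = float(min(max(log2C, LOG2C_RANGE[0]), LOG2C_RANGE[1]))
    log2gamma = float(min(max(log2gamma, LOG2GAMMA_RANGE[0]), LOG2GAMMA_RANGE[1]))
    C = 2.0 ** log2C
    n = vec_alpha.size
    alpha = _repair(vec_alpha, C, y, config.feas_tol(n, C))
    return SolutionString(alpha=alpha, log2C=log2C, log2gamma=log2gamma)


# ---------------------------------------------------------------------------
# public operations

def init_population(
    data: Dataset,
    config: FAConfig,
    rng: np.random.Generator | None = None,
    sqdist: np.ndarray | None = None,
) -> SwarmState:
    """Random feasible initial swarm: log2 C ~ U(-15,15), log2 gamma ~
    U(-5,5), alpha ~ U(0, C) then projected feasible; brightness is the
    dual objective; best is the brightest member."""
    data.require_binary()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if sqdist is None:
        sqdist = squared_distances(data.X)
    y = data.y.astype(float)
    population = []
    for _ in range(config.population_m):
        log2C = float(rng.uniform(*LOG2C_RANGE))
        log2gamma = float(rng.uniform(*LOG2GAMMA_RANGE))
        C = 2.0 ** log2C
        alpha = _repair(
            rng.uniform(0.0, C, size=data.n), C, y,
            config.feas_tol(data.n, C),
        )
        s = SolutionString(alpha=alpha, log2C=log2C, log2gamma=log2gamma)
        s.brightness = _dual(s.alpha, s.gamma, y, sqdist)
        population.append(s)
    best = max(population, key=lambda s: s.brightness).copy()
    return SwarmState(population=population, best=best, iteration=0)


def distance(a: SolutionString, b: SolutionString) -> float:
    """Euclidean distance between two strings after per-dimension
    normalization to [0, 1].

    Each multiplier dimension is normalized by the larger of the two
    strings' box widths C, and the two log dimensions by their range
    widths, so no block of coordinates saturates the attractiveness decay.
    """
    if a.dim != b.dim:
        raise ValueError("solution strings differ in dimension")
    return _distance_arrays(a.alpha, a.log2C, a.log2gamma,
                            b.alpha, b.log2C, b.log2gamma)


def attractiveness(
    brightness_i: float,
    brightness_j: float,
    r: float,
    absorption: float,
) -> float:
    """Attractiveness beta in (0, 1), strictly decreasing in distance.

    The raw pull is (sum of the two brightness values, floored at a small
    positive constant) times exp(-absorption * r); squashing by
    x / (1 + x) keeps the subsequent move a convex combination.
    """
    if r < 0:
        raise ValueError("distance must be nonnegative")
    return _beta(brightness_i, brightness_j, r, absorption)


def move_toward(
    s_i: SolutionString,
    s_j: SolutionString,
    beta: float,
    rng: np.random.Generator,
    data: Dataset,
    config: FAConfig,
    sqdist: np.ndarray | None = None,
) -> SolutionString:
    """Move s_i toward the brighter s_j: per-dimension convex combination
    (1 - beta) s_i + beta s_j plus a uniform random walk, then clip, repair
    and re-score."""
    if sqdist is None:
        sqdist = squared_distances(data.X)
    y = data.y.astype(float)
    n = data.n
    hw = config.walk_halfwidths(n, s_i.C)
    walk = rng.uniform(-hw, hw)
    omb = 1.0 - beta
    s = _propose(
        omb * s_i.alpha + beta * s_j.alpha + walk[:n],
        omb * s_i.log2C + beta * s_j.log2C + walk[n],
        omb * s_i.log2gamma + beta * s_j.log2gamma + walk[n + 1],
        y, config, rng,
    )
    s.brightness = _dual(s.alpha, s.gamma, y, sqdist)
    return s


def best_random_walk(
    state: SwarmState,
    rng: np.random.Generator,
    data: Dataset,
    config: FAConfig,
    sqdist: np.ndarray | None = None,
) -> SwarmState:
    """Elitist random walk of the best firefly: the proposal replaces the
    record only on a strict brightness improvement, so the best trace is
    non-decreasing."""
    if sqdist is None:
        sqdist = squared_distances(data.X)
    y = data.y.astype(float)
    n = data.n
    hw = config.walk_halfwidths(n, state.best.C)
    walk = rng.uniform(-hw, hw)
    best = state.best
    proposal = _propose(best.alpha + walk[:n], best.log2C + walk[n],
                        best.log2gamma + walk[n + 1], y, config, rng)
    proposal.brightness = _dual(proposal.alpha, proposal.gamma, y, sqdist)
    if proposal.brightness > best.brightness:
        state.best = proposal
    return state


def _train_ccr(best: SolutionString, data: Dataset) -> float:
    try:
        model = build_model(best, data)
    except DegenerateModelError:
        return ccr(data.y, np.ones(data.n, dtype=int))
    return ccr(data.y, predict_many(model, data.X))


def train_firefly_svm(
    data: Dataset,
    config: FAConfig | None = None,
) -> tuple[SVMModel, "pd.DataFrame"]:
    """Full firefly-SVM training run.

    Returns the machine built from the best string found plus a
    per-iteration history frame (iteration, best_brightness, train_ccr)
    whose brightness column is non-decreasing by elitism.  The run is a
    pure function of (data, config): all randomness flows from one
    generator seeded with ``config.seed``.
    """
    import pandas as pd

    if config is None:
        config = FAConfig()
    data.require_binary()
    rng = np.random.default_rng(config.seed)
    sqdist = squared_distances(data.X)
    y = data.y.astype(float)
    n = data.n
    state = init_population(data, config, rng, sqdist)
    m = config.population_m
    absorption = config.absorption
    records = [(0, state.best.brightness, _train_ccr(state.best, data))]
    pop = state.population
    for t in range(1, config.max_iter + 1):
        for i in range(m):
            for j in range(m):
                s_i, s_j = pop[i], pop[j]
                if j == i or s_j.brightness <= s_i.brightness:
                    continue
                r = _distance_arrays(
                    s_i.alpha, s_i.log2C, s_i.log2gamma,
                    s_j.alpha, s_j.log2C, s_j.log2gamma,
                )
                beta = _beta(s_i.brightness, s_j.brightness, r, absorption)
                hw = config.walk_halfwidths(n, s_i.C)
                walk = rng.uniform(-hw, hw)
                omb = 1.0 - beta
                s = _propose(
                    omb * s_i.alpha + beta * s_j.alpha + walk[:n],
                    omb * s_i.log2C + beta * s_j.log2C + walk[n],
                    omb * s_i.log2gamma + beta * s_j.log2gamma + walk[n + 1],
                    y, config, rng,
                )
                s.brightness = _dual(s.alpha, s.gamma, y, sqdist)
                pop[i] = s
        pop_best = max(pop, key=lambda s: s.brightness)
        if pop_best.brightness > state.best.brightness:
            state.best = pop_best.copy()
        state = best_random_walk(state, rng, data, config, sqdist)
        state.iteration = t
        records.append((t, state.best.brightness, _train_ccr(state.best, data)))
    history = pd.DataFrame(
        records, columns=["iteration", "best_brightness", "train_ccr"]
    )
    model = build_model(state.best, data)
    return model, history
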