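"""Synthetic fixture datasets.

Three families cover the geometries the classifiers must handle:
isotropic Gaussian blobs (linearly separable when the class means are far
apart relative to the within-class spread), two concentric rings (a case
a linear separator cannot solve but an RBF machine can), and an XOR-style
four-blob layout (linearly non-separable with multimodal classes).
Generation is a pure function of the spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Dataset

__all__ = ["SynthSpec", "generate", "gaussian_blobs", "rings", "xor_blobs"]


@dataclass
class SynthSpec:
    """Recipe for one synthetic dataset.

    ``separation`` is the inter-mean distance in units of the within-class
    standard deviation (blobs) or the radial gap in units of the ring
    thickness (rings); ``label_noise`` is the fraction of labels flipped
    after generation.
    """

    kind: str = "gaussian_blobs"
    n_per_class: int = 30
    d: int = 2
    k: int = 2
    separation: float = 6.0
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"gaussian_blobs", "rings", "xor"}:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.n_per_class * self.k < 4:
            raise ValueError("need n_per_class * k >= 4")
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")
        if not 0 <= self.label_noise < 1:
            raise ValueError("label_noise must lie in [0, 1)")


def gaussian_blobs(
    n_per_class: int, d: int = 2, k: int = 2, separation: float = 6.0,
    seed: int = 0,
) -> Dataset:
    """k isotropic unit-variance Gaussians with means ``separation`` apart.

    For k=2 the means sit at +-(separation/2) e_1 and labels are {-1,+1};
    for k>2 the means are spread on a circle in the first two coordinates
    and labels are 1..k.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_per_class * k, d))
    if k == 2:
        means = np.zeros((2, d))
        means[0, 0] = -separation / 2.0
        means[1, 0] = +separation / 2.0
        y = np.repeat([-1, 1], n_per_class)
    else:
        if d < 2:
            raise ValueError("k > 2 blobs need d >= 2")
        # circle radius chosen so adjacent means are `separation` apart
        radius = separation / (2.0 * np.sin(np.pi / k))
        angles = 2.0 * np.pi * np.arange(k) / k
        means = np.zeros((k, d))
        means[:, 0] = radius * np.cos(angles)
        means[:, 1] = radius * np.sin(angles)
        y = np.repeat(np.arange(1, k + 1), n_per_class)
    X += np.repeat(means, n_per_class, axis=0)
    return Dataset(X, y)


def rings(
    n_per_class: int, separation: float = 6.0, seed: int = 0,
) -> Dataset:
    """Two concentric 2-D annuli: inner ring labeled -1, outer +1.

    Ring thickness (radial SD) is 0.1; the radial gap between the two
    mean radii is ``separation`` thicknesses, with inner radius 1.
    """
    rng = np.random.default_rng(seed)
    thickness = 0.1
    r_inner, r_outer = 1.0, 1.0 + separation * thickness
    n = 2 * n_per_class
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    radii = np.concatenate(
        [
            r_inner + thickness * rng.standard_normal(n_per_class),
            r_outer + thickness * rng.standard_normal(n_per_class),
        ]
    )
    X = np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
    y = np.repeat([-1, 1], n_per_class)
    return Dataset(X, y)


def xor_blobs(
    n_per_class: int, separation: float = 6.0, seed: int = 0,
) -> Dataset:
    """Four unit-variance blobs at the corners of a square with alternating
    labels — the classical linearly non-separable layout."""
    rng = np.random.default_rng(seed)
    half = separation / 2.0
    corners = np.array([[-half, -half], [half, half], [-half, half], [half, -half]])
    labels = np.array([-1, -1, 1, 1])
    per_corner = [n_per_class // 2 + (n_per_class % 2 if i % 2 == 0 else 0)
                  for i in range(4)]
    X_parts, y_parts = [], []
    for corner, lab, m in zip(corners, labels, per_corner):
        X_parts.append(corner + rng.standard_normal((m, 2)))
        y_parts.append(np.full(m, lab))
    return Dataset(np.vstack(X_parts), np.concatenate(y_parts))


def generate(spec: SynthSpec) -> Dataset:
    """Materialize a SynthSpec, then apply label noise (if any) with the
    same seeded generator stream."""
    if spec.kind == "gaussian_blobs":
        data = gaussian_blobs(
            spec.n_per_class, spec.d, spec.k, spec.separation, spec.seed
        )
    elif spec.kind == "rings":
        data = rings(spec.n_per_class, spec.separation, spec.seed)
    else:
        data = xor_blobs(spec.n_per_class, spec.separation, spec.seed)
    if spec.label_noise > 0:
        rng = np.random.default_rng(spec.seed + 1_000_003)
        flip = rng.uniform(size=data.n) < spec.label_noise
        y = data.y.copy()
        if spec.k == 2 and set(np.unique(y)) <= {-1, 1}:
            y[flip] = -y[flip]
        else:
            tags = np.unique(y)
            shift = rng.integers(1, len(tags), size=int(flip.sum()))
            idx = np.searchsorted(tags, y[flip])
            y[flip] = tags[(idx + shift) % len(tags)]
        data = Dataset(data.X, y, scaled=data.scaled)
    return data
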