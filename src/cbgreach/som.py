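"""Self-organizing map used by the proprioceptive cortex, the map layer of the
motor cortex, and the prefrontal goal map.

One generic Kohonen SOM serves three roles that differ only in their feature
space: 4-d muscle-length vectors (proprioceptive cortex), flattened 15x15
proprioceptive activity sheets (motor-cortex map layer, 225-d) and 2-d target
locations (prefrontal cortex). Node activation is a Gaussian of the distance
between the input and the node's weight vector,

    act_i(x) = exp(-||x - W_i||^2 / sigma^2),

so the best-matching node responds maximally and activation decays with
feature-space distance (not grid distance).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["SOMGrid", "SOMTrainingSchedule", "som_activation", "som_train", "winner"]


@dataclass
class SOMGrid:
    """A square SOM: ``weights`` has shape (n, n, feature_dim)."""

    weights: np.ndarray
    sigma_act: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 3 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must have shape (n, n, feature_dim)")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if not self.sigma_act > 0:
            raise ValueError("sigma_act must be positive")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.weights.shape[2]

    @classmethod
    def random(cls, n: int, feature_dim: int, sigma_act: float, rng,
               low: float = 0.0, high: float = 1.0) -> "SOMGrid":
        w = rng.uniform(low, high, size=(n, n, feature_dim))
        return cls(weights=w, sigma_act=sigma_act)

    def copy(self) -> "SOMGrid":
        return SOMGrid(weights=self.weights.copy(), sigma_act=self.sigma_act)


@dataclass(frozen=True)
class SOMTrainingSchedule:
    """Linear-decay Kohonen schedule over single-sample presentation steps."""

    n_steps: int = 5000
    rate_initial: float = 0.5
    rate_final: float = 0.01
    radius_initial: float | None = None  # default n/2 at train time
    radius_final: float = 1.0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not (self.rate_initial >= self.rate_final > 0):
            raise ValueError("learning rates must be positive and non-increasing")
        if self.radius_initial is not None and not (self.radius_initial >= self.radius_final > 0):
            raise ValueError("radii must be positive and non-increasing")


def _check_dim(x: np.ndarray, grid: SOMGrid) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != grid.feature_dim:
        raise ValueError(f"feature dimension {x.shape[0]} does not match grid ({grid.feature_dim})")
    return x


def som_activation(x, grid: SOMGrid) -> np.ndarray:
    """Gaussian activity sheet (n, n): ``exp(-||x - W_i||^2 / sigma^2)``."""
    x = _check_dim(x, grid)
    d2 = np.sum((grid.weights - x) ** 2, axis=2)
    return np.exp(-d2 / grid.sigma_act ** 2)


def winner(x, grid: SOMGrid, mask: np.ndarray | None = None) -> tuple[int, int]:
    """Best-matching node (row, col): argmin of ``||x - W_i||`` over unmasked nodes.

    ``mask`` is a boolean (n, n) array marking *excluded* nodes (used to keep
    lesioned motor-cortex nodes from winning during retraining). Ties break in
    row-major order (np.argmin convention).
    """
    x = _check_dim(x, grid)
    d2 = np.sum((grid.weights - x) ** 2, axis=2)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.all():
            raise ValueError("mask excludes every node")
        d2 = np.where(mask, np.inf, d2)
    flat = int(np.argmin(d2))
    return flat // grid.n, flat % grid.n


def som_train(samples, grid: SOMGrid, sched: SOMTrainingSchedule,
              rng, mask: np.ndarray | None = None) -> SOMGrid:
    """Train the map online (winner + Gaussian grid neighbourhood update).

    Samples are drawn uniformly with replacement for ``sched.n_steps`` steps;
    the learning rate and neighbourhood radius decay linearly. Deterministic
    given the generator state. ``mask`` excludes nodes from *winning* (their
    weights may still move as neighbours); passing the previously trained grid
    warm-starts retraining.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[None, :]
    if samples.shape[0] == 0:
        raise ValueError("need at least one training sample")
    if samples.shape[1] != grid.feature_dim:
        raise ValueError("sample feature dimension does not match grid")

    out = grid.copy()
    n = out.n
    r0 = sched.radius_initial if sched.radius_initial is not None else n / 2
    rows, cols = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    idx = rng.integers(0, samples.shape[0], size=sched.n_steps)
    denom = max(sched.n_steps - 1, 1)
    for t in range(sched.n_steps):
        frac = t / denom
        rate = sched.rate_initial + frac * (sched.rate_final - sched.rate_initial)
        radius = r0 + frac * (sched.radius_final - r0)
        x = samples[idx[t]]
        wi, wj = winner(x, out, mask=mask)
        h = np.exp(-((rows - wi) ** 2 + (cols - wj) ** 2) / (2 * radius ** 2))
        out.weights += rate * h[:, :, None] * (x - out.weights)
    return out
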