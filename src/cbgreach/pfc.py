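"""Prefrontal goal representation and the slow cortical route to the motor
cortex.

The prefrontal cortex is a SOM trained on reachable workspace locations; a
target location activates a Gaussian bump on it (the goal code). A linear
all-to-all projection W_PFC->MC maps that goal code into motor-cortex space;
it is trained with a delta rule *only on trials that reach the target*,
using the motor-cortex sheet captured at the moment of closest approach as
the teaching signal. Across trials control crossfades from the basal ganglia
(exploratory, slow) to this cortical route (learned, fast).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .som import SOMGrid, som_activation

__all__ = [
    "GoalMap",
    "GoalToMotorWeights",
    "ArbitrationSchedule",
    "pfc_activation",
    "pfc_to_mc",
    "train_pfc_mc",
    "arbitrate",
]


@dataclass
class GoalMap:
    """Trained 2-d SOM over workspace locations (the goal map)."""

    grid: SOMGrid

    def __post_init__(self) -> None:
        if self.grid.feature_dim != 2:
            raise ValueError("goal map features are 2-d workspace locations")


def pfc_activation(x_targ, gm: GoalMap) -> np.ndarray:
    """Goal-code sheet U for a target location (Gaussian SOM activation)."""
    return som_activation(x_targ, gm.grid)


@dataclass
class GoalToMotorWeights:
    """Linear goal-to-motor projection: vec(G_PFC) = W @ vec(U)."""

    W: np.ndarray  # (n*n, n*n)
    eta: float = 0.1

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("goal-to-motor weights must be square (n^2, n^2)")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("weights must be finite")

    @classmethod
    def zeros(cls, n: int, eta: float = 0.1) -> "GoalToMotorWeights":
        return cls(W=np.zeros((n * n, n * n)), eta=eta)

    def copy(self) -> "GoalToMotorWeights":
        return GoalToMotorWeights(W=self.W.copy(), eta=self.eta)


def pfc_to_mc(U: np.ndarray, w: GoalToMotorWeights) -> np.ndarray:
    """Motor-cortex drive induced by the goal code (same sheet shape as U)."""
    U = np.asarray(U, dtype=float)
    flat = w.W @ U.ravel()
    return flat.reshape(U.shape)


def train_pfc_mc(U: np.ndarray, G_targ: np.ndarray, G_PFC: np.ndarray,
                 w: GoalToMotorWeights, reached: bool = True) -> GoalToMotorWeights:
    """Delta-rule update dW = eta (G_targ - G_PFC) vec(U)^T, gated on success.

    ``G_targ`` is the motor-cortex output captured when the arm was closest
    to the target on a successful trial. When ``reached`` is False the update
    is skipped and the weights are returned unchanged.
    """
    if not reached:
        return w
    out = w.copy()
    err = np.asarray(G_targ, dtype=float).ravel() - np.asarray(G_PFC, dtype=float).ravel()
    out.W += out.eta * np.outer(err, np.asarray(U, dtype=float).ravel())
    return out


@dataclass(frozen=True)
class ArbitrationSchedule:
    """Linear BG->PFC control crossfade over a trial horizon.

    The two gains sum to ``total`` on every trial: trial 0 is all basal
    ganglia (exploration), trials >= ``horizon`` are all prefrontal
    (exploitation).
    """

    horizon: int = 50
    total: float = 1.0
    A_BG_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.total <= 0 or self.A_BG_floor < 0 or self.A_BG_floor > self.total:
            raise ValueError("invalid gain bounds")


def arbitrate(trial_index: int, sched: ArbitrationSchedule) -> tuple[float, float]:
    """(A_BG, A_PFC) for a trial index; A_PFC rises, A_BG falls, sum constant."""
    frac = min(max(trial_index, 0), sched.horizon) / sched.horizon
    a_pfc = frac * (sched.total - sched.A_BG_floor)
    a_bg = sched.total - a_pfc
    return a_bg, a_pfc
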