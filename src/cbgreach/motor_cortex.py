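"""Motor cortex: afferent integration, inter-hemispheric coupling, lesion
injection, motor-neuron readout and readout training.

The motor cortex of each hemisphere is a CANN sheet whose afferent input sums
three gated activity sheets — proprioceptive cortex, basal ganglia (via the
thalamus) and prefrontal cortex — plus the contralateral motor cortex output
scaled by a signed coupling factor epsilon:

    I_MC = A_PC G_PC + A_BG G_BG + A_PFC G_PFC + eps * G_MC_other

A hemiparetic lesion is a square patch of nodes whose internal state is
multiplied by a small suppression factor at every integration step. The CANN
output sheet projects linearly onto the four motor neurons,
``phi = A_MN W vec(G)`` (clipped to [0, 1]); the readout weights are trained
with a delta rule against a babbled desired activation so that the full
sensory-motor loop (desired phi -> arm -> proprioception -> motor cortex ->
actual phi) becomes consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MCInputGains",
    "CouplingFactor",
    "LesionSpec",
    "ReadoutWeights",
    "mc_input",
    "coupled_mc_input",
    "lesion_mask",
    "apply_lesion",
    "mn_readout",
    "train_mc_mn",
    "retrain_post_lesion",
]


@dataclass(frozen=True)
class MCInputGains:
    """Non-negative gains of the three afferent sheets."""

    A_PC: float = 1.0
    A_BG: float = 1.0
    A_PFC: float = 1.0

    def __post_init__(self) -> None:
        for name in ("A_PC", "A_BG", "A_PFC"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0")


@dataclass(frozen=True)
class CouplingFactor:
    """Signed inter-hemispheric coupling (eps_right scales the left MC output
    added to the right MC input, and vice versa). Zero means unimanual."""

    eps_right: float = 0.0
    eps_left: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.eps_right) and np.isfinite(self.eps_left)):
            raise ValueError("coupling factors must be finite")


# Table-style coupling presets for the three aiming tasks: the right arm is
# paretic; it receives inhibition from the left MC while exciting it.
TASK_COUPLING = {
    "symmetric": CouplingFactor(eps_right=-0.5, eps_left=0.5),
    "congruent": CouplingFactor(eps_right=-0.2, eps_left=0.89),
    "incongruent": CouplingFactor(eps_right=-0.2, eps_left=0.8),
}


@dataclass(frozen=True)
class LesionSpec:
    """Square lesion of side ``size`` centred at ``centre`` on the sheet.

    Nodes inside have their internal state multiplied by ``suppression``
    every step; a size-0 lesion is a no-op. The square is clipped at sheet
    edges.
    """

    size: int
    centre: tuple[int, int]
    suppression: float = 0.01

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("lesion size must be >= 0")
        if not (0 <= self.suppression <= 1):
            raise ValueError("suppression factor must be in [0, 1]")


def lesion_mask(lesion: LesionSpec | None, n: int) -> np.ndarray:
    """Boolean (n, n) array, True inside the lesion square."""
    mask = np.zeros((n, n), dtype=bool)
    if lesion is None or lesion.size == 0:
        return mask
    ci, cj = lesion.centre
    half = (lesion.size - 1) // 2
    i0, i1 = max(ci - half, 0), min(ci - half + lesion.size, n)
    j0, j1 = max(cj - half, 0), min(cj - half + lesion.size, n)
    mask[i0:i1, j0:j1] = True
    return mask


def apply_lesion(g: np.ndarray, lesion: LesionSpec | None) -> np.ndarray:
    """Suppress the sheet state inside the lesion square (returns a copy)."""
    if lesion is None or lesion.size == 0:
        return np.array(g, dtype=float, copy=True)
    out = np.array(g, dtype=float, copy=True)
    mask = lesion_mask(lesion, out.shape[0])
    out[mask] *= lesion.suppression
    return out


def mc_input(G_PC: np.ndarray, G_BG: np.ndarray, G_PFC: np.ndarray,
             gains: MCInputGains) -> np.ndarray:
    """Gated sum of the three afferent sheets."""
    G_PC, G_BG, G_PFC = (np.asarray(a, dtype=float) for a in (G_PC, G_BG, G_PFC))
    if not (G_PC.shape == G_BG.shape == G_PFC.shape):
        raise ValueError("afferent sheets must share a shape")
    return gains.A_PC * G_PC + gains.A_BG * G_BG + gains.A_PFC * G_PFC


def coupled_mc_input(G_PC: np.ndarray, G_BG: np.ndarray, G_PFC: np.ndarray,
                     gains: MCInputGains, eps: float,
                     G_MC_other: np.ndarray) -> np.ndarray:
    """Afferent sum plus the contralateral MC output scaled by eps.

    Under constraint-induced therapy the caller holds ``G_MC_other`` fixed at
    the constrained arm's resting output, so the coupling term is constant
    over the trial.
    """
    own = mc_input(G_PC, G_BG, G_PFC, gains)
    G_MC_other = np.asarray(G_MC_other, dtype=float)
    if G_MC_other.shape != own.shape:
        raise ValueError("contralateral sheet shape mismatch")
    return own + eps * G_MC_other


@dataclass
class ReadoutWeights:
    """Linear MC -> motor-neuron readout: ``phi = clip(A_MN W vec(G), 0, 1)``."""

    W: np.ndarray  # (4, n*n)
    A_MN: float = 1.0
    eta: float = 0.1

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != 4:
            raise ValueError("readout weights must have shape (4, n*n)")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("readout weights must be finite")

    @classmethod
    def zeros(cls, n: int, A_MN: float = 1.0, eta: float = 0.1) -> "ReadoutWeights":
        return cls(W=np.zeros((4, n * n)), A_MN=A_MN, eta=eta)

    def copy(self) -> "ReadoutWeights":
        return ReadoutWeights(W=self.W.copy(), A_MN=self.A_MN, eta=self.eta)


def mn_readout(G: np.ndarray, w: ReadoutWeights, clip: bool = True) -> np.ndarray:
    """Motor-neuron activation from the MC output sheet."""
    phi = w.A_MN * (w.W @ np.asarray(G, dtype=float).ravel())
    return np.clip(phi, 0.0, 1.0) if clip else phi


def delta_rule_update(w: ReadoutWeights, phi_desired: np.ndarray,
                      phi_actual: np.ndarray, G: np.ndarray) -> None:
    """In-place delta-rule step: dW = eta (phi_D - phi) vec(G)^T."""
    err = np.asarray(phi_desired, dtype=float) - np.asarray(phi_actual, dtype=float)
    w.W += w.eta * np.outer(err, np.asarray(G, dtype=float).ravel())


def finite_difference_update(w: ReadoutWeights, phi_t: np.ndarray,
                             phi_t1: np.ndarray, G: np.ndarray) -> None:
    """Consistency update from MN outputs at consecutive closest-approach steps.

    dW = eta (phi(t) - phi(t+1)) vec(G)^T: nudges the readout so that the MC
    activity near the goal stops producing drift in the motor command. Used
    during chronic retraining alongside the supervised loop re-closure.
    """
    err = np.asarray(phi_t, dtype=float) - np.asarray(phi_t1, dtype=float)
    w.W += w.eta * np.outer(err, np.asarray(G, dtype=float).ravel())


def retrain_post_lesion(hemi, lesion: LesionSpec, rng,
                        n_samples: int | None = None):
    """Retrain the cortical loop around a lesion (returns a new hemisphere).

    (i) The motor-cortex map is retrained warm-started from the intact
    weights, with lesioned nodes excluded from winning, so neighbouring nodes
    take over the representations lost inside the lesion; (ii) the MC->MN
    readout is re-closed by supervised babbling through the *lesioned* loop.
    """
    from dataclasses import replace as _replace
    from .som import SOMTrainingSchedule, som_activation, som_train
    from .arm import mn_to_joint_angles, muscle_feature_vector

    cfg = hemi.config
    mask = lesion_mask(lesion, hemi.n)
    if mask.all():
        raise ValueError("lesion covers the whole sheet; nothing to retrain")

    n_samples = n_samples or cfg.train.n_babble
    phis = rng.uniform(0.0, 1.0, size=(n_samples, 4))
    feats = np.array([muscle_feature_vector(mn_to_joint_angles(p), hemi.geom)
                      for p in phis])
    pc_sheets = np.array([som_activation(f, hemi.pc_som).ravel() for f in feats])

    sched = SOMTrainingSchedule(
        n_steps=cfg.som.retrain_steps,
        rate_initial=cfg.som.retrain_rate_initial, rate_final=cfg.som.rate_final,
        radius_initial=cfg.som.retrain_radius_initial, radius_final=cfg.som.radius_final)
    mc_som = som_train(pc_sheets, hemi.mc_som, sched, rng, mask=mask)

    out = _replace(hemi, mc_som=mc_som, lesion=lesion)
    readout, _ = train_mc_mn(
        lambda phi_d, w: out.loop_response(phi_d, w, lesion=lesion),
        phis, out.readout, sweeps=cfg.train.loop_sweeps, tol=cfg.train.loop_tol)
    out.readout = readout
    return out


def train_mc_mn(loop, phi_samples: np.ndarray, w: ReadoutWeights,
                sweeps: int = 5, tol: float = 1e-3) -> tuple[ReadoutWeights, list[float]]:
    """Close the sensory-motor loop by supervised babbling.

    ``loop`` maps a desired activation phi_D to ``(G, phi_actual)`` by driving
    the arm with phi_D and propagating proprioception through the motor
    cortex. Sweeps over the babbling set apply the delta rule per sample;
    training stops early when the mean loop error drops below ``tol`` and
    aborts if the error grows for three consecutive sweeps.

    Returns the trained weights and the per-sweep mean-error history.
    """
    w = w.copy()
    history: list[float] = []
    grow = 0
    for _ in range(sweeps):
        errs = []
        for phi_d in phi_samples:
            G, phi = loop(phi_d, w)
            errs.append(float(np.linalg.norm(phi_d - phi)))
            delta_rule_update(w, phi_d, phi, G)
        mean_err = float(np.mean(errs))
        history.append(mean_err)
        if mean_err < tol:
            break
        if len(history) >= 2 and mean_err > 1.05 * history[-2]:
            grow += 1
            if grow >= 3:
                raise RuntimeError(
                    f"MC->MN training diverged: error grew 3 consecutive sweeps {history[-4:]}")
        else:
            grow = 0
    return w, history
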