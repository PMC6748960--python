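"""Basal ganglia loop: value computation, pathway gating, STN-GPe
exploration, GPi integration and the thalamic relay.

The striatum evaluates the current arm position against the goal with a
Gaussian value function V = exp(-||x_targ - x_arm||^2 / sigma_V^2). Its
temporal difference delta_V gates two medium-spiny-neuron populations with
opposed sigmoids (lambda_D1 = -lambda_D2), so an *increase* in value routes
the recent change in motor-cortex activity (DeltaG) through the direct
("go") pathway while a *decrease* engages the indirect pathway, whose
excitatory-inhibitory STN-GPe lattices generate complex, weakly correlated
oscillations — the model's exploratory drive. The GPi combines both
pathways, y_GPi = A_D1 y_D1 - A_D2 y_STN, and a thalamic CANN relays the
result to the motor cortex. The net effect is stochastic hill climbing on
the value function: climb when value grows, explore when it falls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cann import CANNKernel, CANNState, cann_step, dense_lateral_matrix

__all__ = [
    "ValueParams",
    "MSNParams",
    "STNGPeParams",
    "STNGPeState",
    "value_function",
    "value_difference",
    "msn_gate",
    "stn_gpe_lateral_kernel",
    "stn_gpe_step",
    "gpi_integrate",
    "BGLoop",
]


@dataclass(frozen=True)
class ValueParams:
    """sigma_V sets the workspace radius over which the value is sensitive."""

    sigma_V: float = 0.1

    def __post_init__(self) -> None:
        if not self.sigma_V > 0:
            raise ValueError("sigma_V must be positive")


@dataclass(frozen=True)
class MSNParams:
    """Gains/thresholds of the D1 (direct) and D2 (indirect) MSN sigmoids."""

    lambda_D1: float = 50.0
    lambda_D2: float = -50.0
    t_D1: float = 0.0
    t_D2: float = 0.05

    def __post_init__(self) -> None:
        if self.lambda_D1 != -self.lambda_D2:
            raise ValueError("opposed pathways require lambda_D1 = -lambda_D2")


def value_function(x_arm, x_targ, p: ValueParams) -> float:
    """V = exp(-||x_targ - x_arm||^2 / sigma_V^2), in (0, 1]."""
    x_arm = np.asarray(x_arm, dtype=float)
    x_targ = np.asarray(x_targ, dtype=float)
    if not (np.all(np.isfinite(x_arm)) and np.all(np.isfinite(x_targ))):
        raise ValueError("positions must be finite")
    d2 = float(np.sum((x_targ - x_arm) ** 2))
    return float(np.exp(-d2 / p.sigma_V ** 2))


def value_difference(v_now: float, v_prev: float) -> float:
    """Temporal value difference delta_V = V(t) - V(t-1)."""
    return float(v_now) - float(v_prev)


def _sigmoid(z: float) -> float:
    return float(1.0 / (1.0 + np.exp(-z)))


def msn_gate(delta_V: float, dG: np.ndarray, p: MSNParams) -> tuple[np.ndarray, np.ndarray]:
    """D1/D2 MSN outputs: opposed sigmoid gates scaling the DeltaG sheet.

    y_D1 = sigm(lambda_D1 (delta_V - t_D1)) * dG,
    y_D2 = sigm(lambda_D2 (delta_V - t_D2)) * dG  (element-wise).
    """
    dG = np.asarray(dG, dtype=float)
    g1 = _sigmoid(p.lambda_D1 * (delta_V - p.t_D1))
    g2 = _sigmoid(p.lambda_D2 * (delta_V - p.t_D2))
    return g1 * dG, g2 * dG


@dataclass(frozen=True)
class STNGPeParams:
    """Coupled excitatory (STN) / inhibitory (GPe) lattice constants.

    Defaults place the uncoupled lattice in an oscillatory regime (checked by
    the calibration test): lateral inhibition within GPe (eps_g < 0), lateral
    excitation within STN (eps_s > 0), mutual STN<->GPe coupling w_sg/w_gs.
    """

    eps_g: float = -0.1
    eps_s: float = 0.2
    w_sg: float = 2.0
    w_gs: float = 2.0
    tau_STN: float = 1.0
    tau_GPe: float = 2.0
    lambda_STN: float = 3.0
    sigma_lat_g: float = 1.5
    sigma_lat_s: float = 1.5
    dt: float = 0.1

    def __post_init__(self) -> None:
        if not (self.dt < self.tau_STN and self.dt < self.tau_GPe):
            raise ValueError("stability requires dt < min(tau_STN, tau_GPe)")


def stn_gpe_lateral_kernel(sigma: float, n: int) -> np.ndarray:
    """Gaussian lateral stencil exp(-(di^2+dj^2)/sigma^2), size (2n-1, 2n-1)."""
    off = np.arange(-(n - 1), n)
    di, dj = np.meshgrid(off, off, indexing="ij")
    return np.exp(-(di ** 2 + dj ** 2) / sigma ** 2)


@dataclass
class STNGPeState:
    """Lattice states of the STN-GPe pair plus the tanh STN output."""

    x_GPe: np.ndarray
    x_STN: np.ndarray
    params: STNGPeParams = field(default_factory=STNGPeParams)
    y_STN: np.ndarray | None = None
    _kern_g: np.ndarray | None = None
    _kern_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x_GPe = np.asarray(self.x_GPe, dtype=float)
        self.x_STN = np.asarray(self.x_STN, dtype=float)
        if self.x_GPe.shape != self.x_STN.shape:
            raise ValueError("STN and GPe lattices must share a shape")
        if self.y_STN is None:
            self.y_STN = np.tanh(self.params.lambda_STN * self.x_STN)
        n = self.x_GPe.shape[0]
        if self._kern_g is None:
            self._kern_g = dense_lateral_matrix(
                stn_gpe_lateral_kernel(self.params.sigma_lat_g, n), n)
        if self._kern_s is None:
            self._kern_s = dense_lateral_matrix(
                stn_gpe_lateral_kernel(self.params.sigma_lat_s, n), n)

    @classmethod
    def random(cls, n: int, rng, params: STNGPeParams | None = None,
               amplitude: float = 0.1) -> "STNGPeState":
        """Seeded initial condition, uniform in [-amplitude, amplitude]."""
        params = params or STNGPeParams()
        return cls(x_GPe=rng.uniform(-amplitude, amplitude, (n, n)),
                   x_STN=rng.uniform(-amplitude, amplitude, (n, n)),
                   params=params)


def stn_gpe_step(state: STNGPeState, y_D2: np.ndarray) -> STNGPeState:
    """One Euler step of the STN-GPe lattice dynamics driven by y_D2.

    tau_GPe dx_GPe/dt = -x_GPe + eps_g (W_glat * x_GPe) + w_sg y_STN + y_D2
    tau_STN dx_STN/dt = -x_STN + eps_s (W_slat * y_STN) - w_gs x_GPe
    y_STN = tanh(lambda_STN x_STN)
    """
    p = state.params
    y_D2 = np.asarray(y_D2, dtype=float)
    if y_D2.shape != state.x_GPe.shape:
        raise ValueError("striatal input shape mismatch")
    shape = state.x_GPe.shape
    lat_g = (state._kern_g @ state.x_GPe.ravel()).reshape(shape)
    lat_s = (state._kern_s @ state.y_STN.ravel()).reshape(shape)
    x_gpe = state.x_GPe + (p.dt / p.tau_GPe) * (
        -state.x_GPe + p.eps_g * lat_g + p.w_sg * state.y_STN + y_D2)
    x_stn = state.x_STN + (p.dt / p.tau_STN) * (
        -state.x_STN + p.eps_s * lat_s - p.w_gs * state.x_GPe)
    if not (np.all(np.isfinite(x_gpe)) and np.all(np.isfinite(x_stn))):
        raise FloatingPointError("STN-GPe state became non-finite")
    return STNGPeState(x_GPe=x_gpe, x_STN=x_stn, params=p,
                       _kern_g=state._kern_g, _kern_s=state._kern_s)


def gpi_integrate(y_D1: np.ndarray, y_STN: np.ndarray,
                  A_D1: float = 1.0, A_D2: float = 1.0,
                  explore_gate: float = 1.0) -> np.ndarray:
    """GPi output: y_GPi = A_D1 y_D1 - A_D2 * explore_gate * y_STN.

    With ``explore_gate=1`` this is the plain weighted difference of the
    direct-pathway and STN sheets. The loop passes the indirect-pathway
    (D2) gate for ``explore_gate``, so the exploratory STN drive reaching
    the GPi shrinks as the value climbs steeply — without this arbitration
    the tanh-scale STN oscillation would dominate the GPi at all times and
    exploration could never anneal into exploitation.
    """
    y_D1 = np.asarray(y_D1, dtype=float)
    y_STN = np.asarray(y_STN, dtype=float)
    if y_D1.shape != y_STN.shape:
        raise ValueError("pathway sheets must share a shape")
    return A_D1 * y_D1 - A_D2 * explore_gate * y_STN


@dataclass
class BGLoop:
    """Stateful basal-ganglia loop for one hemisphere.

    Holds the value history, the previous motor-cortex output sheet (for
    DeltaG), the STN-GPe lattices and the thalamic CANN relay; ``drive``
    composes one full pass and returns the G_BG sheet fed to the motor
    cortex. ``msn_gain`` scales the DeltaG sheet into the striatal operating
    range so the gated pathways can compete with the tanh-scale STN output.
    """

    value_params: ValueParams
    msn_params: MSNParams
    stn_gpe: STNGPeState
    thalamus: CANNState
    thal_kernel: CANNKernel
    A_D1: float = 1.0
    A_D2: float = 1.0
    msn_gain: float = 1.0
    v_prev: float | None = None
    G_prev: np.ndarray | None = None
    trace: list = field(default_factory=list)  # per-step diagnostics

    def reset(self, x_arm, x_targ) -> None:
        """Start-of-trial state: DeltaG buffer zeroed, value seeded at start."""
        n = self.stn_gpe.x_GPe.shape[0]
        self.G_prev = np.zeros((n, n))
        self.trace = []
        self.v_prev = value_function(x_arm, x_targ, self.value_params)
        self.thalamus = CANNState.zeros(n, tau=self.thalamus.tau,
                                        dt=self.thalamus.dt, b=self.thalamus.b)

    def drive(self, x_arm, x_targ, G_MC: np.ndarray) -> np.ndarray:
        """One BG pass: value -> gates -> STN-GPe -> GPi -> thalamus -> G_BG."""
        if self.G_prev is None or self.v_prev is None:
            raise RuntimeError("BGLoop.reset must be called at trial start")
        v = value_function(x_arm, x_targ, self.value_params)
        dv = value_difference(v, self.v_prev)
        dG = self.msn_gain * (np.asarray(G_MC, dtype=float) - self.G_prev)
        y_d1, y_d2 = msn_gate(dv, dG, self.msn_params)
        self.stn_gpe = stn_gpe_step(self.stn_gpe, y_d2)
        gate2 = _sigmoid(self.msn_params.lambda_D2 * (dv - self.msn_params.t_D2))
        y_gpi = gpi_integrate(y_d1, self.stn_gpe.y_STN, self.A_D1, self.A_D2,
                              explore_gate=gate2)
        self.thalamus = cann_step(self.thalamus, self.thal_kernel, y_gpi)
        gate1 = _sigmoid(self.msn_params.lambda_D1 * (dv - self.msn_params.t_D1))
        self.trace.append(dict(V=v, delta_V=dv, gate_D1=gate1, gate_D2=gate2,
                               y_STN_std=float(self.stn_gpe.y_STN.std()),
                               G_BG_max=float(self.thalamus.G.max())))
        self.v_prev = v
        self.G_prev = np.array(G_MC, dtype=float, copy=True)
        return self.thalamus.G
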