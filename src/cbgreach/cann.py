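"""Continuous attractor neural network (CANN) sheet.

A square sheet of rate neurons with short-range excitation and long-range
(global) inhibition. The lateral kernel is a Gaussian minus a constant,

    W(di, dj) = A_lat exp(-(di^2 + dj^2) / (2 sigma_lat^2)) - K,

the internal state g follows leaky-integrator dynamics driven by the lateral
feedback (kernel correlated with the current *output* sheet) plus afferent
input, and the output applies an element-wise square with global divisive
normalization:

    tau dg/dt = -g + W (*) G + I
    G = g^2 / (1 + (2*pi/N^2) * b * sum(g^2))

The squared numerator makes the output sign-blind: input that drives g
*negative* still produces positive output — a property the inter-hemispheric
coupling relies on. One instance models each motor cortex; a second instance
per hemisphere models the thalamic relay of the basal-ganglia output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
__all__ = ["CANNKernel", "CANNState", "build_lateral_kernel", "cann_step", "cann_output",
           "dense_lateral_matrix"]


def dense_lateral_matrix(stencil: np.ndarray, n: int) -> np.ndarray:
    """(n^2, n^2) matrix M with M[p, q] = stencil[i_p - i_q + n-1, j_p - j_q + n-1].

    ``M @ vec(sheet)`` equals the 'valid' correlation of the sheet with the
    full-size stencil; precomputing it makes the per-step lateral interaction
    a single BLAS matvec.
    """
    idx = np.arange(n)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    pi, pj = ii.ravel(), jj.ravel()
    di = pi[:, None] - pi[None, :] + (n - 1)
    dj = pj[:, None] - pj[None, :] + (n - 1)
    return stencil[di, dj]


@dataclass(frozen=True)
class CANNKernel:
    """Lateral stencil of size (2n-1, 2n-1) centred on the zero offset."""

    A_lat: float
    sigma_lat: float
    K: float
    kernel: np.ndarray
    matrix: np.ndarray | None = None


def build_lateral_kernel(A_lat: float, sigma_lat: float, K: float, n: int,
                         literal_sum_offsets: bool = False) -> CANNKernel:
    """Gaussian-excitation / constant-inhibition kernel for an n x n sheet.

    ``literal_sum_offsets=True`` squares the *sum* of the row and column
    offsets instead of their Euclidean norm (an anisotropic variant kept as a
    switch; the default isotropic form is the one used throughout).
    """
    if not sigma_lat > 0:
        raise ValueError("sigma_lat must be positive")
    if not A_lat > 0:
        raise ValueError("A_lat must be positive")
    if K < 0:
        raise ValueError("K must be non-negative")
    off = np.arange(-(n - 1), n)
    di, dj = np.meshgrid(off, off, indexing="ij")
    if literal_sum_offsets:
        d2 = (di + dj) ** 2
    else:
        d2 = di ** 2 + dj ** 2
    kern = A_lat * np.exp(-d2 / (2 * sigma_lat ** 2)) - K
    return CANNKernel(A_lat=A_lat, sigma_lat=sigma_lat, K=K, kernel=kern,
                      matrix=dense_lateral_matrix(kern, n))


@dataclass
class CANNState:
    """Internal state ``g`` plus integration constants and the output sheet ``G``."""

    g: np.ndarray
    tau: float = 1.0
    dt: float = 0.1
    b: float = 1.0
    G: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        if self.g.ndim != 2 or self.g.shape[0] != self.g.shape[1]:
            raise ValueError("state g must be a square sheet")
        if not self.dt < self.tau:
            raise ValueError("stability requires dt < tau")
        if self.G is None:
            self.G = cann_output(self)

    @classmethod
    def zeros(cls, n: int, tau: float = 1.0, dt: float = 0.1, b: float = 1.0) -> "CANNState":
        return cls(g=np.zeros((n, n)), tau=tau, dt=dt, b=b)

    def copy(self) -> "CANNState":
        return CANNState(g=self.g.copy(), tau=self.tau, dt=self.dt, b=self.b,
                         G=self.G.copy())


def cann_output(state: CANNState) -> np.ndarray:
    """Squared output under global divisive normalization (always >= 0)."""
    g2 = state.g ** 2
    n2 = state.g.size
    return g2 / (1.0 + (2 * np.pi / n2) * state.b * g2.sum())


def cann_step(state: CANNState, kernel: CANNKernel, I: np.ndarray) -> CANNState:
    """One Euler step of the sheet dynamics (zero-padded boundaries).

    g <- g + (dt/tau) (-g + W (*) G + I), then G is recomputed. The lateral
    term correlates the kernel with the *current output* G, implemented as a
    'valid' convolution of G with the (symmetric, full-size) stencil.
    """
    I = np.asarray(I, dtype=float)
    if I.shape != state.g.shape:
        raise ValueError("input sheet shape mismatch")
    if kernel.matrix is not None:
        lateral = (kernel.matrix @ state.G.ravel()).reshape(state.G.shape)
    else:
        from scipy.signal import convolve
        lateral = convolve(state.G, kernel.kernel, mode="valid", method="auto")
    g_new = state.g + (state.dt / state.tau) * (-state.g + lateral + I)
    if not np.all(np.isfinite(g_new)):
        raise FloatingPointError("CANN state became non-finite")
    out = CANNState(g=g_new, tau=state.tau, dt=state.dt, b=state.b, G=None)
    return out
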