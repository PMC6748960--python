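"""Two-link planar kinematic arm driven by agonist/antagonist muscle pairs.

Each of the two joints (shoulder, elbow) is actuated by an agonist/antagonist
muscle pair, innervated by one motor neuron each, so the arm's command is a
four-dimensional motor-neuron activation vector

    phi = [phi_Ag^S, phi_An^S, phi_Ag^E, phi_An^E],  each in [0, 1].

The difference of each pair sets the joint angle affinely; muscle lengths
follow from the law of cosines around each joint; the end effector position
is obtained by planar forward kinematics. There are no dynamics — the arm is
purely kinematic and the temporal structure of a movement comes entirely from
the cortical network driving ``phi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArmGeometry",
    "DEFAULT_GEOMETRY",
    "mn_to_joint_angles",
    "joint_angles_to_muscle_lengths",
    "forward_kinematics",
    "muscle_feature_vector",
    "reach_radius",
]


@dataclass(frozen=True)
class ArmGeometry:
    """Link lengths and muscle attachment distances of one arm.

    ``a_S``/``b_S`` (``a_E``/``b_E``) are the attachment distances of the
    shoulder (elbow) muscle pair on either side of the joint; ``l_S``/``l_E``
    are the link lengths. All in consistent (arbitrary) workspace length
    units. ``side`` tags handedness: the left arm mirrors the x1 axis.
    """

    a_S: float = 0.04
    b_S: float = 0.07
    a_E: float = 0.03
    b_E: float = 0.08
    l_S: float = 0.3
    l_E: float = 0.3
    side: str = "right"
    shoulder_separation: float = 0.4

    def __post_init__(self) -> None:
        for name in ("a_S", "b_S", "a_E", "b_E", "l_S", "l_E"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.a_S < self.l_S:
            raise ValueError("shoulder attachment a_S must lie on the link (a_S < l_S)")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


DEFAULT_GEOMETRY = ArmGeometry()


def _as_phi(phi) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (4,):
        raise ValueError(f"motor-neuron activation must be a 4-vector, got shape {phi.shape}")
    if not np.all(np.isfinite(phi)):
        raise ValueError("motor-neuron activation must be finite")
    return np.clip(phi, 0.0, 1.0)


def mn_to_joint_angles(phi) -> np.ndarray:
    """Map motor-neuron activations to joint angles (radians).

    Per joint, ``theta = (phi_Ag - phi_An) * pi/2 + pi/2`` using that joint's
    agonist/antagonist pair, so activations in [0, 1] place both joints in
    [0, pi]. Returns ``[theta_S, theta_E]``.
    """
    phi = _as_phi(phi)
    theta_s = (phi[0] - phi[1]) * (np.pi / 2) + np.pi / 2
    theta_e = (phi[2] - phi[3]) * (np.pi / 2) + np.pi / 2
    return np.array([theta_s, theta_e])


def joint_angles_to_muscle_lengths(theta, geom: ArmGeometry = DEFAULT_GEOMETRY) -> np.ndarray:
    """Muscle lengths ``[mu_Ag^S, mu_An^S, mu_Ag^E, mu_An^E]`` from joint angles.

    Law of cosines around each joint: the agonist length uses ``+2ab cos``,
    the antagonist ``-2ab cos``, so the pair satisfies
    ``mu_Ag^2 + mu_An^2 = 2(a^2 + b^2)`` identically.
    """
    theta = np.asarray(theta, dtype=float)
    c_s, c_e = np.cos(theta[0]), np.cos(theta[1])
    a_s, b_s, a_e, b_e = geom.a_S, geom.b_S, geom.a_E, geom.b_E
    # clip guards tiny negative radicands from rounding at theta = 0 or pi
    return np.sqrt(np.clip(np.array([
        a_s ** 2 + b_s ** 2 + 2 * a_s * b_s * c_s,
        a_s ** 2 + b_s ** 2 - 2 * a_s * b_s * c_s,
        a_e ** 2 + b_e ** 2 + 2 * a_e * b_e * c_e,
        a_e ** 2 + b_e ** 2 - 2 * a_e * b_e * c_e,
    ]), 0.0, None))


def forward_kinematics(theta, geom: ArmGeometry = DEFAULT_GEOMETRY) -> np.ndarray:
    """End-effector position in the arm's own frame (shoulder at the origin).

    ``x1 = (l_S - a_S) cos th_S + l_E cos(th_S + th_E)`` and the sine analogue
    for ``x2``; the left arm mirrors ``x1 -> -x1`` so the two arms face each
    other across the body midline.
    """
    theta = np.asarray(theta, dtype=float)
    th_s, th_e = theta[0], theta[1]
    x1 = (geom.l_S - geom.a_S) * np.cos(th_s) + geom.l_E * np.cos(th_s + th_e)
    x2 = (geom.l_S - geom.a_S) * np.sin(th_s) + geom.l_E * np.sin(th_s + th_e)
    if geom.side == "left":
        x1 = -x1
    return np.array([x1, x2])


def shoulder_origin(geom: ArmGeometry) -> np.ndarray:
    """Global position of this arm's shoulder (arms offset laterally)."""
    half = geom.shoulder_separation / 2
    return np.array([half if geom.side == "right" else -half, 0.0])


def muscle_feature_vector(theta, geom: ArmGeometry = DEFAULT_GEOMETRY) -> np.ndarray:
    """Proprioceptive feature: the 4-vector of muscle lengths at ``theta``.

    This is the training/input feature of the proprioceptive-cortex map.
    """
    return joint_angles_to_muscle_lengths(theta, geom)


def reach_radius(geom: ArmGeometry = DEFAULT_GEOMETRY) -> float:
    """Maximum end-effector distance from the shoulder: (l_S - a_S) + l_E."""
    return (geom.l_S - geom.a_S) + geom.l_E
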