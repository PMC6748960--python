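"""Assembly of one hemispheric reaching system and the coupled bimanual model.

A hemisphere owns: a two-link arm, the proprioceptive-cortex SOM (muscle
lengths -> 15x15 sheet), the motor-cortex map layer (SOM over flattened
proprioceptive sheets) and CANN dynamics, the linear motor-neuron readout,
the prefrontal goal map (SOM over workspace locations) with its learned
goal-to-motor projection, and a basal-ganglia loop. Building a hemisphere
runs the developmental sequence: motor babbling -> map formation -> closing
the sensory-motor loop. The bimanual model is two such hemispheres, by
default each with its own babbling and map topology (as between real
hemispheres), coupled at the motor-cortex level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arm import ArmGeometry, forward_kinematics, mn_to_joint_angles, muscle_feature_vector
from .basal_ganglia import BGLoop, MSNParams, STNGPeParams, STNGPeState, ValueParams
from .cann import CANNKernel, CANNState, build_lateral_kernel, cann_output
from .config import RunConfig
from .motor_cortex import (LesionSpec, ReadoutWeights, mn_readout, train_mc_mn)
from .pfc import (ArbitrationSchedule, GoalMap, GoalToMotorWeights, pfc_activation,
                  pfc_to_mc)
from .som import SOMGrid, SOMTrainingSchedule, som_activation, som_train, winner

__all__ = ["Hemisphere", "BimanualModel", "build_model", "build_hemisphere",
           "save_checkpoint", "load_checkpoint"]

REST_PHI = np.zeros(4)  # zero drive -> both joints at pi/2


@dataclass
class Hemisphere:
    """One cortico-basal-ganglia system controlling one arm."""

    geom: ArmGeometry
    pc_som: SOMGrid
    mc_som: SOMGrid
    mc_kernel: CANNKernel
    readout: ReadoutWeights
    goal_map: GoalMap
    pfc_w: GoalToMotorWeights
    config: RunConfig
    ik_thetas: np.ndarray  # (m, 2) posture table for inverse kinematics
    ik_positions: np.ndarray  # (m, 2) matching end-effector positions
    lesion: LesionSpec | None = None

    def copy(self) -> "Hemisphere":
        from dataclasses import replace
        return replace(self, pc_som=self.pc_som.copy(), mc_som=self.mc_som.copy(),
                       readout=self.readout.copy(),
                       goal_map=GoalMap(grid=self.goal_map.grid.copy()),
                       pfc_w=self.pfc_w.copy())

    # -- kinematic shortcuts ------------------------------------------------
    @property
    def n(self) -> int:
        return self.mc_som.n

    def rest_position(self) -> np.ndarray:
        return forward_kinematics(mn_to_joint_angles(REST_PHI), self.geom)

    def inverse_kinematics(self, x_targ) -> np.ndarray:
        """Posture whose end effector is closest to the target (table lookup)."""
        x_targ = np.asarray(x_targ, dtype=float)
        d2 = np.sum((self.ik_positions - x_targ) ** 2, axis=1)
        return self.ik_thetas[int(np.argmin(d2))]

    # -- cortical responses -------------------------------------------------
    def pc_sheet(self, theta) -> np.ndarray:
        """Proprioceptive-cortex activity for a posture."""
        return som_activation(muscle_feature_vector(theta, self.geom), self.pc_som)

    def g_pc(self, theta) -> np.ndarray:
        """Motor-cortex map-layer response to the proprioceptive sheet."""
        return som_activation(self.pc_sheet(theta).ravel(), self.mc_som)

    def goal_node(self, x_targ) -> tuple[int, int]:
        """MC node that is activated when the arm is at the target posture."""
        theta = self.inverse_kinematics(x_targ)
        return winner(self.pc_sheet(theta).ravel(), self.mc_som)

    def fresh_cann(self) -> CANNState:
        c = self.config.cann
        return CANNState.zeros(self.n, tau=c.tau, dt=c.dt, b=c.b)

    def fresh_bg(self, rng) -> BGLoop:
        cfg = self.config
        params = STNGPeParams(
            eps_g=cfg.bg.eps_g, eps_s=cfg.bg.eps_s, w_sg=cfg.bg.w_sg,
            w_gs=cfg.bg.w_gs, tau_STN=cfg.bg.tau_STN, tau_GPe=cfg.bg.tau_GPe,
            lambda_STN=cfg.bg.lambda_STN, sigma_lat_g=cfg.bg.sigma_lat_g,
            sigma_lat_s=cfg.bg.sigma_lat_s, dt=cfg.cann.dt)
        return BGLoop(
            value_params=ValueParams(sigma_V=cfg.bg.sigma_V),
            msn_params=MSNParams(lambda_D1=cfg.bg.lambda_D1, lambda_D2=cfg.bg.lambda_D2,
                                 t_D1=cfg.bg.t_D1, t_D2=cfg.bg.t_D2),
            stn_gpe=STNGPeState.random(self.n, rng, params=params,
                                       amplitude=cfg.bg.init_amplitude),
            thalamus=CANNState.zeros(self.n, tau=cfg.cann.tau, dt=cfg.cann.dt,
                                     b=cfg.bg.thal_b),
            thal_kernel=self.mc_kernel,
            A_D1=cfg.bg.A_D1, A_D2=cfg.bg.A_D2, msn_gain=cfg.bg.msn_gain)

    def pfc_drive(self, x_targ) -> tuple[np.ndarray, np.ndarray]:
        """(U, G_PFC): goal-code sheet and the motor drive it induces.

        The projected drive is rectified: negative lobes left by the delta
        rule would otherwise be squared into spurious activity by the CANN
        output stage.
        """
        U = pfc_activation(np.asarray(x_targ, dtype=float), self.goal_map)
        return U, np.maximum(pfc_to_mc(U, self.pfc_w), 0.0)

    # -- loop closure -------------------------------------------------------
    def settle(self, I: np.ndarray, steps: int, lesion: LesionSpec | None = None) -> CANNState:
        """Run the MC CANN from rest under constant input (lesion applied each step)."""
        from .cann import cann_step
        from .motor_cortex import apply_lesion
        state = self.fresh_cann()
        for _ in range(steps):
            state = cann_step(state, self.mc_kernel, I)
            if lesion is not None and lesion.size > 0:
                state.g = apply_lesion(state.g, lesion)
                state.G = cann_output(state)
        return state

    def loop_response(self, phi_d, readout: ReadoutWeights,
                      lesion: LesionSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Traverse the sensory-motor loop once for a desired MN activation.

        phi_d moves the arm; the resulting proprioception drives the motor
        cortex (input gain A_PC); the settled output is read out (unclipped,
        for training). Returns (G, phi_actual).
        """
        theta = mn_to_joint_angles(phi_d)
        I = self.config.gains.A_PC * self.g_pc(theta)
        state = self.settle(I, self.config.train.loop_settle_steps, lesion=lesion)
        phi = mn_readout(state.G, readout, clip=False)
        return state.G, phi


def _ik_table(geom: ArmGeometry, resolution: int = 80) -> tuple[np.ndarray, np.ndarray]:
    th = np.linspace(0.0, np.pi, resolution)
    ts, te = np.meshgrid(th, th, indexing="ij")
    thetas = np.stack([ts.ravel(), te.ravel()], axis=1)
    l1 = geom.l_S - geom.a_S
    x1 = l1 * np.cos(thetas[:, 0]) + geom.l_E * np.cos(thetas.sum(axis=1))
    x2 = l1 * np.sin(thetas[:, 0]) + geom.l_E * np.sin(thetas.sum(axis=1))
    if geom.side == "left":
        x1 = -x1
    return thetas, np.stack([x1, x2], axis=1)


def build_hemisphere(cfg: RunConfig, rng, side: str = "right") -> Hemisphere:
    """Developmental sequence for one hemisphere.

    1. motor babbling: uniform random MN activations exercise the arm;
    2. the proprioceptive SOM organizes over muscle-length vectors;
    3. the motor-cortex SOM organizes over flattened proprioceptive sheets;
    4. the prefrontal SOM organizes over visited workspace locations;
    5. the MC->MN readout is trained until the loop reproduces babbled
       commands (loop closure).
    """
    n = cfg.som.n
    geom = ArmGeometry(a_S=cfg.arm.a_S, b_S=cfg.arm.b_S, a_E=cfg.arm.a_E,
                       b_E=cfg.arm.b_E, l_S=cfg.arm.l_S, l_E=cfg.arm.l_E,
                       side=side, shoulder_separation=cfg.arm.shoulder_separation)

    phis = rng.uniform(0.0, 1.0, size=(cfg.train.n_babble, 4))
    thetas = np.array([mn_to_joint_angles(p) for p in phis])
    features = np.array([muscle_feature_vector(t, geom) for t in thetas])
    positions = np.array([forward_kinematics(t, geom) for t in thetas])

    sched = SOMTrainingSchedule(n_steps=cfg.som.n_steps, rate_initial=cfg.som.rate_initial,
                                rate_final=cfg.som.rate_final, radius_final=cfg.som.radius_final)

    lo, hi = features.min(axis=0), features.max(axis=0)
    pc_init = SOMGrid(weights=rng.uniform(lo, hi, size=(n, n, 4)), sigma_act=cfg.som.sigma_pc)
    pc_som = som_train(features, pc_init, sched, rng)

    pc_sheets = np.array([som_activation(f, pc_som).ravel() for f in features])
    mc_init = SOMGrid(weights=rng.uniform(0.0, 1.0, size=(n, n, n * n)),
                      sigma_act=cfg.som.sigma_mc)
    mc_som = som_train(pc_sheets, mc_init, sched, rng)

    plo, phi_hi = positions.min(axis=0), positions.max(axis=0)
    pfc_init = SOMGrid(weights=rng.uniform(plo, phi_hi, size=(n, n, 2)),
                       sigma_act=cfg.som.sigma_pfc)
    pfc_som = som_train(positions, pfc_init, sched, rng)

    kernel = build_lateral_kernel(cfg.cann.A_lat, cfg.cann.sigma_lat, cfg.cann.K, n,
                                  literal_sum_offsets=cfg.cann.literal_sum_offsets)
    ik_thetas, ik_positions = _ik_table(geom)

    hemi = Hemisphere(geom=geom, pc_som=pc_som, mc_som=mc_som, mc_kernel=kernel,
                      readout=ReadoutWeights.zeros(n, A_MN=cfg.gains.A_MN,
                                                   eta=cfg.gains.eta_mc_mn),
                      goal_map=GoalMap(grid=pfc_som),
                      pfc_w=GoalToMotorWeights.zeros(n, eta=cfg.gains.eta_pfc_mc),
                      config=cfg, ik_thetas=ik_thetas, ik_positions=ik_positions)

    readout, _ = train_mc_mn(lambda phi_d, w: hemi.loop_response(phi_d, w),
                             phis, hemi.readout, sweeps=cfg.train.loop_sweeps,
                             tol=cfg.train.loop_tol)
    hemi.readout = readout
    return hemi


def _mirror_hemisphere(hemi: Hemisphere, cfg: RunConfig) -> Hemisphere:
    """Left twin of a trained right hemisphere.

    Mirror-symmetric arms with identical babbling produce identical muscle
    length streams, so the posture maps and readout transfer verbatim. The
    goal map is trained on workspace *positions*, which mirror across the
    midline, so its weights transfer with the x1 component negated — node
    identities are preserved, keeping the two motor maps and the shared
    goal-to-motor weights in exact correspondence.
    """
    geom = ArmGeometry(a_S=hemi.geom.a_S, b_S=hemi.geom.b_S, a_E=hemi.geom.a_E,
                       b_E=hemi.geom.b_E, l_S=hemi.geom.l_S, l_E=hemi.geom.l_E,
                       side="left", shoulder_separation=hemi.geom.shoulder_separation)
    ik_thetas, ik_positions = _ik_table(geom)
    goal_grid = hemi.goal_map.grid.copy()
    goal_grid.weights[:, :, 0] *= -1.0
    return Hemisphere(geom=geom, pc_som=hemi.pc_som.copy(), mc_som=hemi.mc_som.copy(),
                      mc_kernel=hemi.mc_kernel,
                      readout=hemi.readout.copy(),
                      goal_map=GoalMap(grid=goal_grid),
                      pfc_w=hemi.pfc_w.copy(), config=cfg,
                      ik_thetas=ik_thetas, ik_positions=ik_positions)


@dataclass
class BimanualModel:
    """Two coupled hemispheric systems. ``right`` controls the (paretic after
    lesioning) right arm, ``left`` the non-paretic arm."""

    right: Hemisphere
    left: Hemisphere
    config: RunConfig

    def hemisphere(self, side: str) -> Hemisphere:
        return self.right if side == "right" else self.left

    def copy(self) -> "BimanualModel":
        return BimanualModel(right=self.right.copy(), left=self.left.copy(),
                             config=self.config)

    def arbitration(self) -> ArbitrationSchedule:
        g = self.config.gains
        return ArbitrationSchedule(horizon=g.arbitration_horizon,
                                   total=g.arbitration_total,
                                   A_BG_floor=g.arbitration_floor)


def build_model(cfg: RunConfig, seed: int | None = None,
                independent_left: bool = True) -> BimanualModel:
    """Build and developmentally train both hemispheres (maps + loop closure).

    By default the left hemisphere runs its own babbling and map formation
    (continuing the same generator), so the two motor maps have unrelated
    topologies — the coupling between them then acts as structured
    interference rather than a node-aligned echo, as between real
    hemispheres. ``independent_left=False`` instead mirrors the trained right
    hemisphere exactly (nodewise-corresponding maps).
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    right = build_hemisphere(cfg, rng, side="right")
    if independent_left:
        left = build_hemisphere(cfg, rng, side="left")
    else:
        left = _mirror_hemisphere(right, cfg)
    return BimanualModel(right=right, left=left, config=cfg)


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(model: BimanualModel, path) -> None:
    """Single-archive NPZ checkpoint: all weights + config YAML + seed."""
    import yaml
    arrays = {}
    for side in ("right", "left"):
        h = model.hemisphere(side)
        arrays[f"{side}_pc_w"] = h.pc_som.weights
        arrays[f"{side}_mc_w"] = h.mc_som.weights
        arrays[f"{side}_pfc_som_w"] = h.goal_map.grid.weights
        arrays[f"{side}_readout"] = h.readout.W
        arrays[f"{side}_pfc_w"] = h.pfc_w.W
    arrays["config_yaml"] = np.frombuffer(
        yaml.safe_dump(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> BimanualModel:
    import yaml
    from .config import RunConfig
    with np.load(path) as z:
        cfg = RunConfig.from_dict(yaml.safe_load(bytes(z["config_yaml"]).decode()))
        sides = {}
        for side in ("right", "left"):
            geom = ArmGeometry(a_S=cfg.arm.a_S, b_S=cfg.arm.b_S, a_E=cfg.arm.a_E,
                               b_E=cfg.arm.b_E, l_S=cfg.arm.l_S, l_E=cfg.arm.l_E,
                               side=side, shoulder_separation=cfg.arm.shoulder_separation)
            kernel = build_lateral_kernel(cfg.cann.A_lat, cfg.cann.sigma_lat, cfg.cann.K,
                                          cfg.som.n,
                                          literal_sum_offsets=cfg.cann.literal_sum_offsets)
            ik_thetas, ik_positions = _ik_table(geom)
            sides[side] = Hemisphere(
                geom=geom,
                pc_som=SOMGrid(weights=z[f"{side}_pc_w"], sigma_act=cfg.som.sigma_pc),
                mc_som=SOMGrid(weights=z[f"{side}_mc_w"], sigma_act=cfg.som.sigma_mc),
                mc_kernel=kernel,
                readout=ReadoutWeights(W=z[f"{side}_readout"], A_MN=cfg.gains.A_MN,
                                       eta=cfg.gains.eta_mc_mn),
                goal_map=GoalMap(grid=SOMGrid(weights=z[f"{side}_pfc_som_w"],
                                              sigma_act=cfg.som.sigma_pfc)),
                pfc_w=GoalToMotorWeights(W=z[f"{side}_pfc_w"], eta=cfg.gains.eta_pfc_mc),
                config=cfg, ik_thetas=ik_thetas, ik_positions=ik_positions)
    return BimanualModel(right=sides["right"], left=sides["left"], config=cfg)
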