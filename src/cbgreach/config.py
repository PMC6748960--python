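"""Run configuration: every tunable model constant, grouped, with YAML
round-tripping and strict validation (unknown keys are rejected)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class ArmConfig:
    a_S: float = 0.04
    b_S: float = 0.07
    a_E: float = 0.03
    b_E: float = 0.08
    l_S: float = 0.3
    l_E: float = 0.3
    shoulder_separation: float = 0.4

    def validate(self) -> None:
        for name in ("a_S", "b_S", "a_E", "b_E", "l_S", "l_E"):
            if getattr(self, name) <= 0:
                raise ValueError(f"arm.{name} must be positive")
        if self.a_S >= self.l_S:
            raise ValueError("arm.a_S must be < arm.l_S")


@dataclass
class SOMConfig:
    n: int = 15
    sigma_pc: float = 0.015
    sigma_mc: float = 2.5
    sigma_pfc: float = 0.1
    n_steps: int = 4000
    rate_initial: float = 0.5
    rate_final: float = 0.01
    radius_final: float = 1.0
    retrain_steps: int = 1500
    retrain_rate_initial: float = 0.1
    retrain_radius_initial: float = 2.0

    def validate(self) -> None:
        if self.n < 3:
            raise ValueError("som.n must be >= 3")
        for name in ("sigma_pc", "sigma_mc", "sigma_pfc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"som.{name} must be positive")


@dataclass
class CANNConfig:
    A_lat: float = 0.5
    sigma_lat: float = 1.2
    K: float = 0.02
    tau: float = 1.0
    dt: float = 0.1
    b: float = 20.0
    literal_sum_offsets: bool = False

    def validate(self) -> None:
        if self.sigma_lat <= 0 or self.A_lat <= 0 or self.K < 0:
            raise ValueError("cann kernel parameters out of range")
        if not self.dt < self.tau:
            raise ValueError("cann.dt must be < cann.tau")


@dataclass
class BGConfig:
    sigma_V: float = 0.2
    lambda_D1: float = 50.0
    lambda_D2: float = -50.0
    t_D1: float = 0.0
    t_D2: float = 0.05
    eps_g: float = -0.1
    eps_s: float = 0.2
    w_sg: float = 2.0
    w_gs: float = 2.0
    tau_STN: float = 1.0
    tau_GPe: float = 2.0
    lambda_STN: float = 3.0
    sigma_lat_g: float = 1.5
    sigma_lat_s: float = 1.5
    A_D1: float = 2.0
    A_D2: float = 2.0
    msn_gain: float = 10.0
    thal_b: float = 0.2
    init_amplitude: float = 0.3

    def validate(self) -> None:
        if self.sigma_V <= 0:
            raise ValueError("bg.sigma_V must be positive")
        if self.lambda_D1 != -self.lambda_D2:
            raise ValueError("bg pathways require lambda_D1 = -lambda_D2")


@dataclass
class GainsConfig:
    A_PC: float = 0.3
    A_MN: float = 1.0
    eta_mc_mn: float = 0.1
    eta_pfc_mc: float = 0.1
    arbitration_total: float = 2.0
    arbitration_horizon: int = 50
    arbitration_floor: float = 0.3

    def validate(self) -> None:
        if self.A_PC < 0 or self.A_MN <= 0:
            raise ValueError("gains out of range")


@dataclass
class CouplingConfig:
    # per-task signed coupling of the two motor cortices (right arm paretic)
    symmetric_eps_right: float = -0.5
    symmetric_eps_left: float = 0.5
    congruent_eps_right: float = -0.2
    congruent_eps_left: float = 0.89
    incongruent_eps_right: float = -0.2
    incongruent_eps_left: float = 0.8

    def validate(self) -> None:
        pass

    def for_task(self, task: str) -> tuple[float, float]:
        try:
            return (getattr(self, f"{task}_eps_right"), getattr(self, f"{task}_eps_left"))
        except AttributeError:
            raise KeyError(f"no coupling preset for task {task!r}") from None


@dataclass
class TaskConfig:
    far_distance: float = 0.3
    near_ratio: float = 0.5
    steps_per_trial: int = 100
    n_trials: int = 50
    reach_threshold: float = 0.02
    smooth_window: int = 5
    equivalence_margin: float = 0.10
    # lesion size for the aiming (PRV) experiments: large enough that the
    # unimanual paretic deficit matches pronounced hemiparesis
    aiming_lesion_size: int = 6

    def validate(self) -> None:
        if self.far_distance <= 0 or not (0 < self.near_ratio < 1):
            raise ValueError("task distances out of range")
        if self.steps_per_trial < 1 or self.n_trials < 1:
            raise ValueError("task sizes out of range")


@dataclass
class TrainConfig:
    n_babble: int = 400
    loop_sweeps: int = 8
    loop_tol: float = 0.05
    loop_settle_steps: int = 25
    retrain_trials: int = 30

    def validate(self) -> None:
        if self.n_babble < 1:
            raise ValueError("train.n_babble must be >= 1")


@dataclass
class SweepConfig:
    sizes: list = field(default_factory=lambda: [1, 2, 3, 4, 5, 6, 7])
    conditions: list = field(default_factory=lambda: ["unimanual", "bimanual", "cimt"])
    stages: list = field(default_factory=lambda: ["acute", "chronic"])
    n_seeds: int = 10
    test_trials: int = 3

    def validate(self) -> None:
        if any(s < 0 or s > 7 for s in self.sizes):
            raise ValueError("sweep sizes must lie in 0..7")
        if self.n_seeds < 1:
            raise ValueError("sweep.n_seeds must be >= 1")


_GROUPS = {
    "arm": ArmConfig,
    "som": SOMConfig,
    "cann": CANNConfig,
    "bg": BGConfig,
    "gains": GainsConfig,
    "coupling": CouplingConfig,
    "task": TaskConfig,
    "train": TrainConfig,
    "sweep": SweepConfig,
}


@dataclass
class RunConfig:
    arm: ArmConfig = field(default_factory=ArmConfig)
    som: SOMConfig = field(default_factory=SOMConfig)
    cann: CANNConfig = field(default_factory=CANNConfig)
    bg: BGConfig = field(default_factory=BGConfig)
    gains: GainsConfig = field(default_factory=GainsConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    task: TaskConfig = field(default_factory=TaskConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    seed: int = 0

    def validate(self) -> "RunConfig":
        for name in _GROUPS:
            getattr(self, name).validate()
        return self

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        for name, group_cls in _GROUPS.items():
            sub = d.pop(name, {})
            if not isinstance(sub, dict):
                raise ValueError(f"config section {name!r} must be a mapping")
            known = {f.name for f in dataclasses.fields(group_cls)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
            kwargs[name] = group_cls(**sub)
        seed = d.pop("seed", 0)
        if d:
            raise ValueError(f"unknown top-level config keys: {sorted(d)}")
        return cls(seed=int(seed), **kwargs).validate()


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(data)


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest of the full parameter set (recorded in outputs)."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
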