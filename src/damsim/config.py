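"""Typed configuration for the Dimensional Attachment Model.

Every model constant, arena parameter and initial condition is exposed here as a
validated, serializable field.  The shipped defaults are the published study
conditions of the model: an adapted dyad (the attacher's dimensional level equals
the caregiver's feature level) interacting for 1,000 iterations in a 30x30 lab.

The configuration is a flat, dotted key space (``model.*``, ``arena.*``,
``sim.*``) when serialized to YAML/JSON; unknown keys are rejected so that a
typo'd override fails loudly instead of silently running the defaults.
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

Dimension = Literal["avoidance", "ambivalence"]
Role = Literal["attacher", "caregiver"]


class DimensionLevels(BaseModel):
    """Stored dimensional levels of the dyad.

    ``A_v``/``A_m`` are the attacher's avoidance and ambivalence; ``I_n``/``U_n``
    the caregiver's insensitivity and unresponsiveness.  In an adapted dyad the
    attacher's level equals the caregiver's feature (A_v = I_n, A_m = U_n):
    the acquisition of the dimension is assumed to have already happened before
    the simulated session.
    """

    model_config = ConfigDict(extra="forbid")

    A_v: float = Field(default=0.5, ge=0.0, le=1.0)
    A_m: float = Field(default=0.5, ge=0.0, le=1.0)
    I_n: float = Field(default=0.5, ge=0.0, le=1.0)
    U_n: float = Field(default=0.5, ge=0.0, le=1.0)
    require_adapted: bool = True

    @model_validator(mode="after")
    def _check_adapted(self) -> "DimensionLevels":
        if self.require_adapted:
            if self.A_v != self.I_n:
                raise ValueError(
                    f"adapted dyad requires A_v == I_n (got {self.A_v} != {self.I_n}); "
                    "set require_adapted=False for a mismatched dyad"
                )
            if self.A_m != self.U_n:
                raise ValueError(
                    f"adapted dyad requires A_m == U_n (got {self.A_m} != {self.U_n})"
                )
        return self

    @classmethod
    def adapted(cls, dimension: Dimension, level: float) -> "DimensionLevels":
        """Levels for an adapted dyad at ``level`` on one dimension (other at 0.5)."""
        if dimension == "avoidance":
            return cls(A_v=level, I_n=level)
        return cls(A_m=level, U_n=level)


class ModelConstants(BaseModel):
    """Constants of the drive/need/threshold equations.

    Defaults are the published values: coupling factors C_f,av = 4 and
    C_f,am = 2, drive offsets c0*, threshold baseline T_bl = 0.75 with
    excursion tau = 0.08, and action-rule margins k_E = 1.01, k_P = 1.1.

    ``percept_scale`` divides the perception variables (S_E, D_P, which live on
    a 0-100 scale) inside the drive equations so that drives stay of order one
    and needs oscillate around the 0.75 baseline.  ``variable_c0`` switches the
    avoidant offsets to the level-dependent form c0a_av = -0.30*A_v + 0.60,
    c0c_av = -0.30*A_v + 0.59.
    """

    model_config = ConfigDict(extra="forbid")

    Cf_av: float = Field(default=4.0, ge=0.0)
    Cf_am: float = Field(default=2.0, ge=0.0)
    c0a_av: float = 0.49
    c0c_av: float = 0.50
    c0a_am: float = 0.20
    c0c_am: float = 0.50
    T_bl: float = 0.75
    tau: float = Field(default=0.08, ge=0.0)
    k_E: float = 1.01
    k_P: float = 1.10
    K_coeff: float = 0.5
    percept_scale: float = Field(default=100.0, gt=0.0)
    variable_c0: bool = False

    def c0_avoidant(self, A_v: float) -> Tuple[float, float]:
        """(c0a_av, c0c_av), honoring the variable-coefficient variant."""
        if self.variable_c0:
            return (-0.30 * A_v + 0.60, -0.30 * A_v + 0.59)
        return (self.c0a_av, self.c0c_av)


class ArenaConfig(BaseModel):
    """Geometry of the square lab and the agents' kinematic envelope.

    Coordinates run from 1 to ``S`` (actual side S-1).  Speeds and visions are
    fractions of the reference length ``L``: the child moves L/9 and sees L/3;
    the caregiver moves L/3 and sees L/1, i.e. three times the child's speed
    and vision.  ``L`` defaults to the lab diagonal sqrt(2)*S, under which the
    caregiver's vision covers the whole lab; ``L_mode='double'`` gives L = 2S.
    """

    model_config = ConfigDict(extra="forbid")

    S: float = Field(default=30.0, gt=1.0)
    L_mode: Literal["diagonal", "double"] = "diagonal"
    n_objects_per_agent: int = Field(default=3, ge=0)
    refractory_period: int = Field(default=7, ge=0)
    # Fixed object placements: child objects in the top corner region,
    # caregiver objects in the bottom corner region.
    child_objects: Optional[Tuple[Tuple[float, float], ...]] = None
    caregiver_objects: Optional[Tuple[Tuple[float, float], ...]] = None
    # Optional explicit overrides for the derived kinematics.
    child_speed: Optional[float] = None
    child_vision: Optional[float] = None
    caregiver_speed: Optional[float] = None
    caregiver_vision: Optional[float] = None

    @property
    def L(self) -> float:
        return math.sqrt(2.0) * self.S if self.L_mode == "diagonal" else 2.0 * self.S

    def speed(self, role: Role) -> float:
        if role == "attacher":
            return self.child_speed if self.child_speed is not None else self.L / 9.0
        return self.caregiver_speed if self.caregiver_speed is not None else self.L / 3.0

    def vision(self, role: Role) -> float:
        if role == "attacher":
            return self.child_vision if self.child_vision is not None else self.L / 3.0
        return self.caregiver_vision if self.caregiver_vision is not None else self.L / 1.0

    def object_positions(self, owner: Role) -> Tuple[Tuple[float, float], ...]:
        if owner == "attacher":
            if self.child_objects is not None:
                return self.child_objects
            top = self.S
            base = ((top - 3.0, top - 3.0), (top - 1.0, top - 2.0), (top - 2.0, top - 1.0))
        else:
            if self.caregiver_objects is not None:
                return self.caregiver_objects
            base = ((2.0, 3.0), (3.0, 2.0), (4.0, 4.0))
        return base[: self.n_objects_per_agent]


class InitialState(BaseModel):
    """Initial conditions, identical in all published simulations."""

    model_config = ConfigDict(extra="forbid")

    K: int = Field(default=0, ge=0)
    N: float = 0.75
    S_E: float = 50.0
    D_P: float = 50.0
    i: float = 55.0
    child_pos: Tuple[float, float] = (9.0, 15.0)
    caregiver_pos: Tuple[float, float] = (21.0, 15.0)


class SimulationConfig(BaseModel):
    """Full declarative description of one simulation run."""

    model_config = ConfigDict(extra="forbid")

    dimension: Dimension = "avoidance"
    levels: DimensionLevels = Field(default_factory=DimensionLevels)
    consts: ModelConstants = Field(default_factory=ModelConstants)
    arena: ArenaConfig = Field(default_factory=ArenaConfig)
    init: InitialState = Field(default_factory=InitialState)
    n_iterations: int = Field(default=1000, ge=1)
    seed: int = 0
    # Care provision is threshold-only in the published model; the proximity
    # gate is an experimentation variant.
    care_requires_proximity: bool = False
    care_proximity: float = 1.0
    conflict_action: Literal["explore", "none"] = "explore"

    @model_validator(mode="after")
    def _check_positions(self) -> "SimulationConfig":
        for name, (x, y) in (
            ("child_pos", self.init.child_pos),
            ("caregiver_pos", self.init.caregiver_pos),
        ):
            if not (1.0 <= x <= self.arena.S and 1.0 <= y <= self.arena.S):
                raise ValueError(f"{name}={x, y} outside lab [1, {self.arena.S}]^2")
        return self


def load_config(path: str) -> SimulationConfig:
    """Load a YAML config file; missing keys take the published defaults.

    An empty file yields the full default configuration; unknown keys raise.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return SimulationConfig.model_validate(data)


def dump_config(config: SimulationConfig, path: Optional[str] = None) -> str:
    """Serialize a config to YAML; round-trips through :func:`load_config`."""
    text = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
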