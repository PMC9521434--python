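"""Controller and main loop of the dyadic simulation.

Each iteration applies a fixed synchronous update order:

1. behavioral variables — the inter-agent distance ``d`` from the current
   positions and the caregiver's cumulative indifference ``i``;
2. perceptions — S_E (avoidance) or D_P (ambivalence) for both agents;
3. drives — each agent's drive from the care clock, the *other* agent's need
   of the previous iteration, and the agent's fresh perception;
4. needs — Hill saturation of the drives;
5. thresholds — hysteretic noisy baseline per agent;
6. care clock — reset when the caregiver's need exceeds its threshold
   ("care provided"), incremented otherwise;
7. action selection — approach / explore per the set-goal rule;
8. movement — simultaneous speed-limited moves; exploration may consume an
   object of interest, triggering its refractory period.

The selection rule compares need against threshold *and* the controlled
perception against a margin times its set-goal: an agent explores when it
feels no need and its perception sits below the margin, approaches when it
feels a need and its perception sits above.  The two remaining (conflicting)
quadrants fall back to exploration — the default motivational baseline — and
are flagged in the record so the share of incoherent iterations is auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Tuple

import numpy as np
import pandas as pd

from . import core
from .arena import Arena, Position, random_direction_move, step_toward
from .config import Dimension, Role, SimulationConfig
from .core import TargetSet
from .rng import NoiseStreams

Action = Literal["approach", "explore", "none"]


@dataclass(frozen=True)
class StepRecord:
    """Full state snapshot after one iteration."""

    iteration: int
    x_a: float
    y_a: float
    x_c: float
    y_c: float
    drive_a: float
    drive_c: float
    N_R: float
    N_G: float
    T_R: float
    T_G: float
    S_Ea: float
    S_Ec: float
    D_Pa: float
    D_Pc: float
    i: float
    d: float
    K: int
    care_provided: bool
    action_a: Action
    action_c: Action
    conflict_a: bool
    conflict_c: bool
    N_ex: int


@dataclass
class Trajectory:
    """Ordered per-iteration records plus the config that produced them."""

    records: List[StepRecord]
    config: SimulationConfig

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per iteration, fixed column order (the documented CSV schema)."""
        return pd.DataFrame([r.__dict__ for r in self.records])


def activate_dimension(
    A_v: float, A_m: float, beta: float, rng
) -> Tuple[Dimension, Tuple[float, float]]:
    """Winner-take-all softmax selection of the session's dimension.

    s(d_i) = exp(beta*(d_i + r_i)) / sum_j exp(beta*(d_j + r_j)) with standard
    normal contextual noise r_i; the dimension with the larger softmax value
    wins (avoidance on exact ties).  Evaluation is shifted by the max exponent
    so large |beta| cannot overflow.
    """
    r1, r2 = rng.normal(), rng.normal()
    z = (beta * (A_v + r1), beta * (A_m + r2))
    m = max(z)
    exps = (math.exp(z[0] - m), math.exp(z[1] - m))
    total = exps[0] + exps[1]
    softmax = (exps[0] / total, exps[1] / total)
    dimension: Dimension = "avoidance" if softmax[0] >= softmax[1] else "ambivalence"
    return dimension, softmax


def select_action(
    role: Role,
    dimension: Dimension,
    N: float,
    T: float,
    percept: float,
    targets: TargetSet,
    consts,
    conflict_action: Action = "explore",
) -> Tuple[Action, bool]:
    """Set-goal action rule; returns ``(action, conflict_flag)``.

    Coherent quadrants: (N < T and percept < k*target) -> explore;
    (N > T and percept > k*target) -> approach.  Anything else (including
    ties) is a motivational conflict resolved to ``conflict_action``.
    """
    k = consts.k_E if dimension == "avoidance" else consts.k_P
    margin = k * targets.psychological
    if N < T and percept < margin:
        return "explore", False
    if N > T and percept > margin:
        return "approach", False
    return conflict_action, True


def update_care_clock(K: int, care_provided: bool) -> int:
    """K' = 0 when care was provided this iteration, else K + 1."""
    return 0 if care_provided else K + 1


@dataclass
class _AgentState:
    role: Role
    pos: Position
    S_E: float
    D_P: float
    N: float
    N_prev: float
    T: float
    drive: float = 0.0
    targets: TargetSet = field(default_factory=TargetSet)
    h: float = 0.5
    speed: float = 1.0
    vision: float = 1.0


def _move(
    agent: _AgentState,
    action: Action,
    other_pos: Position,
    arena: Arena,
    iteration: int,
    rng,
) -> Position:
    """Execute one agent's selected action; handles object consumption."""
    if action == "none" or agent.speed <= 0:
        # zero-speed agents stay put while their internal state keeps evolving
        return agent.pos
    if action == "approach":
        return step_toward(agent.pos, other_pos, agent.speed, rng, S=arena.S)
    obj = arena.select_exploration_target(agent.pos, agent.vision, agent.role, iteration)
    if obj is None:
        return random_direction_move(agent.pos, agent.speed, rng, S=arena.S)
    new_pos = step_toward(agent.pos, obj.position, agent.speed, rng, S=arena.S)
    # Reaching the object (within the +/-0.5 arrival band) consumes it.
    if max(abs(new_pos[0] - obj.position[0]), abs(new_pos[1] - obj.position[1])) <= 0.5:
        arena.mark_explored(obj, iteration)
    return new_pos


def step(
    n: int,
    child: _AgentState,
    caregiver: _AgentState,
    K: int,
    N_ex: int,
    i_prev: float,
    arena: Arena,
    config: SimulationConfig,
    rng,
) -> Tuple[StepRecord, int, int]:
    """Advance the dyad by one iteration; returns (record, K', N_ex')."""
    consts = config.consts
    levels = config.levels
    dim = config.dimension

    # (1) behavioral variables from the current state
    d_now = core.distancing(child.pos, caregiver.pos)
    i_now = core.indifference(N_ex, n - 1) if n > 1 else i_prev

    # (2) perceptions
    if dim == "avoidance":
        child.S_E = core.update_emotional_separation(
            child.S_E, i_now, child.targets, rng["percept_child"]
        )
        caregiver.S_E = core.update_emotional_separation(
            caregiver.S_E, i_now, caregiver.targets, rng["percept_caregiver"]
        )
        percept_child, percept_cg = child.S_E, caregiver.S_E
    else:
        child.D_P = core.update_perceived_distance(
            child.D_P, d_now, child.targets, rng["percept_child"]
        )
        caregiver.D_P = core.update_perceived_distance(
            caregiver.D_P, d_now, caregiver.targets, rng["percept_caregiver"]
        )
        percept_child, percept_cg = child.D_P, caregiver.D_P

    # (3) drives — coupled through the other agent's need of the previous iteration
    if dim == "avoidance":
        drive_child = core.drive_avoidant_attacher(K, caregiver.N, child.S_E, levels, consts)
        drive_cg = core.drive_avoidant_caregiver(K, child.N, caregiver.S_E, levels, consts)
    else:
        drive_child = core.drive_ambivalent_attacher(K, caregiver.N, child.D_P, levels, consts)
        drive_cg = core.drive_ambivalent_caregiver(K, child.N, caregiver.D_P, levels, consts)

    # (4) needs
    N_R = core.need(drive_child, child.h)
    N_G = core.need(drive_cg, caregiver.h)

    # (5) thresholds (hysteresis on each agent's own need)
    T_R = core.update_threshold(N_R < child.N, consts, rng["threshold_child"])
    T_G = core.update_threshold(N_G < caregiver.N, consts, rng["threshold_caregiver"])

    # (6) care clock
    care = N_G > T_G
    if config.care_requires_proximity:
        care = care and d_now <= config.care_proximity
    K_next = update_care_clock(K, care)

    # (7) action selection
    action_child, conflict_child = select_action(
        "attacher", dim, N_R, T_R, percept_child, child.targets, consts, config.conflict_action
    )
    action_cg, conflict_cg = select_action(
        "caregiver", dim, N_G, T_G, percept_cg, caregiver.targets, consts, config.conflict_action
    )

    # (8) simultaneous movement from start-of-iteration positions
    pos_child = _move(child, action_child, caregiver.pos, arena, n, rng["move_child"])
    pos_cg = _move(caregiver, action_cg, child.pos, arena, n, rng["move_caregiver"])
    # Indifference counts the caregiver's *motivated* explorations only:
    # conflict-resolved moves are a fallback, not a choice to explore, and
    # counting them would decouple the cumulative indifference i from its
    # set-goal T_i.
    if action_cg == "explore" and not conflict_cg:
        N_ex += 1

    # commit
    child.pos, caregiver.pos = pos_child, pos_cg
    child.N_prev, caregiver.N_prev = child.N, caregiver.N
    child.N, caregiver.N = N_R, N_G
    child.T, caregiver.T = T_R, T_G
    child.drive, caregiver.drive = drive_child, drive_cg

    record = StepRecord(
        iteration=n,
        x_a=pos_child[0],
        y_a=pos_child[1],
        x_c=pos_cg[0],
        y_c=pos_cg[1],
        drive_a=drive_child,
        drive_c=drive_cg,
        N_R=N_R,
        N_G=N_G,
        T_R=T_R,
        T_G=T_G,
        S_Ea=child.S_E,
        S_Ec=caregiver.S_E,
        D_Pa=child.D_P,
        D_Pc=caregiver.D_P,
        i=i_now,
        d=d_now,
        K=K_next,
        care_provided=care,
        action_a=action_child,
        action_c=action_cg,
        conflict_a=conflict_child,
        conflict_c=conflict_cg,
        N_ex=N_ex,
    )
    return record, K_next, N_ex


def _make_agent(role: Role, config: SimulationConfig) -> _AgentState:
    init = config.init
    pos = init.child_pos if role == "attacher" else init.caregiver_pos
    return _AgentState(
        role=role,
        pos=tuple(pos),
        S_E=init.S_E,
        D_P=init.D_P,
        N=init.N,
        N_prev=init.N,
        T=config.consts.T_bl,
        targets=core.compute_targets(config.levels, role, config.dimension),
        h=core.hill_parameter(config.levels, role, config.dimension),
        speed=config.arena.speed(role),
        vision=config.arena.vision(role),
    )


def run(config: SimulationConfig, rng=None) -> Trajectory:
    """Run a full simulation; deterministic given ``config`` (incl. its seed).

    ``rng`` may inject a :class:`damsim.rng.FixtureRNG` with scripted streams;
    by default the named streams derive from ``config.seed``.
    """
    if rng is None:
        rng = NoiseStreams.from_seed(config.seed)
    arena = Arena(config.arena)
    child = _make_agent("attacher", config)
    caregiver = _make_agent("caregiver", config)
    K = config.init.K
    N_ex = 0
    i_prev = config.init.i
    records: List[StepRecord] = []
    for n in range(1, config.n_iterations + 1):
        record, K, N_ex = step(n, child, caregiver, K, N_ex, i_prev, arena, config, rng)
        records.append(record)
    return Trajectory(records=records, config=config)
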