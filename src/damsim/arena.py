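"""The 2D lab: geometry, objects of interest, vision and speed-limited movement.

The lab is a square with coordinates in [1, S].  Each agent owns a few objects
of interest placed in opposite corners (toys for the child, a desk for the
caregiver).  Exploration heads for the nearest visible, non-refractory owned
object; an object just explored loses its attraction for a fixed number of
iterations.  Movement is speed-limited: a far target is approached along the
straight line at exactly ``speed`` per iteration, a near target is "reached"
by landing at a random position within +/-0.5 of it per coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .config import ArenaConfig, Role

Position = Tuple[float, float]


@dataclass
class ObjectOfInterest:
    """An explorable object with refractory bookkeeping.

    After being explored at iteration ``n`` the object is unselectable for
    iterations ``n+1 .. n+period`` and selectable again strictly after
    ``refractory_until``.
    """

    position: Position
    owner: Role
    refractory_until: int = -1

    def selectable(self, iteration: int) -> bool:
        return iteration > self.refractory_until


def clamp_position(pos: Position, S: float) -> Position:
    """Clamp to the lab bounds [1, S]^2 (walls absorb, they do not reflect)."""
    return (min(max(pos[0], 1.0), S), min(max(pos[1], 1.0), S))


def step_toward(pos: Position, target: Position, speed: float, rng, S: float = math.inf) -> Position:
    """One speed-limited move toward ``target``.

    Beyond the speed limit the agent covers exactly ``speed`` along the angle
    to the target; within it, the agent lands uniformly within +/-0.5 of the
    target on each coordinate (arrival jitter).  The result is clamped to the
    lab bounds.
    """
    if speed <= 0:
        raise ValueError(f"speed must be positive, got {speed}")
    dx, dy = target[0] - pos[0], target[1] - pos[1]
    dist = math.hypot(dx, dy)
    if dist > speed:
        angle = math.atan2(dy, dx)
        new = (pos[0] + speed * math.cos(angle), pos[1] + speed * math.sin(angle))
    else:
        new = (
            target[0] + rng.uniform(-0.5, 0.5),
            target[1] + rng.uniform(-0.5, 0.5),
        )
    return clamp_position(new, S)


def random_direction_move(pos: Position, speed: float, rng, S: float = math.inf) -> Position:
    """Exploration fallback: a full-speed move in a uniformly random direction."""
    angle = rng.uniform(0.0, 2.0 * math.pi)
    new = (pos[0] + speed * math.cos(angle), pos[1] + speed * math.sin(angle))
    return clamp_position(new, S)


class Arena:
    """Lab geometry plus the mutable refractory state of the objects."""

    def __init__(self, config: ArenaConfig):
        self.config = config
        self.objects: List[ObjectOfInterest] = [
            ObjectOfInterest(position=p, owner="attacher")
            for p in config.object_positions("attacher")
        ] + [
            ObjectOfInterest(position=p, owner="caregiver")
            for p in config.object_positions("caregiver")
        ]

    @property
    def S(self) -> float:
        return self.config.S

    def select_exploration_target(
        self, agent_pos: Position, vision: float, owner: Role, iteration: int
    ) -> Optional[ObjectOfInterest]:
        """Nearest owned, visible, non-refractory object — or ``None``.

        ``None`` means exploration falls back to a random-direction move.
        """
        best: Optional[ObjectOfInterest] = None
        best_dist = math.inf
        for obj in self.objects:
            if obj.owner != owner or not obj.selectable(iteration):
                continue
            dist = math.hypot(obj.position[0] - agent_pos[0], obj.position[1] - agent_pos[1])
            if dist <= vision and dist < best_dist:
                best, best_dist = obj, dist
        return best

    def mark_explored(self, obj: ObjectOfInterest, iteration: int) -> ObjectOfInterest:
        """Start (or extend) the object's refractory period at ``iteration``."""
        obj.refractory_until = max(
            obj.refractory_until, iteration + self.config.refractory_period
        )
        return obj
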