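"""Named noise streams and scripted test doubles.

One master seed fans out into independent, named streams — one per stochastic
element of the model (perception noise, threshold noise, movement jitter,
dimension activation).  Toggling or re-ordering one stochastic element
therefore never shifts the draws consumed by another, and a run is bitwise
reproducible from its seed alone.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence

import numpy as np

# Stable order of the named streams; index into the spawned children.
STREAM_NAMES = (
    "percept_child",
    "percept_caregiver",
    "threshold_child",
    "threshold_caregiver",
    "move_child",
    "move_caregiver",
    "activation",
)


class NoiseStreams:
    """Bundle of independent ``numpy`` generators, one per model noise source."""

    def __init__(self, streams: Dict[str, np.random.Generator]):
        missing = set(STREAM_NAMES) - set(streams)
        if missing:
            raise ValueError(f"missing noise streams: {sorted(missing)}")
        self._streams = streams

    @classmethod
    def from_seed(cls, seed: int) -> "NoiseStreams":
        children = np.random.SeedSequence(seed).spawn(len(STREAM_NAMES))
        return cls(
            {name: np.random.default_rng(child) for name, child in zip(STREAM_NAMES, children)}
        )

    def __getitem__(self, name: str) -> np.random.Generator:
        return self._streams[name]


class ScriptedStream:
    """Generator-like object replaying a fixed script of draws.

    Used by tests to freeze every stochastic element of a step.  Exhausting the
    script raises instead of wrapping around, so a change in the number or
    order of draws consumed by the code under test fails loudly.
    """

    def __init__(self, uniforms: Sequence[float] = (), normals: Sequence[float] = ()):
        self._uniforms: List[float] = list(uniforms)
        self._normals: List[float] = list(normals)

    def _pop(self, pool: List[float], kind: str) -> float:
        if not pool:
            raise RuntimeError(f"scripted {kind} stream exhausted")
        return pool.pop(0)

    def uniform(self, low: float = 0.0, high: float = 1.0) -> float:
        # Scripted values are on [0, 1]; rescale like Generator.uniform.
        return low + (high - low) * self._pop(self._uniforms, "uniform")

    def normal(self, loc: float = 0.0, scale: float = 1.0) -> float:
        return loc + scale * self._pop(self._normals, "normal")


class FixtureRNG:
    """A :class:`NoiseStreams` stand-in backed by scripted sequences."""

    def __init__(self, scripts: Dict[str, ScriptedStream]):
        self._streams = dict(scripts)

    @classmethod
    def constant(cls, uniform: float, n: int = 10_000, normal: float = 0.0) -> "FixtureRNG":
        """Every stream replays the same constant draw ``n`` times."""
        return cls(
            {
                name: ScriptedStream(uniforms=[uniform] * n, normals=[normal] * n)
                for name in STREAM_NAMES
            }
        )

    def __getitem__(self, name: str) -> ScriptedStream:
        if name not in self._streams:
            raise KeyError(f"no scripted stream for {name!r}")
        return self._streams[name]
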