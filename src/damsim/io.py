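"""Serialization: trajectories, manifests, reports.

A trajectory is written as CSV (one row per iteration, fixed column order,
UTF-8, '.' decimal) or JSON (config + records).  A run manifest captures
everything needed to re-execute the run bit-exactly: the full config snapshot
(which includes the seed) and the tool version.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import List, Union

import pandas as pd

from . import __version__
from .config import SimulationConfig
from .simulation import StepRecord, Trajectory, run

PathLike = Union[str, Path]

#: Documented CSV column schema (header row order).
TRAJECTORY_COLUMNS = tuple(StepRecord.__dataclass_fields__)


def write_trajectory(trajectory: Trajectory, path: PathLike, format: str = "csv") -> None:
    """Write a trajectory; ``read_trajectory`` round-trips it exactly."""
    if len(trajectory) == 0:
        raise ValueError("refusing to write an empty trajectory")
    path = Path(path)
    if format == "csv":
        df = trajectory.to_dataframe()[list(TRAJECTORY_COLUMNS)]
        # 17 significant digits round-trip IEEE doubles exactly
        df.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")
    elif format == "json":
        payload = {
            "config": trajectory.config.model_dump(mode="json"),
            "records": [asdict(r) for r in trajectory.records],
        }
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def read_trajectory(path: PathLike, config: SimulationConfig = None) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    CSV carries no config; pass the matching one (or accept a default-config
    placeholder useful only for record access).
    """
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        config = SimulationConfig.model_validate(payload["config"])
        records = [StepRecord(**r) for r in payload["records"]]
        return Trajectory(records=records, config=config)
    df = pd.read_csv(path, float_precision="round_trip")
    records: List[StepRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        d["iteration"] = int(d["iteration"])
        d["K"] = int(d["K"])
        d["N_ex"] = int(d["N_ex"])
        d["care_provided"] = bool(d["care_provided"])
        d["conflict_a"] = bool(d["conflict_a"])
        d["conflict_c"] = bool(d["conflict_c"])
        records.append(StepRecord(**d))
    return Trajectory(records=records, config=config or SimulationConfig())


def write_manifest(trajectory: Trajectory, path: PathLike, artifacts: dict = None) -> None:
    """Run manifest: config snapshot + seed + version, enough to re-execute."""
    payload = {
        "tool": "damsim",
        "version": __version__,
        "created_unix": time.time(),
        "seed": trajectory.config.seed,
        "n_iterations": trajectory.config.n_iterations,
        "config": trajectory.config.model_dump(mode="json"),
        "artifacts": artifacts or {},
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def run_from_manifest(path: PathLike) -> Trajectory:
    """Re-execute the run a manifest describes (bit-identical to the original)."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    config = SimulationConfig.model_validate(payload["config"])
    return run(config)
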