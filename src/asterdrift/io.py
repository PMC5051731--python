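"""Trajectory CSV and config/result JSON readers and writers.

The trajectory dialect is a plain CSV with header ``track_id,t_s,x_um,y_um``
(one row per sample, cell-centred Cartesian coordinates in um).  Captured
tracks simply end with their last point inside the chromatin radius.
Writes are deterministic: rows ordered by (track_id, t), numbers formatted
to 6 significant digits, so identical data gives byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .rwd import Trajectory

__all__ = ["read_trajectories", "write_trajectories", "RunManifest",
           "write_manifest", "TrajectoryParseError"]

HEADER = ["track_id", "t_s", "x_um", "y_um"]


class TrajectoryParseError(ValueError):
    pass


def read_trajectories(path, r_chr: Optional[float] = None) -> list[Trajectory]:
    """Parse the trajectory CSV; tracks grouped by id and sorted by time.

    Row order in the file is irrelevant.  Missing columns, non-numeric
    cells and duplicated (track_id, t) pairs are rejected with the
    offending row named.  When ``r_chr`` is given, a track whose final
    position lies inside the chromatin radius gets its capture time set to
    the final timestamp, and nucleation distances are filled in.
    """
    try:
        df = pd.read_csv(path, dtype={"track_id": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TrajectoryParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in HEADER if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: missing columns {missing}")
    for col in ("t_s", "x_um", "y_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 2   # 1-based, plus header line
            raise TrajectoryParseError(f"{path}: non-numeric {col} at line {row}")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0]) + 2
            raise TrajectoryParseError(f"{path}: empty {col} at line {row}")
        df[col] = vals
    dup = df.duplicated(subset=["track_id", "t_s"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise TrajectoryParseError(f"{path}: duplicated (track_id, t) at line {row}")

    trajs = []
    for tid, g in df.sort_values(["track_id", "t_s"]).groupby("track_id", sort=True):
        times = g["t_s"].to_numpy()
        pos = g[["x_um", "y_um"]].to_numpy()
        t_c = None
        d_n = None
        if r_chr is not None:
            if np.hypot(*pos[-1]) <= r_chr:
                t_c = float(times[-1])
            d_n = float(np.hypot(*pos[0]) - r_chr)
        trajs.append(Trajectory(track_id=str(tid), times=times, positions=pos,
                                d_n=d_n, t_c=t_c))
    return trajs


def write_trajectories(trajs: Iterable[Trajectory], path) -> None:
    """Write the trajectory CSV with deterministic order and formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in sorted(trajs, key=lambda t: t.track_id):
        for t, (x, y) in zip(tr.times, tr.positions):
            rows.append((tr.track_id, t, x, y))
    with open(path, "w") as fh:
        fh.write(",".join(HEADER) + "\n")
        for tid, t, x, y in rows:
            fh.write(f"{tid},{t:.6g},{x:.6g},{y:.6g}\n")


class RunManifest:
    """Provenance record emitted once per CLI run.

    Captures the command, a digest of the resolved configuration, the
    seed, artifact version and output paths, so a run can be reproduced
    bit-identically for its deterministic stages.
    """

    def __init__(self, command: str, config: dict, seed: int,
                 outputs: list[str]):
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        self.record = {
            "command": command,
            "config_digest": hashlib.sha256(blob).hexdigest(),
            "config": config,
            "seed": seed,
            "artifact_version": _version(),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": outputs,
        }


def _version() -> str:
    try:
        from importlib.metadata import version
        return version("asterdrift")
    except Exception:
        return "unknown"


def write_manifest(manifest: RunManifest, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest.record, fh, indent=2, default=str)
        fh.write("\n")
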