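"""Readers/writers for the package's delimited-text formats.

All tables are comma-separated UTF-8 with documented headers and
deterministic row order; a missing ``parent_id`` is written as an empty
field and times are decimal hours.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .ensemble import EnsembleSummary
from .lineage import COLUMNS, LineageTable
from .model import LineageTrajectory
from .params import InvalidInputError, ModelParams
from .segment import NucleusDetection

__all__ = [
    "ParseError",
    "read_lineage_table",
    "write_lineage_table",
    "write_trajectory",
    "read_trajectory",
    "write_ensemble_summary",
    "write_detections",
    "write_run_config",
]


class ParseError(ValueError):
    """Raised when an input file violates the documented format."""


def read_lineage_table(path: str | Path) -> LineageTable:
    """Read and validate a lineage table CSV.

    Violations are reported with the offending column or (1-based, header
    included) line number.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"nucleus_id": str, "parent_id": str, "lineage_id": str})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    try:
        return LineageTable(frame)
    except InvalidInputError as exc:
        message = str(exc)
        # translate 0-based frame rows into file line numbers
        for token in message.split():
            cleaned = token.strip("[],:")
            if cleaned.isdigit():
                message = message.replace(token, token.replace(cleaned, str(int(cleaned) + 2)), 1)
                message += " (line number, counting the header as line 1)"
                break
        raise ParseError(f"{path}: {message}") from exc


def write_lineage_table(table: LineageTable, path: str | Path) -> None:
    frame = table.frame.sort_values(["time_h", "nucleus_id"], kind="stable")
    frame = frame.assign(parent_id=frame["parent_id"].fillna(""))
    frame.to_csv(path, index=False)


def write_trajectory(trajectory: LineageTrajectory, path: str | Path) -> None:
    """Long-format run table: time_h, lineage, outer, inner (lineage-major)."""
    n_times, n = trajectory.outer.shape
    frame = pd.DataFrame(
        {
            "time_h": np.tile(trajectory.times, n),
            "lineage": np.repeat(np.arange(1, n + 1), n_times),
            "outer": trajectory.outer.T.ravel(),
            "inner": trajectory.inner.T.ravel(),
        }
    )
    frame.to_csv(path, index=False)


def read_trajectory(path: str | Path, params: ModelParams | None = None, seed: int = -1) -> LineageTrajectory:
    frame = pd.read_csv(path)
    needed = {"time_h", "lineage", "outer", "inner"}
    if not needed.issubset(frame.columns):
        raise ParseError(f"{path}: missing column(s) {sorted(needed - set(frame.columns))}")
    times = np.sort(frame["time_h"].unique())
    lineages = np.sort(frame["lineage"].unique())
    outer = np.empty((times.size, lineages.size))
    inner = np.empty((times.size, lineages.size))
    for j, lin in enumerate(lineages):
        sub = frame[frame["lineage"] == lin].sort_values("time_h")
        outer[:, j] = sub["outer"].to_numpy()
        inner[:, j] = sub["inner"].to_numpy()
    return LineageTrajectory(times=times, outer=outer, inner=inner, seed=seed, params=params)


def write_ensemble_summary(summary: EnsembleSummary, path: str | Path) -> None:
    """Rank-then-time ordered summary table."""
    summary.to_frame().to_csv(path, index=False)


def write_detections(detections: Sequence[NucleusDetection], path: str | Path) -> None:
    """Detections ordered by label; header-only file when empty."""
    frame = pd.DataFrame(
        [
            {
                "label": d.label,
                "x_px": d.center[0],
                "y_px": d.center[1],
                "radius_px": d.radius,
                "area_px": d.area,
            }
            for d in sorted(detections, key=lambda d: d.label)
        ],
        columns=["label", "x_px", "y_px", "radius_px", "area_px"],
    )
    frame.to_csv(path, index=False)


def write_run_config(mapping: dict, path: str | Path) -> None:
    """Record the resolved configuration (and seeds) next to run outputs."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(mapping, fh, sort_keys=False)
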