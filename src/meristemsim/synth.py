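"""Synthetic lineage tables and nuclei image series with ground truth.

The generator runs a discrete-time branching process on the imaging grid:
every non-antheridium cell divides per frame interval with a layer-, phase-
and lineage-dependent probability.  Phase I is uniform across lineages;
in Phase II one designated lineage (the emergent dominant one) switches to a
high rate while the others decay linearly to mitotic inactivity.  Inner
cells divide at ``gamma`` times the outer rate; outer divisions are
anticlinal (both daughters outer) with probability ``p_anticlinal`` and
periclinal otherwise.  Every statistic of interest is tracked by the
generator itself into a :class:`GroundTruth` ledger so analysis code can be
checked against it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lineage import DivisionEvent, LineageTable
from .params import InvalidInputError

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_lineage_table",
    "generate_nuclei_series",
    "render_frame",
]

#: Hours over which non-dominant Phase II division rates decay linearly to 0.
DEFAULT_PHASE2_DECAY_H = 24.0


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the branching-process generator.

    Rates are per hour; the per-frame division probability is
    ``rate * interval`` and must not exceed 1.
    """

    n_founders: int = 5
    phase1_end: float = 54.0
    rate_outer_phase1: float = 0.02
    rate_outer_phase2_mpc: float = 0.06
    rate_outer_phase2_other: float = 0.01
    gamma: float = 0.5
    p_anticlinal: float = 0.5
    interval: float = 6.0
    t_end: float = 120.0
    n_antheridia: int = 3
    antheridium_drop_time: float = 78.0
    mpc_index: int = 0
    phase2_decay_h: float = DEFAULT_PHASE2_DECAY_H  # inf = no decay
    frame_shape: tuple[int, int] = (256, 256)
    founder_spacing: float = 36.0
    position_jitter: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 1:
            raise InvalidInputError("n_founders must be >= 1")
        if not (0 <= self.p_anticlinal <= 1):
            raise InvalidInputError("p_anticlinal must lie in [0, 1]")
        if not (0 < self.gamma <= 1):
            raise InvalidInputError("gamma must lie in (0, 1]")
        if self.interval <= 0 or self.t_end <= self.phase1_end:
            raise InvalidInputError("need interval > 0 and t_end > phase1_end")
        for name in ("rate_outer_phase1", "rate_outer_phase2_mpc", "rate_outer_phase2_other"):
            rate = getattr(self, name)
            if rate < 0 or rate * self.interval > 1:
                raise InvalidInputError(
                    f"{name} * interval must be a probability in [0, 1]"
                )
        if not (0 <= self.mpc_index < self.n_founders):
            raise InvalidInputError("mpc_index out of range")


@dataclass
class GroundTruth:
    """Generator-side ledger of everything the analysis should recover."""

    events: list[DivisionEvent]
    counts: pd.DataFrame  # lineage x time, non-antheridium cells
    mpc_lineage: str
    progeny_totals: pd.Series  # root nucleus -> divisions in the 60 h window
    progeny_window: tuple[float, float]
    root_layers: pd.Series  # root nucleus -> layer at window start
    divided_per_window: pd.Series  # window start -> number of division events


@dataclass
class _Cell:
    nucleus_id: str
    lineage_id: str
    layer: str
    x: float
    y: float
    is_antheridium: bool = False
    root: str | None = None
    parent_id: str | None = None  # set only on the frame a cell is born


def _outer_rate(config: SynthConfig, lineage_idx: int, window_start: float) -> float:
    if window_start < config.phase1_end:
        return config.rate_outer_phase1
    if lineage_idx == config.mpc_index:
        return config.rate_outer_phase2_mpc
    if not np.isfinite(config.phase2_decay_h):
        return config.rate_outer_phase2_other
    decay = 1.0 - (window_start - config.phase1_end) / config.phase2_decay_h
    return config.rate_outer_phase2_other * max(decay, 0.0)


def generate_lineage_table(config: SynthConfig) -> tuple[LineageTable, GroundTruth]:
    """Run the branching process and emit the table plus its ledger.

    Fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    height, width = config.frame_shape
    times = np.arange(0.0, config.t_end + config.interval / 2, config.interval)
    lineages = [f"L{i + 1}" for i in range(config.n_founders)]
    mpc_lineage = lineages[config.mpc_index]

    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"n{counter:05d}"

    def jitter(x: float, y: float) -> tuple[float, float]:
        dx, dy = rng.normal(0.0, config.position_jitter, size=2)
        margin = 8.0
        return (
            float(np.clip(x + dx, margin, width - margin)),
            float(np.clip(y + dy, margin, height - margin)),
        )

    cells: list[_Cell] = []
    x0 = (width - (config.n_founders - 1) * config.founder_spacing) / 2.0
    for i, lid in enumerate(lineages):
        cells.append(
            _Cell(new_id(), lid, "outer", x0 + i * config.founder_spacing, height * 0.35)
        )
    for j in range(config.n_antheridia):
        cells.append(
            _Cell(
                new_id(),
                f"A{j + 1}",
                "outer",
                x0 + j * config.founder_spacing * 0.5,
                height * 0.75,
                is_antheridium=True,
            )
        )

    records: list[dict] = []
    events: list[DivisionEvent] = []
    counts = {lid: {} for lid in lineages}
    divided_per_window: dict[float, int] = {}

    window = (config.phase1_end, min(config.phase1_end + 60.0, config.t_end))
    progeny_totals: dict[str, int] = {}
    root_layers: dict[str, str] = {}

    for frame_idx, t in enumerate(times):
        if frame_idx > 0:
            window_start = times[frame_idx - 1]
            divided_per_window[float(window_start)] = 0
            next_cells: list[_Cell] = []
            for cell in cells:
                if cell.is_antheridium:
                    cell.parent_id = None
                    next_cells.append(cell)
                    continue
                lineage_idx = lineages.index(cell.lineage_id)
                rate = _outer_rate(config, lineage_idx, window_start)
                if cell.layer == "inner":
                    rate *= config.gamma
                p_div = min(rate * config.interval, 1.0)
                if rng.random() < p_div:
                    if cell.layer == "outer":
                        anticlinal = rng.random() < config.p_anticlinal
                        layers = ("outer", "outer") if anticlinal else ("outer", "inner")
                        orientation = "anticlinal" if anticlinal else "periclinal"
                    else:
                        layers = ("inner", "inner")
                        orientation = "inner"
                    daughters = []
                    for layer in layers:
                        dx, dy = jitter(cell.x, cell.y)
                        if layer == "inner" and cell.layer == "outer":
                            dy = min(dy + 10.0, height - 8.0)  # pushed inward
                        daughters.append(
                            _Cell(
                                new_id(),
                                cell.lineage_id,
                                layer,
                                dx,
                                dy,
                                root=cell.root,
                                parent_id=cell.nucleus_id,
                            )
                        )
                    events.append(
                        DivisionEvent(
                            parent_id=cell.nucleus_id,
                            daughter_ids=tuple(sorted(d.nucleus_id for d in daughters)),
                            t_start=float(window_start),
                            t_end=float(t),
                            orientation=orientation,
                            lineage_id=cell.lineage_id,
                        )
                    )
                    divided_per_window[float(window_start)] += 1
                    if cell.root is not None and window[0] < t <= window[1]:
                        progeny_totals[cell.root] += 1
                    next_cells.extend(daughters)
                else:
                    cell.parent_id = None
                    x, y = jitter(cell.x, cell.y)
                    cell.x, cell.y = x, y
                    next_cells.append(cell)
            cells = next_cells
            # antheridia "mature" and drop out of the table
            if t >= config.antheridium_drop_time:
                cells = [c for c in cells if not c.is_antheridium]

        if abs(t - window[0]) < 1e-9:
            for cell in cells:
                if not cell.is_antheridium:
                    cell.root = cell.nucleus_id
                    progeny_totals[cell.nucleus_id] = 0
                    root_layers[cell.nucleus_id] = cell.layer

        for lid in lineages:
            counts[lid][float(t)] = sum(
                1 for c in cells if c.lineage_id == lid and not c.is_antheridium
            )
        for cell in cells:
            records.append(
                {
                    "nucleus_id": cell.nucleus_id,
                    "time_h": float(t),
                    "x_px": round(cell.x, 2),
                    "y_px": round(cell.y, 2),
                    "lineage_id": cell.lineage_id,
                    "layer": cell.layer,
                    "is_antheridium": cell.is_antheridium,
                    "parent_id": cell.parent_id,
                }
            )

    table = LineageTable(pd.DataFrame(records))
    counts_frame = pd.DataFrame(counts).T
    counts_frame = counts_frame.reindex(index=sorted(lineages))
    counts_frame.index.name = "lineage_id"
    counts_frame.columns.name = "time_h"
    truth = GroundTruth(
        events=events,
        counts=counts_frame,
        mpc_lineage=mpc_lineage,
        progeny_totals=pd.Series(progeny_totals, name="division_events").sort_index(),
        progeny_window=window,
        root_layers=pd.Series(root_layers, name="layer").sort_index(),
        divided_per_window=pd.Series(divided_per_window).sort_index(),
    )
    return table, truth


def render_frame(
    centers,
    shape: tuple[int, int],
    spot_sigma: float = 2.5,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render Gaussian spots (value ``amplitude`` at the center) plus
    additive Gaussian background noise."""
    height, width = shape
    frame = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0:height, 0:width]
    for x, y in centers:
        if not (0 <= x < width and 0 <= y < height):
            raise InvalidInputError(f"spot center ({x}, {y}) out of bounds for {shape}")
        frame += amplitude * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * spot_sigma**2)
        )
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        frame = frame + rng.normal(0.0, noise_sd, size=shape)
    return frame


def generate_nuclei_series(
    table: LineageTable,
    spot_sigma: float = 2.5,
    noise_sd: float = 0.02,
    shape: tuple[int, int] | None = None,
    amplitude: float = 1.0,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[list[tuple[float, float]]]]:
    """One rendered frame per table time point plus ground-truth centers."""
    if shape is None:
        margin = 8
        shape = (
            int(np.ceil(table.frame["y_px"].max())) + margin,
            int(np.ceil(table.frame["x_px"].max())) + margin,
        )
    rng = np.random.default_rng(seed)
    frames, centers_per_frame = [], []
    for t in table.time_points:
        sub = table.records_at(t, include_antheridia=True)
        centers = list(zip(sub["x_px"].astype(float), sub["y_px"].astype(float)))
        frames.append(
            render_frame(centers, shape, spot_sigma, amplitude, noise_sd, rng)
        )
        centers_per_frame.append(centers)
    return frames, centers_per_frame
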