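"""Quantitative analytics on per-nucleus lineage-tracking tables.

A lineage table holds one record per nucleus per imaging time point with its
lineage membership, layer (outer/marginal vs inner) and, on the first frame
after a division, a link to the parent nucleus.  Divisions are taken from
these curated parent links, never inferred from positions.  Records flagged
as antheridium cells are excluded from every division statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import InvalidInputError

__all__ = [
    "COLUMNS",
    "LAYERS",
    "DegenerateTestError",
    "DivisionEvent",
    "LineageTable",
    "WelchResult",
    "division_events",
    "cells_per_lineage",
    "divisions_per_window",
    "progeny_division_totals",
    "progeny_cell_count",
    "compare_layer_divisions",
    "orientation_summary",
]

COLUMNS = [
    "nucleus_id",
    "time_h",
    "x_px",
    "y_px",
    "lineage_id",
    "layer",
    "is_antheridium",
    "parent_id",
]
LAYERS = ("outer", "inner")


class DegenerateTestError(ValueError):
    """Raised when a statistical test is undefined for the given data."""


@dataclass(frozen=True)
class DivisionEvent:
    """One division: the parent disappears, two daughters appear at t_end.

    The event is localized to the window ``(t_start, t_end]`` whose length is
    the table's imaging interval.  Orientation is classified from the
    daughters' layers: both outer -> anticlinal, one outer + one inner ->
    periclinal, both inner -> "inner" (excluded from the marginal-orientation
    statistics).
    """

    parent_id: str
    daughter_ids: tuple[str, str]
    t_start: float
    t_end: float
    orientation: str
    lineage_id: str


@dataclass(frozen=True)
class WelchResult:
    mean_outer: float
    mean_inner: float
    t: float
    df: float
    p: float


class LineageTable:
    """Validated per-nucleus, per-time tracking table."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = _validate(frame)
        self.time_points = np.sort(self.frame["time_h"].unique())
        if len(self.time_points) >= 2:
            steps = np.diff(self.time_points)
            if not np.allclose(steps, steps[0]):
                raise InvalidInputError("time points are not evenly spaced")
            self.interval = float(steps[0])
        else:
            self.interval = float("nan")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def lineage_ids(self) -> list[str]:
        return sorted(self.frame["lineage_id"].unique())

    def records_at(self, time_h: float, include_antheridia: bool = False) -> pd.DataFrame:
        sub = self.frame[self.frame["time_h"] == time_h]
        if not include_antheridia:
            sub = sub[~sub["is_antheridium"]]
        return sub


def _validate(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise InvalidInputError(f"lineage table missing column(s): {missing}")
    frame = frame[COLUMNS].copy()
    frame["nucleus_id"] = frame["nucleus_id"].astype(str)
    frame["lineage_id"] = frame["lineage_id"].astype(str)
    frame["time_h"] = frame["time_h"].astype(float)
    frame["is_antheridium"] = frame["is_antheridium"].astype(bool)
    bad_layer = ~frame["layer"].isin(LAYERS)
    if bad_layer.any():
        rows = frame.index[bad_layer].tolist()[:5]
        raise InvalidInputError(f"invalid layer value(s) at rows {rows}")
    dup = frame.duplicated(subset=["nucleus_id", "time_h"])
    if dup.any():
        rows = frame.index[dup].tolist()[:5]
        raise InvalidInputError(f"duplicate (nucleus_id, time_h) at rows {rows}")

    # parent links must point at a nucleus present in the preceding frame
    times = np.sort(frame["time_h"].unique())
    present: dict[float, set[str]] = {
        t: set(frame.loc[frame["time_h"] == t, "nucleus_id"]) for t in times
    }
    prev_of = {t: times[i - 1] for i, t in enumerate(times) if i > 0}
    has_parent = frame["parent_id"].notna() & (frame["parent_id"] != "")
    for row in frame.index[has_parent]:
        t = frame.at[row, "time_h"]
        parent = str(frame.at[row, "parent_id"])
        if t not in prev_of or parent not in present[prev_of[t]]:
            raise InvalidInputError(
                f"row {row}: parent_id {parent!r} absent at the preceding frame"
            )
    frame.loc[~has_parent, "parent_id"] = None
    frame.loc[has_parent, "parent_id"] = frame.loc[has_parent, "parent_id"].astype(str)
    return frame.reset_index(drop=True)


def division_events(table: LineageTable) -> list[DivisionEvent]:
    """All division events implied by the table's parent links.

    Antheridium-flagged daughters are excluded.  Every dividing parent must
    have exactly two daughters.
    """
    events: list[DivisionEvent] = []
    frame = table.frame
    linked = frame[frame["parent_id"].notna() & ~frame["is_antheridium"]]
    for (t, parent), group in linked.groupby(["time_h", "parent_id"], sort=True):
        if len(group) != 2:
            raise InvalidInputError(
                f"parent {parent!r} at t={t} h has {len(group)} daughters, expected 2"
            )
        layers = sorted(group["layer"])
        if layers == ["outer", "outer"]:
            orientation = "anticlinal"
        elif layers == ["inner", "outer"]:
            orientation = "periclinal"
        else:
            orientation = "inner"
        daughters = tuple(sorted(group["nucleus_id"]))
        events.append(
            DivisionEvent(
                parent_id=str(parent),
                daughter_ids=daughters,  # type: ignore[arg-type]
                t_start=float(t) - table.interval,
                t_end=float(t),
                orientation=orientation,
                lineage_id=str(group["lineage_id"].iloc[0]),
            )
        )
    return events


def cells_per_lineage(
    table: LineageTable, lineage_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Non-antheridium cell count per lineage per time point.

    Returns a (lineage x time) DataFrame; rows ordered by lineage id,
    columns by time.
    """
    sub_all = table.frame[~table.frame["is_antheridium"]]
    if lineage_ids is None:
        lineage_ids = sorted(sub_all["lineage_id"].unique())
    unknown = set(lineage_ids) - set(table.lineage_ids)
    if unknown:
        raise InvalidInputError(f"unknown lineage id(s): {sorted(unknown)}")
    sub = table.frame[~table.frame["is_antheridium"]]
    counts = (
        sub[sub["lineage_id"].isin(lineage_ids)]
        .groupby(["lineage_id", "time_h"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=sorted(lineage_ids), columns=table.time_points, fill_value=0)
    )
    counts.index.name = "lineage_id"
    counts.columns.name = "time_h"
    return counts


def _windows(table: LineageTable, window_h: float) -> list[tuple[float, float]]:
    if table.interval != table.interval:  # single frame, NaN interval
        raise InvalidInputError("table has fewer than two time points")
    ratio = window_h / table.interval
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise InvalidInputError(
            f"window ({window_h} h) must be a positive multiple of the "
            f"imaging interval ({table.interval} h)"
        )
    t0, t1 = table.time_points[0], table.time_points[-1]
    starts = np.arange(t0, t1, window_h)
    return [(float(s), float(min(s + window_h, t1))) for s in starts]


def divisions_per_window(table: LineageTable, window_h: float = 12.0) -> pd.DataFrame:
    """Divided/undivided label for every non-antheridium nucleus per window.

    A nucleus is labeled for a window if it is present at any frame in
    ``[start, end)`` and "divided" iff a division event with it as parent
    falls in ``(start, end]``.  Returns a long DataFrame with columns
    (window_start, window_end, nucleus_id, divided).
    """
    events = division_events(table)
    divided_at = {(e.parent_id, e.t_end) for e in events}
    frame = table.frame[~table.frame["is_antheridium"]]
    rows = []
    for start, end in _windows(table, window_h):
        live = frame[(frame["time_h"] >= start) & (frame["time_h"] < end)]
        event_times = {
            p: t for (p, t) in divided_at if start < t <= end
        }
        for nucleus in sorted(live["nucleus_id"].unique()):
            rows.append(
                {
                    "window_start": start,
                    "window_end": end,
                    "nucleus_id": nucleus,
                    "divided": nucleus in event_times,
                }
            )
    return pd.DataFrame(rows, columns=["window_start", "window_end", "nucleus_id", "divided"])


def _children_map(events: Iterable[DivisionEvent]) -> dict[str, list[DivisionEvent]]:
    children: dict[str, list[DivisionEvent]] = {}
    for event in events:
        children.setdefault(event.parent_id, []).append(event)
    return children


def _subtree_ids(root: str, children: dict[str, list[DivisionEvent]]) -> set[str]:
    seen = {root}
    stack = [root]
    while stack:
        node = stack.pop()
        for event in children.get(node, []):
            for d in event.daughter_ids:
                if d not in seen:
                    seen.add(d)
                    stack.append(d)
    return seen


def progeny_division_totals(
    table: LineageTable,
    start_t: float,
    duration: float = 60.0,
    roots: Sequence[str] | None = None,
) -> pd.Series:
    """Division events of each root and all its descendants in
    ``(start_t, start_t + duration]``.

    Roots default to every non-antheridium nucleus present at ``start_t``.
    An event is attributed to a root when its parent belongs to the root's
    subtree (the root itself or any descendant).
    """
    present = set(table.records_at(start_t)["nucleus_id"])
    if not present:
        raise InvalidInputError(f"no non-antheridium nuclei at t={start_t} h")
    if roots is None:
        roots = sorted(present)
    else:
        missing = set(roots) - present
        if missing:
            raise InvalidInputError(
                f"root(s) absent at t={start_t} h: {sorted(missing)}"
            )
    events = division_events(table)
    children = _children_map(events)
    in_window = [e for e in events if start_t < e.t_end <= start_t + duration]
    totals = {}
    for root in roots:
        subtree = _subtree_ids(root, children)
        totals[root] = sum(1 for e in in_window if e.parent_id in subtree)
    return pd.Series(totals, name="division_events").sort_index()


def progeny_cell_count(table: LineageTable, root: str, at_time: float) -> int:
    """Number of descendants of ``root`` (including itself if still present)
    alive at ``at_time``, excluding antheridium records."""
    events = division_events(table)
    subtree = _subtree_ids(root, _children_map(events))
    alive = table.records_at(at_time)
    return int(alive["nucleus_id"].isin(subtree).sum())


def compare_layer_divisions(outer_totals, inner_totals) -> WelchResult:
    """Welch's unequal-variance two-sample t-test (two-tailed).

    ``t`` carries the sign of mean(outer) - mean(inner); degrees of freedom
    follow Welch-Satterthwaite.
    """
    a = np.asarray(outer_totals, dtype=float)
    b = np.asarray(inner_totals, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each group needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(float(a.mean()), float(b.mean()), 0.0, float("nan"), 1.0)
        raise DegenerateTestError("both group variances are zero")
    sa, sb = va / a.size, vb / b.size
    se = math.sqrt(sa + sb)
    t_stat = (a.mean() - b.mean()) / se
    df = (sa + sb) ** 2 / (
        (sa**2 / (a.size - 1) if a.size > 1 else 0.0)
        + (sb**2 / (b.size - 1) if b.size > 1 else 0.0)
    )
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    return WelchResult(float(a.mean()), float(b.mean()), float(t_stat), float(df), float(p))


def orientation_summary(
    table: LineageTable, lineage_ids: Sequence[str] | None = None
) -> tuple[int, int, float]:
    """Anticlinal vs periclinal division counts in the outermost layer and
    the exact two-sided binomial p-value against equal frequencies.

    Inner-layer divisions (both daughters inner) are excluded.
    """
    events = division_events(table)
    if lineage_ids is not None:
        events = [e for e in events if e.lineage_id in set(lineage_ids)]
    n_anti = sum(1 for e in events if e.orientation == "anticlinal")
    n_peri = sum(1 for e in events if e.orientation == "periclinal")
    n = n_anti + n_peri
    if n == 0:
        raise DegenerateTestError("no classifiable outer-layer division events")
    p = stats.binomtest(n_anti, n, 0.5, alternative="two-sided").pvalue
    return n_anti, n_peri, float(p)
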