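"""Reading, writing, and preprocessing of plate-reader OD tables.

Two delimited-text layouts are supported:

* **wide** — one time column plus one column per sample::

      time,ctrl,phageA
      0,0.1,0.1
      0.25,0.12,0.11

* **long** — one row per (time, sample, od) triple::

      time,sample,od
      0,ctrl,0.1
      0,phageA,0.1

The delimiter (comma or tab) is autodetected unless forced.  Times are
converted to hours on read; the input unit is declared by the caller
(minutes are common for 15-min plate reads).  Times are used as given in
the file — the tool never re-zeroes them silently, because the centroid's
time coordinate depends on the origin; pass ``rezero_time=True`` to
subtract each curve's first time point.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import GRID_TOL, GrowthCurve, PlateExperiment, require_same_grid
from .errors import AlignmentError, FormatError, ParseError

log = logging.getLogger(__name__)

WIDE_DEFAULT_MAP = {"time": "time"}
LONG_DEFAULT_MAP = {"time": "time", "sample": "sample", "od": "od"}

_UNIT_TO_HOURS = {"h": 1.0, "hours": 1.0, "hr": 1.0, "min": 1.0 / 60.0, "minutes": 1.0 / 60.0}


def _read_table(path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        # autodetect comma vs tab from the header line
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") > header.count(",") else ","
    try:
        # round_trip parsing keeps write/read cycles bit-exact
        return pd.read_csv(path, sep=sep, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed delimited text
        raise FormatError(f"{path}: could not read delimited table: {exc}") from exc


def _to_numeric(frame: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    out = frame.copy()
    for col in columns:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"{path}: non-numeric value {out[col][row]!r} in column {col!r} "
                f"at data row {row}"
            )
        out[col] = coerced
    return out


def read_plate_table(
    path,
    layout: str = "wide",
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
    time_unit: str = "h",
    rezero_time: bool = False,
    control_ids: list[str] | None = None,
    replicate_groups: dict[str, list[str]] | None = None,
    on_missing: str = "error",
) -> PlateExperiment:
    """Parse a delimited OD table into a :class:`PlateExperiment`.

    ``column_map`` names the special columns: for ``layout="wide"`` only
    ``{"time": <col>}`` (every other column is a sample), for
    ``layout="long"`` all of ``{"time", "sample", "od"}``.  ``time_unit``
    is ``"h"`` or ``"min"``; times are stored in hours.  ``on_missing``
    governs empty OD cells: ``"error"`` rejects them, ``"drop"`` removes
    them per sample (grids may then differ and need alignment).
    """
    if layout not in ("wide", "long"):
        raise FormatError(f"unknown layout {layout!r}; use 'wide' or 'long'")
    if time_unit not in _UNIT_TO_HOURS:
        raise FormatError(f"unknown time unit {time_unit!r}; use 'h' or 'min'")
    if on_missing not in ("error", "drop"):
        raise FormatError(f"on_missing must be 'error' or 'drop', got {on_missing!r}")
    scale = _UNIT_TO_HOURS[time_unit]
    frame = _read_table(path, sep)
    frame.columns = [str(c).strip() for c in frame.columns]

    if layout == "wide":
        cmap = {**WIDE_DEFAULT_MAP, **(column_map or {})}
        tcol = cmap["time"]
        if tcol not in frame.columns:
            raise FormatError(f"{path}: time column {tcol!r} not found")
        sample_cols = [c for c in frame.columns if c != tcol]
        if not sample_cols:
            raise FormatError(f"{path}: no sample columns besides {tcol!r}")
        frame = _to_numeric(frame, [tcol] + sample_cols, path)
        frame = frame.sort_values(tcol, kind="stable").reset_index(drop=True)
        times = frame[tcol].to_numpy() * scale
        dup = frame[tcol].duplicated()
        if dup.any():
            raise ParseError(
                f"{path}: duplicated time {frame[tcol][dup.idxmax()]!r} "
                f"at data row {int(dup.idxmax())}"
            )
        curves = {}
        for col in sample_cols:
            ods = frame[col].to_numpy()
            miss = ~np.isfinite(ods)
            t = times
            if miss.any():
                if on_missing == "error":
                    raise ParseError(
                        f"{path}: missing OD for sample {col!r} at data row "
                        f"{int(np.argmax(miss))}"
                    )
                t, ods = times[~miss], ods[~miss]
                log.warning("sample %s: dropped %d missing OD cells", col, int(miss.sum()))
            if t.size < 2:
                raise ParseError(f"{path}: sample {col!r} has fewer than 2 time points")
            curves[col] = GrowthCurve(col, _maybe_rezero(t, rezero_time), ods)
    else:
        cmap = {**LONG_DEFAULT_MAP, **(column_map or {})}
        missing = [cmap[k] for k in ("time", "sample", "od") if cmap[k] not in frame.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing!r}")
        tcol, scol, ocol = cmap["time"], cmap["sample"], cmap["od"]
        frame = _to_numeric(frame, [tcol, ocol], path)
        curves = {}
        for sid, group in frame.groupby(scol, sort=False):
            group = group.sort_values(tcol, kind="stable")
            dup = group[tcol].duplicated()
            if dup.any():
                raise ParseError(
                    f"{path}: duplicated (sample, time) = "
                    f"({sid!r}, {group[tcol][dup.idxmax()]!r})"
                )
            t = group[tcol].to_numpy() * scale
            ods = group[ocol].to_numpy()
            miss = ~np.isfinite(ods)
            if miss.any():
                if on_missing == "error":
                    raise ParseError(f"{path}: missing OD for sample {sid!r}")
                t, ods = t[~miss], ods[~miss]
            if t.size < 2:
                raise ParseError(f"{path}: sample {sid!r} has fewer than 2 time points")
            curves[str(sid)] = GrowthCurve(str(sid), _maybe_rezero(t, rezero_time), ods)

    return PlateExperiment(
        curves=curves,
        control_ids=list(control_ids or []),
        replicate_groups=dict(replicate_groups or {}),
    )


def _maybe_rezero(times: np.ndarray, rezero: bool) -> np.ndarray:
    return times - times[0] if rezero else times


def write_plate_table(experiment: PlateExperiment, path, layout: str = "long") -> None:
    """Write a :class:`PlateExperiment` back to delimited text.

    The wide layout requires all curves to share one time grid; the long
    layout is fully general.  Values are written with full float precision
    so a write/read cycle round-trips exactly.
    """
    path = Path(path)
    curves = list(experiment.curves.values())
    if layout == "wide":
        first = curves[0]
        for other in curves[1:]:
            require_same_grid(first, other)
        data = {"time": first.times}
        for c in curves:
            data[c.sample_id] = c.ods
        # %.17g round-trips any float64 exactly
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    elif layout == "long":
        rows = [
            (c.sample_id, t, od)
            for c in curves
            for t, od in zip(c.times, c.ods)
        ]
        pd.DataFrame(rows, columns=["sample", "time", "od"])[
            ["time", "sample", "od"]
        ].to_csv(path, index=False, float_format="%.17g")
    else:
        raise FormatError(f"unknown layout {layout!r}")


def subtract_blank(curve: GrowthCurve, blank, floor: float = 0.0) -> GrowthCurve:
    """Subtract a blank (scalar OD or a blank-well curve) pointwise.

    The result is clamped at ``floor`` so downstream areas stay
    nonnegative.  A blank curve must share the sample grid.
    """
    if isinstance(blank, GrowthCurve):
        require_same_grid(curve, blank)
        reduced = curve.ods - blank.ods
    else:
        reduced = curve.ods - float(blank)
    return clamp_nonnegative(curve.with_ods(reduced), floor=floor)


def clamp_nonnegative(curve: GrowthCurve, floor: float = 0.0) -> GrowthCurve:
    """Replace every OD below ``floor`` (default 0) by ``floor``.

    Keeps grids intact (no point dropping) and logs how many points were
    clamped.  Idempotent.
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    below = curve.ods < floor
    if not below.any():
        return curve
    log.info("sample %s: clamped %d OD points to %g", curve.sample_id, int(below.sum()), floor)
    return curve.with_ods(np.where(below, floor, curve.ods))


def align_time_grids(
    a: GrowthCurve, b: GrowthCurve, mode: str = "strict"
) -> tuple[GrowthCurve, GrowthCurve]:
    """Bring two curves onto a common time grid.

    ``strict`` errors unless the grids already agree within 1e-9 h.
    ``interpolate`` restricts both curves to the overlap of their time
    ranges and linearly interpolates each onto the union of time points
    inside it (plus the overlap endpoints).  Piecewise-linear curves are
    unchanged as geometric objects by this resampling, so their centroids
    and areas are preserved.
    """
    if mode == "strict":
        require_same_grid(a, b)
        return a, b
    if mode != "interpolate":
        raise ValueError(f"unknown mode {mode!r}")
    lo = max(a.times[0], b.times[0])
    hi = min(a.times[-1], b.times[-1])
    if not lo < hi:
        raise AlignmentError(
            f"curves {a.sample_id!r} and {b.sample_id!r} have no overlapping time range"
        )
    union = np.union1d(a.times, b.times)
    grid = union[(union >= lo - GRID_TOL) & (union <= hi + GRID_TOL)]
    # ensure exact overlap endpoints are present
    if abs(grid[0] - lo) > GRID_TOL:
        grid = np.insert(grid, 0, lo)
    if abs(grid[-1] - hi) > GRID_TOL:
        grid = np.append(grid, hi)
    if grid.size < 2:
        raise AlignmentError(
            f"overlap of {a.sample_id!r} and {b.sample_id!r} contains fewer than 2 points"
        )
    return (
        GrowthCurve(a.sample_id, grid.copy(), np.interp(grid, a.times, a.ods)),
        GrowthCurve(b.sample_id, grid.copy(), np.interp(grid, b.times, b.ods)),
    )


def aggregate_replicates(
    curves: list[GrowthCurve], method: str = "mean", label: str | None = None
) -> GrowthCurve:
    """Pointwise mean or median of replicate curves sharing one grid."""
    if not curves:
        raise ValueError("need at least one curve")
    first = curves[0]
    for other in curves[1:]:
        require_same_grid(first, other)
    stack = np.vstack([c.ods for c in curves])
    if method == "mean":
        ods = stack.mean(axis=0)
    elif method == "median":
        ods = np.median(stack, axis=0)
    else:
        raise ValueError(f"unknown method {method!r}")
    name = label or "+".join(c.sample_id for c in curves)
    return GrowthCurve(name, first.times.copy(), ods)
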