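"""Comparison metrics: Virulence Index (area ratio), maximum specific
growth rate, and ranking of treatments under any metric.

The Virulence Index here is the per-curve area-ratio form,
``VI = 1 - AUC(treated)/AUC(control)``, the quantity tabulated per
condition when phage treatments are benchmarked against an uninfected
control.  It reacts only to total OD mass, not to where in time that mass
sits — which is exactly what the Centroid Index adds.

``mu_max`` estimates the maximum specific growth rate as the steepest
sliding-window least-squares slope of ln(OD) versus time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import GrowthCurve, require_same_grid
from .errors import DegenerateControlError, NotEstimableError

#: Metric values closer than this are reported as tied.  Matches a
#: two-decimal reporting convention for index values.
TIE_TOL = 5e-3

#: Metrics where a larger value means a more efficient phage.
HIGHER_IS_BETTER = {"CI", "VI"}


@dataclass(frozen=True)
class VIResult:
    """Virulence Index of one treated curve against one control curve."""

    vi: float
    treated_area: float
    control_area: float
    treated_id: str
    control_id: str


@dataclass(frozen=True)
class MuMaxResult:
    """Maximum specific growth rate and the time window that attains it."""

    rate: float          # per hour
    window_start: float  # hours
    window_end: float    # hours


def area_under_curve(curve: GrowthCurve) -> float:
    """Trapezoid-rule integral of OD over time (OD*hours).

    Accumulated with exact (fsum) summation of the per-strip areas so the
    value is identical to the strip-area sum used by the centroid and is
    invariant under reordering of equal strips.
    """
    y0, y1 = curve.ods[:-1], curve.ods[1:]
    dx = np.diff(curve.times)
    return math.fsum(0.5 * (y0 + y1) * dx)


def virulence_index(treated: GrowthCurve, control: GrowthCurve) -> VIResult:
    """``VI = 1 - AUC(treated) / AUC(control)`` on a shared time grid."""
    require_same_grid(treated, control)
    a_ctrl = area_under_curve(control)
    if a_ctrl <= 0.0:
        raise DegenerateControlError(
            f"control {control.sample_id!r} has zero area; VI undefined"
        )
    a_trt = area_under_curve(treated)
    return VIResult(1.0 - a_trt / a_ctrl, a_trt, a_ctrl, treated.sample_id, control.sample_id)


def mu_max(curve: GrowthCurve, window: int = 5, od_floor: float = 0.01) -> MuMaxResult:
    """Maximum specific growth rate (per hour) of a curve.

    Slides a ``window``-point least-squares fit of ln(OD) against time over
    every stretch where all ODs exceed ``od_floor`` and returns the largest
    slope together with the winning window's time span.  A flat curve
    yields rate 0.  Raises :class:`NotEstimableError` when no window of
    ``window`` consecutive points sits entirely above the floor.
    """
    if window < 2:
        raise ValueError("window must be >= 2 points")
    if od_floor <= 0.0:
        raise ValueError("od_floor must be > 0 (ln of OD is taken)")
    t = curve.times
    ok = curve.ods > od_floor
    best: MuMaxResult | None = None
    for i in range(len(curve) - window + 1):
        if not ok[i : i + window].all():
            continue
        tw = t[i : i + window]
        lw = np.log(curve.ods[i : i + window])
        slope = float(np.polyfit(tw, lw, 1)[0])
        if best is None or slope > best.rate:
            best = MuMaxResult(slope, float(tw[0]), float(tw[-1]))
    if best is None:
        raise NotEstimableError(
            f"{curve.sample_id}: no {window} consecutive points above OD {od_floor}"
        )
    return best


@dataclass(frozen=True)
class RankRow:
    label: str
    metric: str
    value: float
    rank: int
    tied: bool


@dataclass
class RankingTable:
    """Treatments ordered from most to least efficient under one metric."""

    rows: list[RankRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.label, r.metric, r.value, r.rank, r.tied) for r in self.rows],
            columns=["condition", "metric", "value", "rank", "tied"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def order(self) -> list[str]:
        return [r.label for r in self.rows]


def rank_treatments(
    results: list[tuple[str, float]],
    metric: str = "CI",
    tie_tol: float = TIE_TOL,
) -> RankingTable:
    """Rank condition labels by a metric value.

    CI and VI rank descending (higher = more efficient phage); mu_max ranks
    ascending (stronger suppression = lower growth rate).  Values within
    ``tie_tol`` of the best value of their group share a (competition) rank
    and are flagged as ties.
    """
    if not results:
        raise ValueError("results must be nonempty")
    descending = metric in HIGHER_IS_BETTER
    ordered = sorted(results, key=lambda lv: lv[1], reverse=descending)
    rows: list[RankRow] = []
    groups: list[list[tuple[str, float]]] = []
    for label, value in ordered:
        if groups and abs(value - groups[-1][0][1]) <= tie_tol:
            groups[-1].append((label, value))
        else:
            groups.append([(label, value)])
    rank = 1
    for group in groups:
        tied = len(group) > 1
        for label, value in group:
            rows.append(RankRow(label, metric, value, rank, tied))
        rank += len(group)
    return RankingTable(rows)
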