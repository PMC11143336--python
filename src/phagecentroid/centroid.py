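"""Centroid of a growth curve and the Centroid Index (CI).

The region between a nonnegative OD trace and the time axis is decomposed
into one trapezoidal strip per sampling interval.  With sample points
``(x_j, y_j)``, j = 0..n, strip j (over ``[x_{j-1}, x_j]``) has area

    A_j = (y_{j-1} + y_j) / 2 * (x_j - x_{j-1})

and centroid

    xbar_j = x_{j-1} + (x_j - x_{j-1}) (y_{j-1} + 2 y_j) / (3 (y_{j-1} + y_j))
    ybar_j = (1/3) (y_j + y_{j-1}^2 / (y_{j-1} + y_j))

The curve centroid is the area-weighted mean of strip centroids,

    xbar = sum_j xbar_j A_j / A ,   ybar = sum_j ybar_j A_j / A ,  A = sum_j A_j,

which is exact for the piecewise-linear interpolant of the samples.  The
Centroid Index of a phage-treated curve i against the uninfected control is

    CI_i = 1 - (xbar_i ybar_i) / (xbar_ctrl ybar_ctrl).

CI = 0 means no effect (treated curve identical to the control), CI = 1
means complete suppression (zero treated area, taken as the continuous
limit), and CI < 0 means the treated culture carried more OD mass, or
carried it later in time, than the control — an inefficient phage.

``centroid_oracle_dense`` evaluates the same centroid by brute-force
midpoint integration of the first moments of area on a refined grid; it is
deliberately independent of the strip decomposition and serves as the test
oracle for :func:`curve_centroid`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .curves import GrowthCurve, require_same_grid
from .errors import DegenerateControlError, DegenerateStripError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Centroid:
    """Centroid coordinates and total area of a curve's region.

    ``x_bar`` is in hours, ``y_bar`` in OD units, ``area`` in OD*hours.
    A zero-area region has no defined centroid: ``area == 0`` and both
    coordinates are NaN; check :attr:`defined`.
    """

    x_bar: float
    y_bar: float
    area: float

    @property
    def defined(self) -> bool:
        return self.area > 0.0

    @property
    def product(self) -> float:
        """The coordinate product x_bar * y_bar used by the Centroid Index."""
        return self.x_bar * self.y_bar


UNDEFINED_CENTROID = Centroid(float("nan"), float("nan"), 0.0)


@dataclass(frozen=True)
class CIResult:
    """Centroid Index of one treated curve against one control curve."""

    ci: float
    treated_centroid: Centroid
    control_centroid: Centroid
    treated_id: str
    control_id: str


def _check_strip(x_prev: float, x: float, y_prev: float, y: float) -> None:
    if not x > x_prev:
        raise ValueError(f"strip needs x > x_prev, got [{x_prev}, {x}]")
    if y_prev < 0 or y < 0:
        raise ValueError(f"strip needs nonnegative ODs, got ({y_prev}, {y})")


def strip_area(x_prev: float, x: float, y_prev: float, y: float) -> float:
    """Trapezoid area of one strip: ``(y_prev + y)/2 * (x - x_prev)``."""
    _check_strip(x_prev, x, y_prev, y)
    return 0.5 * (y_prev + y) * (x - x_prev)


def strip_centroid(x_prev: float, x: float, y_prev: float, y: float) -> tuple[float, float]:
    """Centroid ``(xbar_j, ybar_j)`` of one trapezoidal strip.

    Raises :class:`DegenerateStripError` when both heights vanish — such a
    strip has zero area and no centroid; callers drop it from the weighted
    sums (its weight would be zero anyway).
    """
    _check_strip(x_prev, x, y_prev, y)
    s = y_prev + y
    if s == 0.0:
        raise DegenerateStripError(
            f"strip [{x_prev}, {x}] has zero height at both ends"
        )
    x_bar = x_prev + (x - x_prev) * (y_prev + 2.0 * y) / (3.0 * s)
    y_bar = (y + y_prev * y_prev / s) / 3.0
    return x_bar, y_bar


def curve_centroid(curve: GrowthCurve) -> Centroid:
    """Area-weighted centroid of the region under a nonnegative curve.

    Degenerate (zero-area) strips contribute nothing; if the whole curve
    has zero area the result is the undefined centroid (area 0, NaN
    coordinates).
    """
    t = curve.times
    y = curve.ods
    if np.any(y < 0):
        raise ValueError(f"{curve.sample_id}: negative OD values; clamp first")
    y0, y1 = y[:-1], y[1:]
    dx = np.diff(t)
    s = y0 + y1
    areas = 0.5 * s * dx
    live = s > 0.0
    area = math.fsum(areas[live])
    if area == 0.0:
        log.info("curve %s has zero area; centroid undefined", curve.sample_id)
        return UNDEFINED_CENTROID
    n_dead = int(np.count_nonzero(~live))
    if n_dead:
        log.debug("curve %s: %d zero-area strips skipped", curve.sample_id, n_dead)
    t0, dxl, y0l, y1l, sl, al = t[:-1][live], dx[live], y0[live], y1[live], s[live], areas[live]
    xbar_j = t0 + dxl * (y0l + 2.0 * y1l) / (3.0 * sl)
    ybar_j = (y1l + y0l * y0l / sl) / 3.0
    x_bar = float(np.dot(xbar_j, al) / area)
    y_bar = float(np.dot(ybar_j, al) / area)
    return Centroid(x_bar, y_bar, area)


def centroid_index(treated: GrowthCurve, control: GrowthCurve) -> CIResult:
    """Centroid Index of ``treated`` against ``control`` on a shared grid.

    A treated curve with zero total area scores exactly 1 (complete
    suppression, the continuous limit of the index).  Negative values are
    returned unmodified.  A control whose area or centroid coordinate
    product is zero makes the index undefined and raises
    :class:`DegenerateControlError`.
    """
    require_same_grid(treated, control)
    c_ctrl = curve_centroid(control)
    if not c_ctrl.defined or not c_ctrl.product > 0.0:
        raise DegenerateControlError(
            f"control {control.sample_id!r} has zero area or zero centroid "
            "coordinate product; CI undefined"
        )
    c_trt = curve_centroid(treated)
    if not c_trt.defined:
        log.info(
            "treated %s has zero area: complete suppression, CI = 1",
            treated.sample_id,
        )
        ci = 1.0
    else:
        ci = 1.0 - c_trt.product / c_ctrl.product
    return CIResult(ci, c_trt, c_ctrl, treated.sample_id, control.sample_id)


def centroid_oracle_dense(curve: GrowthCurve, refinement: int = 1000) -> Centroid:
    """Brute-force centroid of the piecewise-linear interpolant of ``curve``.

    Each sampling interval is split into ``refinement`` sub-intervals and
    the area A and first moments Q_y = integral of x dA and
    Q_x = integral of y dA are accumulated by the midpoint rule:

        A   ~ sum  y(x_m) h
        Q_y ~ sum  x_m y(x_m) h
        Q_x ~ sum  y(x_m)^2 / 2 h

    with x_m the midpoint of each sub-interval of width h.  The centroid is
    (Q_y/A, Q_x/A).  Error shrinks as O(refinement^-2).  This routine is an
    independent oracle for :func:`curve_centroid` and is intentionally not
    built on the strip formulas.
    """
    if refinement < 2:
        raise ValueError("refinement must be >= 2")
    t = curve.times
    y = curve.ods
    if np.any(y < 0):
        raise ValueError(f"{curve.sample_id}: negative OD values; clamp first")
    # fractional midpoints of each sub-interval, shared across intervals
    frac = (np.arange(refinement) + 0.5) / refinement
    t0, t1 = t[:-1, None], t[1:, None]
    y0, y1 = y[:-1, None], y[1:, None]
    xm = t0 + frac[None, :] * (t1 - t0)
    ym = y0 + frac[None, :] * (y1 - y0)
    h = (t1 - t0) / refinement
    area = float(np.sum(ym * h))
    if area <= 0.0:
        return UNDEFINED_CENTROID
    q_y = float(np.sum(xm * ym * h))
    q_x = float(np.sum(0.5 * ym * ym * h))
    return Centroid(q_y / area, q_x / area, area)
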