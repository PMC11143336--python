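"""Seeded generators for the growth-curve shapes the metrics must handle.

The generators emulate a 96 h microplate assay read every 15 min (385 time
points, inoculation at OD 0.1): a logistic uninfected control, phage-driven
lysis with optional late bacterial regrowth, exact area-matched curve
pairs whose OD mass sits at different times (the shapes that make an
area-ratio index blind), and curve pairs that share an exponential segment
(identical maximum specific growth rate) but diverge later.  Regrowth is
modelled phenomenologically as piecewise logistic/exponential sections —
the tool scores curves, it does not simulate phage population kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import GrowthCurve

#: Default assay grid: 0 to 96 h sampled every 15 minutes (385 points).
DEFAULT_END_H = 96.0
DEFAULT_STEP_MIN = 15.0
DEFAULT_N0 = 0.1


def default_time_grid(end_h: float = DEFAULT_END_H, step_min: float = DEFAULT_STEP_MIN) -> np.ndarray:
    """Uniform grid from 0 to ``end_h`` hours in ``step_min``-minute steps."""
    n = int(round(end_h * 60.0 / step_min))
    return np.linspace(0.0, end_h, n + 1)


@dataclass(frozen=True)
class LogisticParams:
    """Canonical logistic growth: initial OD ``n0``, carrying capacity ``k``
    (OD units), growth rate ``r`` (per hour)."""

    n0: float = DEFAULT_N0
    k: float = 1.0
    r: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.n0 <= self.k:
            raise ValueError(f"need 0 < n0 <= k, got n0={self.n0}, k={self.k}")
        if self.r <= 0.0:
            raise ValueError(f"growth rate must be > 0, got {self.r}")

    def od(self, t: np.ndarray) -> np.ndarray:
        # n0*k / (n0 + (k-n0) e^{-rt}) form: exact n0 at t=0, exact k when n0=k
        return self.n0 * self.k / (self.n0 + (self.k - self.n0) * np.exp(-self.r * t))


@dataclass(frozen=True)
class LysisRegrowthParams:
    """Lysis-then-regrowth shape.

    Logistic growth until ``t_lysis`` (h), then exponential decay toward 0
    at rate ``decay`` (per hour); from ``t_regrow`` the culture climbs
    logistically toward ``regrow_frac * k`` at ``regrow_rate`` (per hour).
    ``regrow_frac = 0`` gives pure lysis with no comeback.  The curve is
    continuous at both junctions and bounded by [0, k].
    """

    growth: LogisticParams = LogisticParams()
    t_lysis: float = 8.0
    decay: float = 0.5
    regrow_frac: float = 0.0
    t_regrow: float = 48.0
    regrow_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.t_lysis < 0.0 or self.t_regrow <= self.t_lysis:
            raise ValueError("need t_regrow > t_lysis >= 0")
        if self.decay <= 0.0 or self.regrow_rate <= 0.0:
            raise ValueError("decay and regrow_rate must be > 0")
        if not 0.0 <= self.regrow_frac <= 1.0:
            raise ValueError("regrow_frac must be in [0, 1]")


def logistic_curve(p: LogisticParams, times: np.ndarray, sample_id: str = "logistic") -> GrowthCurve:
    """Sample a logistic growth curve on ``times``."""
    return GrowthCurve(sample_id, np.asarray(times, dtype=float), p.od(np.asarray(times, dtype=float)))


def lysis_regrowth_curve(
    p: LysisRegrowthParams, times: np.ndarray, sample_id: str = "lysis"
) -> GrowthCurve:
    """Sample a continuous lysis(-then-regrowth) curve on ``times``."""
    t = np.asarray(times, dtype=float)
    y = p.growth.od(t)
    y_lysis = float(p.growth.od(np.array([p.t_lysis]))[0])
    in_decay = t > p.t_lysis
    y = np.where(in_decay, y_lysis * np.exp(-p.decay * (t - p.t_lysis)), y)
    target = p.regrow_frac * p.growth.k
    y_at_regrow = y_lysis * np.exp(-p.decay * (p.t_regrow - p.t_lysis))
    if target > y_at_regrow:
        # seed the regrowth from a tiny positive inoculum if decay underflowed
        y0 = max(y_at_regrow, 1e-12 * p.growth.k)
        rising = (
            target * y0 / (y0 + (target - y0) * np.exp(-p.regrow_rate * (t - p.t_regrow)))
        )
        y = np.where(t > p.t_regrow, rising, y)
    # else: target at or below the decay level -> keep decaying (monotone)
    return GrowthCurve(sample_id, t, np.clip(y, 0.0, p.growth.k))


def area_matched_pair(base: GrowthCurve) -> tuple[GrowthCurve, GrowthCurve]:
    """Return ``base`` and its time-reflection about the grid midpoint.

    Both members have identical trapezoid area under the curve (the strip
    areas of the reflection are the same multiset), but the reflection
    carries its OD mass at mirrored times — the pair an area-ratio index
    cannot tell apart while a centroid-based index can.  On a uniform grid
    the reflection lives on the very same time grid.
    """
    t = base.times
    dx = np.diff(t)
    if np.all(np.abs(dx - dx[0]) <= 1e-9):
        t_ref = t.copy()
    else:
        t_ref = t[0] + t[-1] - t[::-1]
    return base, GrowthCurve(base.sample_id + "_reflected", t_ref, base.ods[::-1].copy())


def add_noise(curve: GrowthCurve, sigma: float, seed: int) -> GrowthCurve:
    """Add zero-mean Gaussian measurement noise of SD ``sigma`` (OD units),
    clamped at 0.  Identical seed -> identical output; ``sigma = 0`` is the
    identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0:
        return curve
    rng = np.random.default_rng(seed)
    noisy = curve.ods + rng.normal(0.0, sigma, size=len(curve))
    return curve.with_ods(np.maximum(noisy, 0.0))


def mu_max_twin_pair(
    r: float,
    divergence_time: float,
    times: np.ndarray,
    n0: float = 0.05,
    rise_factor: float = 5.0,
) -> tuple[GrowthCurve, GrowthCurve]:
    """Two curves sharing an identical exponential segment, diverging later.

    Both grow as ``n0 * exp(r t)`` until ``divergence_time``; afterwards
    one plateaus at the divergence value while the other keeps rising at
    half the log-slope until ``rise_factor`` times that value.  Whenever a
    full fitting window fits inside the shared segment, the maximum
    specific growth rate of the two members is identical to machine
    precision (the shared points are bit-identical) while their centroids
    differ.  A ``divergence_time`` beyond the grid end yields two identical
    curves.
    """
    if r <= 0:
        raise ValueError("rate must be > 0")
    t = np.asarray(times, dtype=float)
    shared = n0 * np.exp(r * t)
    y_div = n0 * np.exp(r * divergence_time)
    flat = np.minimum(shared, y_div)
    slow = np.where(
        t <= divergence_time,
        shared,
        np.minimum(y_div * np.exp(0.5 * r * (t - divergence_time)), rise_factor * y_div),
    )
    return GrowthCurve("twin_plateau", t, flat), GrowthCurve("twin_rising", t, slow)


def random_piecewise_curve(
    times: np.ndarray,
    rng: np.random.Generator,
    n_knots: int = 8,
    od_max: float = 1.2,
    sample_id: str = "random",
) -> GrowthCurve:
    """Random nonnegative piecewise-linear curve on ``times``.

    Draws ``n_knots`` uniform OD values at random interior knots and
    linearly interpolates onto the grid — a generic stress shape for the
    centroid and area machinery (no biological meaning claimed).
    """
    t = np.asarray(times, dtype=float)
    if n_knots < 2:
        raise ValueError("need at least 2 knots")
    kt = np.sort(rng.uniform(t[0], t[-1], size=n_knots))
    kt[0], kt[-1] = t[0], t[-1]
    ky = rng.uniform(0.0, od_max, size=n_knots)
    return GrowthCurve(sample_id, t, np.interp(t, kt, ky))
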