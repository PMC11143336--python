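"""Core containers: a single OD time series and a plate of labelled series.

A :class:`GrowthCurve` is one well's optical-density trace on a strictly
increasing time grid (hours).  A :class:`PlateExperiment` bundles the curves
of one microplate run together with the designation of uninfected-control
wells and optional replicate groupings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AlignmentError, ParseError

#: Two time grids are considered identical if every point agrees within
#: this absolute tolerance (hours); 1e-9 h is well below any plate-reader
#: sampling resolution.
GRID_TOL = 1e-9


@dataclass(frozen=True)
class GrowthCurve:
    """One sample's OD time series.

    Parameters
    ----------
    sample_id:
        Well or condition label.
    times:
        Strictly increasing time points in hours, length >= 2.
    ods:
        Optical-density readings (dimensionless absorbance), same length
        as ``times``.  Raw readings may be negative before blank
        subtraction/clamping; the centroid and area routines require
        nonnegative values.
    """

    sample_id: str
    times: np.ndarray
    ods: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        ods = np.asarray(self.ods, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ods", ods)
        if times.ndim != 1 or ods.ndim != 1:
            raise ParseError(f"{self.sample_id}: times and ods must be 1-D")
        if times.size != ods.size:
            raise ParseError(
                f"{self.sample_id}: {times.size} time points but {ods.size} OD values"
            )
        if times.size < 2:
            raise ParseError(
                f"{self.sample_id}: need at least 2 time points, got {times.size}"
            )
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(ods)):
            raise ParseError(f"{self.sample_id}: non-finite time or OD value")
        if np.any(np.diff(times) <= 0):
            j = int(np.argmax(np.diff(times) <= 0))
            raise ParseError(
                f"{self.sample_id}: times not strictly increasing at index {j + 1} "
                f"(t={times[j + 1]!r} follows t={times[j]!r})"
            )

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_intervals(self) -> int:
        """Number of time intervals (strips) between consecutive samples."""
        return len(self) - 1

    def with_ods(self, ods: np.ndarray, sample_id: str | None = None) -> "GrowthCurve":
        """Return a copy with replaced OD values (and optionally a new label)."""
        return GrowthCurve(sample_id or self.sample_id, self.times.copy(), np.asarray(ods, dtype=float))

    def same_grid(self, other: "GrowthCurve", tol: float = GRID_TOL) -> bool:
        """True if both curves sample the same time points within ``tol`` hours."""
        return len(self) == len(other) and bool(
            np.all(np.abs(self.times - other.times) <= tol)
        )


def require_same_grid(a: GrowthCurve, b: GrowthCurve, tol: float = GRID_TOL) -> None:
    """Raise :class:`AlignmentError` unless ``a`` and ``b`` share a time grid."""
    if not a.same_grid(b, tol):
        raise AlignmentError(
            f"curves {a.sample_id!r} and {b.sample_id!r} are not on the same "
            f"time grid (lengths {len(a)} vs {len(b)})"
        )


@dataclass
class PlateExperiment:
    """A collection of labelled growth curves from one plate run.

    ``control_ids`` name the uninfected-control samples.  ``replicate_groups``
    optionally map a condition label to the sample ids of its biological
    replicates.  All referenced ids must exist in ``curves``.
    """

    curves: dict[str, GrowthCurve]
    control_ids: list[str] = field(default_factory=list)
    replicate_groups: dict[str, list[str]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid in self.control_ids:
            if cid not in self.curves:
                raise ParseError(f"control id {cid!r} not among samples")
        for cond, members in self.replicate_groups.items():
            for sid in members:
                if sid not in self.curves:
                    raise ParseError(
                        f"replicate member {sid!r} of condition {cond!r} not among samples"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.curves)

    def __getitem__(self, sample_id: str) -> GrowthCurve:
        return self.curves[sample_id]

    def treated_ids(self) -> list[str]:
        """Sample ids that are not controls."""
        return [s for s in self.curves if s not in self.control_ids]

    def condition_of(self, sample_id: str) -> str:
        """Condition label of a sample (its replicate group, else itself)."""
        for cond, members in self.replicate_groups.items():
            if sample_id in members:
                return cond
        return sample_id


def _replace(curve: GrowthCurve, **kw) -> GrowthCurve:  # pragma: no cover - thin alias
    return replace(curve, **kw)
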