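"""Quantification of visual fields.

Two kinds of field measurements flow through this module:

* a :class:`Meridian` — the azimuth-indexed boundary curve separating the
  visible from the lid-occluded superior field, as produced by the
  bisection engine; its headline quantity is the area under the meridian
  (AUM, deg²) by the trapezoidal rule, normalized to a percent of the
  testable frame; and
* a :class:`VisualFieldGrid` — a static-perimetry sensitivity grid (dB)
  whose grayscale visibility semantics (threshold luminance below
  10 apostilbs ⇔ sensitivity above 30 dB) let a deterministic tracer
  extract the same boundary curve from grid data.

Also here: the percent-improvement statistic that drives surgical
eligibility, anatomic severity grading from MRD1, and the IQR outlier rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .geometry import (
    DEFAULT_GEOMETRY,
    GRID_FRAME,
    FieldGeometry,
    GridPoint,
    make_grid_pattern,
)

__all__ = [
    "Meridian",
    "VisualFieldGrid",
    "aum_trapezoid",
    "percent_visible",
    "percent_improvement",
    "classify_severity",
    "db_to_asb",
    "asb_to_db",
    "trace_grid_meridian",
    "percent_degrees_visible",
    "iqr_outlier_filter",
    "SEVERE",
    "MILD",
    "NORMAL",
    "DEFAULT_CUTOFF_ASB",
]

SEVERE = "severe"
MILD = "mild"
NORMAL = "normal"

#: Grayscale visibility cutoff: threshold luminance below 10 asb (= stimulus
#: attenuation above 30 dB) counts as seen.
DEFAULT_CUTOFF_ASB = 10.0

#: Half of the 6° grid cell, credited above the highest seen grid row.
_HALF_CELL_DEG = 3.0


@dataclass(frozen=True)
class Meridian:
    """Boundary curve of the visible superior field.

    ``samples`` are (azimuth_deg, elevation_deg) pairs with strictly
    increasing azimuths; elevations are clamped to the physical frame by
    whoever constructs them.
    """

    samples: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        s = tuple((float(a), float(e)) for a, e in self.samples)
        if any(b[0] <= a[0] for a, b in zip(s, s[1:])):
            raise ValueError("meridian azimuths must be strictly increasing")
        if any(e < 0 for _, e in s):
            raise ValueError("meridian elevations must be non-negative")
        object.__setattr__(self, "samples", s)

    @classmethod
    def from_dict(cls, mapping: dict) -> "Meridian":
        return cls(tuple(sorted(mapping.items())))

    @property
    def azimuths_deg(self) -> np.ndarray:
        return np.array([a for a, _ in self.samples])

    @property
    def elevations_deg(self) -> np.ndarray:
        return np.array([e for _, e in self.samples])

    def mirrored(self) -> "Meridian":
        """Reflection about the vertical midline (x → −x)."""
        return Meridian(tuple((-a, e) for a, e in reversed(self.samples)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=["azimuth_deg", "elevation_deg"])


@dataclass
class VisualFieldGrid:
    """Central-field sensitivity grid with grayscale visibility semantics."""

    points: List[GridPoint]
    eye_id: str = ""
    condition: str = "untaped"   # untaped | taped
    device: str = "hvfa_sim"     # hvfa_sim | mcht_sim

    def __post_init__(self) -> None:
        pattern = {(p.azimuth_deg, p.elevation_deg) for p in make_grid_pattern()}
        seen: set[Tuple[float, float]] = set()
        for p in self.points:
            loc = (p.azimuth_deg, p.elevation_deg)
            if loc not in pattern:
                raise ValueError(f"grid point {loc} is not on the test pattern")
            if loc in seen:
                raise ValueError(f"duplicate grid location {loc}")
            seen.add(loc)

    @property
    def superior_points(self) -> List[GridPoint]:
        return [p for p in self.points if p.elevation_deg > 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.azimuth_deg, p.elevation_deg, p.sensitivity_db) for p in self.points],
            columns=["azimuth_deg", "elevation_deg", "sensitivity_db"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **meta) -> "VisualFieldGrid":
        df = pd.read_csv(path)
        pts = [GridPoint(r.azimuth_deg, r.elevation_deg,
                         None if pd.isna(r.sensitivity_db) else float(r.sensitivity_db))
               for r in df.itertuples()]
        return cls(pts, **meta)


def aum_trapezoid(meridian: Meridian) -> float:
    """Area under the meridian (deg²) by the trapezoidal rule.

    No extrapolation beyond the first/last sampled azimuth.
    """
    if len(meridian.samples) < 2:
        raise ValueError("AUM requires at least 2 meridian samples")
    return float(np.trapezoid(meridian.elevations_deg, meridian.azimuths_deg))


def percent_visible(aum_deg2: float, geometry: FieldGeometry = DEFAULT_GEOMETRY) -> float:
    """AUM as a percent of the maximal testable superior area.

    The normalizing frame is the geometry's superior extent times the span
    of its column azimuths (first to last tested column).
    """
    if aum_deg2 < 0:
        raise ValueError("aum must be non-negative")
    span = geometry.column_azimuths_deg[-1] - geometry.column_azimuths_deg[0]
    if span <= 0 or geometry.elevation_max_deg <= 0:
        raise ValueError("degenerate zero-width geometry")
    return 100.0 * aum_deg2 / (geometry.elevation_max_deg * span)


def percent_improvement(aum_untaped: float, aum_taped: float) -> float:
    """Percent change in visible area from untaped to taped.

    A fully occluded baseline that opens at all under taping is reported as
    +inf (trivially past any eligibility threshold); two zero fields are 0%.
    """
    if aum_untaped < 0 or aum_taped < 0:
        raise ValueError("areas must be non-negative")
    if aum_untaped == 0:
        return float("inf") if aum_taped > 0 else 0.0
    return 100.0 * (aum_taped - aum_untaped) / aum_untaped


def classify_severity(mrd1_mm: float) -> str:
    """Anatomic ptosis grade from MRD1: <2 severe, 2–4 mild, ≥4 normal."""
    if mrd1_mm < 0:
        raise ValueError("MRD1 must be non-negative")
    if mrd1_mm < 2.0:
        return SEVERE
    if mrd1_mm < 4.0:
        return MILD
    return NORMAL


def db_to_asb(sensitivity_db: float) -> float:
    """Threshold luminance (apostilbs) of a sensitivity in dB attenuation.

    0 dB corresponds to the 10,000 asb maximal stimulus; each 10 dB is a
    tenfold attenuation, so higher dB ⇔ dimmer detectable stimulus.
    """
    if sensitivity_db < 0:
        raise ValueError("sensitivity_db must be non-negative")
    return 10000.0 * 10.0 ** (-sensitivity_db / 10.0)


def asb_to_db(asb: float) -> float:
    if asb <= 0:
        raise ValueError("luminance must be positive")
    return -10.0 * np.log10(asb / 10000.0)


def _column_extent(elevations: Sequence[float], visible: Sequence[bool],
                   full_extent: float) -> float:
    """Visible extent of one grid column.

    Contiguity from fixation: walk the available elevations upward from the
    lowest row while points stay visible; the extent is the highest
    contiguously seen elevation plus a half cell.  A column whose every
    available point is seen carries no evidence of occlusion and is
    credited the full frame extent.
    """
    if all(visible):
        return full_extent
    if not visible[0]:
        return 0.0
    top = elevations[0]
    for e, v in zip(elevations[1:], visible[1:]):
        if not v:
            break
        top = e
    return top + _HALF_CELL_DEG


def trace_grid_meridian(grid: VisualFieldGrid,
                        cutoff_asb: float = DEFAULT_CUTOFF_ASB) -> Meridian:
    """Deterministic tracer of the visible-field boundary on a grid.

    A point is seen iff its threshold luminance is below ``cutoff_asb``
    (sensitivity above ≈30 dB at the 10 asb default).  Each column's visible
    extent follows the contiguity-from-fixation rule of
    :func:`_column_extent`, so islands of vision above a gap (scotoma-like
    deviations) do not extend the boundary.
    """
    sup = grid.superior_points
    if not sup:
        raise ValueError("grid has no superior points to trace")
    samples = []
    for az in sorted({p.azimuth_deg for p in sup}):
        col = sorted((p for p in sup if p.azimuth_deg == az),
                     key=lambda p: p.elevation_deg)
        elevations = [p.elevation_deg for p in col]
        vis = [p.sensitivity_db is not None and db_to_asb(p.sensitivity_db) < cutoff_asb
               for p in col]
        samples.append((az, _column_extent(elevations, vis,
                                           GRID_FRAME.elevation_max_deg)))
    return Meridian(tuple(samples))


def percent_degrees_visible(field: Union[VisualFieldGrid, Meridian],
                            geometry: FieldGeometry = DEFAULT_GEOMETRY,
                            cutoff_asb: float = DEFAULT_CUTOFF_ASB) -> float:
    """Percent of the vertical midline (x = 0) that is visible.

    For grids: the test pattern has no x = 0 column, so the two columns
    adjacent to the midline (±3°) are traced and their extents averaged,
    normalized by the 30° frame.  For meridians from the hemifield exam:
    linear interpolation at x = 0, normalized by the exam's superior extent.
    """
    if isinstance(field, VisualFieldGrid):
        meridian = trace_grid_meridian(field, cutoff_asb)
        near = [(a, e) for a, e in meridian.samples if abs(a) <= 6.0]
        if not near:
            raise ValueError("no grid columns within 6 degrees of the midline")
        mean_extent = float(np.mean([e for _, e in near]))
        return 100.0 * mean_extent / GRID_FRAME.elevation_max_deg
    meridian = field
    az = meridian.azimuths_deg
    if len(az) == 0 or np.min(np.abs(az)) > 6.0:
        raise ValueError("no meridian samples within 6 degrees of the midline")
    at_zero = float(np.interp(0.0, az, meridian.elevations_deg))
    return 100.0 * at_zero / geometry.elevation_max_deg


def iqr_outlier_filter(values: Iterable[float], k: float = 1.5
                       ) -> Tuple[List[float], List[float]]:
    """Tukey fence outlier flagging.

    Quartiles use the linear-interpolation convention of
    ``numpy.percentile``.  Returns ``(kept, flagged)`` preserving input
    order; their union is the input.
    """
    vals = [float(v) for v in values]
    if len(vals) < 4:
        raise ValueError("IQR filtering requires at least 4 values")
    q1, q3 = np.percentile(vals, [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    kept = [v for v in vals if lo <= v <= hi]
    flagged = [v for v in vals if v < lo or v > hi]
    return kept, flagged
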