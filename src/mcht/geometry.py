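"""Coordinate frame of the superior hemifield and stimulus lattices.

Everything downstream works in degrees of visual angle with fixation at the
origin and superior elevations positive.  The bisection engine, however,
states its stop condition in *pixels* of the rendering display, so the frame
carries a single degrees-to-pixels scale through which every pixel-space
threshold is expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

__all__ = [
    "FieldGeometry",
    "GridPoint",
    "DEFAULT_GEOMETRY",
    "GRID_FRAME",
    "deg_to_px",
    "px_to_deg",
    "make_grid_pattern",
    "superior_subset",
]

#: Azimuths of the ±30° central-field lattice (6° spacing, offset 3°).
_GRID_COORDS = (-27.0, -21.0, -15.0, -9.0, -3.0, 3.0, 9.0, 15.0, 21.0, 27.0)

#: Eccentricity radius of the central-field test pattern, degrees.
GRID_MAX_ECC_DEG = 30.0


@dataclass(frozen=True)
class FieldGeometry:
    """Degree/pixel frame of the superior hemifield test.

    Parameters
    ----------
    azimuth_min_deg, azimuth_max_deg
        Horizontal extent of the tested hemifield.
    elevation_max_deg
        Superior extent above fixation.  Must be an integer multiple of
        ``row_spacing_deg`` so that stimulus rows land exactly on it.
    row_spacing_deg
        Vertical separation of the stimulus rows.
    column_azimuths_deg
        Azimuths of the tested columns, strictly increasing.
    pixels_per_degree
        Angular resolution of the display; all pixel-space thresholds
        scale through this single constant.
    stop_threshold_px
        Bisection stop condition: the search halts once consecutive
        pivots differ by no more than this many pixels.
    """

    azimuth_min_deg: float = -24.0
    azimuth_max_deg: float = 24.0
    elevation_min_deg: float = 0.0
    elevation_max_deg: float = 48.0
    row_spacing_deg: float = 12.0
    column_azimuths_deg: Tuple[float, ...] = (
        -24.0, -18.0, -12.0, -6.0, 0.0, 6.0, 12.0, 18.0, 24.0)
    pixels_per_degree: float = 15.0
    stop_threshold_px: int = 10

    def __post_init__(self) -> None:
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be positive")
        if self.stop_threshold_px < 1:
            raise ValueError("stop_threshold_px must be >= 1")
        if self.elevation_min_deg != 0.0:
            raise ValueError("elevation_min_deg is fixed at 0 (fixation)")
        if self.elevation_max_deg <= 0:
            raise ValueError("elevation_max_deg must be positive")
        n_rows = self.elevation_max_deg / self.row_spacing_deg
        if abs(n_rows - round(n_rows)) > 1e-9:
            raise ValueError(
                "elevation_max_deg must be an integer multiple of row_spacing_deg")
        cols = tuple(float(c) for c in self.column_azimuths_deg)
        if len(cols) < 1:
            raise ValueError("at least one column azimuth required")
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("column_azimuths_deg must be strictly increasing")
        if cols[0] < self.azimuth_min_deg or cols[-1] > self.azimuth_max_deg:
            raise ValueError("column azimuths outside the horizontal extent")
        object.__setattr__(self, "column_azimuths_deg", cols)

    @property
    def elevation_extent_px(self) -> int:
        """Superior extent in pixels (the bisection search interval)."""
        return deg_to_px(self.elevation_max_deg, self)

    @property
    def row_elevations_deg(self) -> Tuple[float, ...]:
        rows = int(round(self.elevation_max_deg / self.row_spacing_deg))
        return tuple(i * self.row_spacing_deg for i in range(rows + 1))

    def is_column(self, azimuth_deg: float) -> bool:
        return any(abs(azimuth_deg - c) < 1e-9 for c in self.column_azimuths_deg)


@dataclass(frozen=True)
class GridPoint:
    """A stimulus/grid location, optionally carrying a sensitivity in dB."""

    azimuth_deg: float
    elevation_deg: float
    sensitivity_db: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sensitivity_db is not None and not (0.0 <= self.sensitivity_db <= 50.0):
            raise ValueError("sensitivity_db must lie in [0, 50]")

    @property
    def eccentricity_deg(self) -> float:
        return math.hypot(self.azimuth_deg, self.elevation_deg)


DEFAULT_GEOMETRY = FieldGeometry()

#: Frame of the synthesized central-field (HVFA-like) grid: 30° superior
#: extent, columns at ±3..±27°.  Used to normalize grid-derived areas.
GRID_FRAME = FieldGeometry(
    azimuth_min_deg=-27.0,
    azimuth_max_deg=27.0,
    elevation_max_deg=30.0,
    row_spacing_deg=6.0,
    column_azimuths_deg=_GRID_COORDS,
)


def deg_to_px(deg: float, geometry: FieldGeometry = DEFAULT_GEOMETRY) -> int:
    """Map degrees of visual angle to (integer) display pixels."""
    return int(round(deg * geometry.pixels_per_degree))


def px_to_deg(px: float, geometry: FieldGeometry = DEFAULT_GEOMETRY) -> float:
    """Inverse of :func:`deg_to_px`; accepts fractional pixel positions."""
    return px / geometry.pixels_per_degree


def make_grid_pattern(pattern_name: str = "grid30_2_approx",
                      geometry: FieldGeometry = DEFAULT_GEOMETRY) -> list[GridPoint]:
    """Stimulus locations of the central-field grid pattern.

    ``grid30_2_approx`` is the 10×10 lattice at azimuth/elevation
    ±3, ±9, ±15, ±21, ±27° restricted to eccentricity ≤ 30°, yielding 80
    locations (40 superior).  This is a deliberate approximation of the
    clinical 76-point central 30° program, used only for synthetic grids.
    """
    if pattern_name != "grid30_2_approx":
        raise ValueError(f"unknown grid pattern: {pattern_name!r}")
    pts = [
        GridPoint(x, y)
        for x in _GRID_COORDS
        for y in _GRID_COORDS
        if math.hypot(x, y) <= GRID_MAX_ECC_DEG
    ]
    return pts


def superior_subset(points: Sequence[GridPoint]) -> list[GridPoint]:
    """Points strictly above fixation (the hemifield occluded by the lid)."""
    return [p for p in points if p.elevation_deg > 0]
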