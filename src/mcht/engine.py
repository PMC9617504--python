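"""Recursive median-cut boundary search over the superior hemifield.

The exam asks a single suprathreshold question per stimulus — seen or not
seen — and exploits the monotone structure of lid occlusion: everything
below the lid margin is visible, everything above it is not.  Each column
of the field is therefore a one-dimensional boundary-finding problem, and
the engine solves it by bisection in display-pixel space:

* running bounds start at the bottom (fixation) and top rows of the field;
* the first stimulus is presented at the middle of the column;
* a seen response raises the lower bound to the stimulus, a not-seen
  response lowers the upper bound, and the next stimulus is the midpoint
  of the surviving bracket;
* the search stops when consecutive pivots differ by at most
  ``stop_threshold_px`` pixels, which bounds the bracket width by twice
  the threshold and hence the boundary error by ``stop_threshold_px``
  pixels (0.67° at the default 15 px/°).

Because the bracket halves on every presentation, the per-column
presentation count is logarithmic in the field extent over the stop
threshold.  After the stop, one probe above and one below the estimated
boundary verify that the column is locally consistent (a persistent
mismatch — e.g. an island of vision above a blind gap — flags the column
as unreliable rather than silently distorting the meridian).
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Protocol, Tuple

import numpy as np

from . import field_metrics
from .geometry import DEFAULT_GEOMETRY, FieldGeometry, deg_to_px, px_to_deg

__all__ = [
    "Responder",
    "ColumnTrace",
    "VerificationResult",
    "ExamResult",
    "bisect_column",
    "verify_boundary",
    "run_hemifield_exam",
    "presentation_bound",
    "MAX_PRESENTATIONS_PER_COLUMN",
]

#: Guard against pathological stochastic responders; the noise-free search
#: needs at most ⌈log2(extent/threshold)⌉ + 2 presentations.
MAX_PRESENTATIONS_PER_COLUMN = 30


class Responder(Protocol):
    """Seen/not-seen oracle for a stimulus at (azimuth, elevation) degrees.

    May be stochastic; must not depend on exam history (the engine never
    passes any).
    """

    def respond(self, azimuth_deg: float, elevation_deg: float) -> bool: ...


class ResponderError(RuntimeError):
    """A responder raised while a column was being tested."""


@dataclass
class ColumnTrace:
    """Per-column bisection history and boundary estimate."""

    azimuth_deg: float
    presentations: List[Tuple[float, bool]] = field(default_factory=list)
    boundary_deg: float = 0.0
    verification_ok: bool = False
    retested: bool = False
    reliable: bool = True

    @property
    def n_presentations(self) -> int:
        return len(self.presentations)


@dataclass(frozen=True)
class VerificationResult:
    ok: bool
    retested: bool
    reliable: bool
    presentations: Tuple[Tuple[float, bool], ...] = ()


@dataclass
class ExamResult:
    """Complete hemifield exam: traces, meridian, area, accounting."""

    geometry: FieldGeometry
    column_traces: Dict[float, ColumnTrace]
    meridian: field_metrics.Meridian
    aum_deg2: float
    percent_visible: float
    total_presentations: int
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "aum_deg2": self.aum_deg2,
            "percent_visible": self.percent_visible,
            "total_presentations": self.total_presentations,
            "geometry": {
                "elevation_max_deg": self.geometry.elevation_max_deg,
                "pixels_per_degree": self.geometry.pixels_per_degree,
                "stop_threshold_px": self.geometry.stop_threshold_px,
                "column_azimuths_deg": list(self.geometry.column_azimuths_deg),
            },
            "meridian": [list(s) for s in self.meridian.samples],
            "columns": [
                {
                    "azimuth_deg": t.azimuth_deg,
                    "boundary_deg": t.boundary_deg,
                    "verification_ok": t.verification_ok,
                    "retested": t.retested,
                    "reliable": t.reliable,
                    "presentations": [[e, bool(s)] for e, s in t.presentations],
                }
                for t in self.column_traces.values()
            ],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_json_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_csv(self, path=None) -> str:
        """Flat per-column summary (azimuth, boundary, presentations, flags)."""
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["azimuth_deg", "boundary_deg", "n_presentations",
                    "verification_ok", "retested", "reliable"])
        for az in sorted(self.column_traces):
            t = self.column_traces[az]
            w.writerow([az, t.boundary_deg, t.n_presentations,
                        t.verification_ok, t.retested, t.reliable])
        text = buf.getvalue()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def presentation_bound(geometry: FieldGeometry) -> int:
    """Worst-case presentations per column for a noise-free responder."""
    extent = geometry.elevation_extent_px
    return int(np.ceil(np.log2(extent / geometry.stop_threshold_px))) + 2


def _respond(responder: Responder, azimuth_deg: float, elevation_deg: float,
             trace: ColumnTrace) -> bool:
    try:
        seen = bool(responder.respond(azimuth_deg, elevation_deg))
    except Exception as exc:  # annotate with column context, then propagate
        raise ResponderError(
            f"responder failed at column {azimuth_deg}°, "
            f"elevation {elevation_deg:.2f}°") from exc
    trace.presentations.append((elevation_deg, seen))
    return seen


def bisect_column(responder: Responder, azimuth_deg: float,
                  geometry: FieldGeometry = DEFAULT_GEOMETRY,
                  rng_seed: int = 0,
                  max_presentations: int = MAX_PRESENTATIONS_PER_COLUMN
                  ) -> ColumnTrace:
    """Locate the visibility boundary of one column by pixel-space bisection.

    The stop condition compares the *exact* midpoint of the surviving
    bracket against the last pivot, so the final bracket is at most
    ``2 × stop_threshold_px`` wide and the midpoint estimate is within
    ``stop_threshold_px`` pixels of a monotone responder's true boundary.

    If the search converged with one bound untouched (every response went
    the same way), the extreme row itself is presented once: a seen top
    row pins the boundary at the full extent, an unseen bottom row at 0.
    The search itself is deterministic (``rng_seed`` is accepted for
    interface symmetry with stochastic orchestration).
    """
    if not geometry.is_column(azimuth_deg):
        raise ValueError(f"{azimuth_deg}° is not a column of the geometry")
    trace = ColumnTrace(azimuth_deg=azimuth_deg)

    lower, upper = 0, geometry.elevation_extent_px
    lower_touched = upper_touched = False
    threshold = geometry.stop_threshold_px

    pivot = int(round((lower + upper) / 2))
    while True:
        seen = _respond(responder, azimuth_deg, px_to_deg(pivot, geometry), trace)
        if seen:
            lower, lower_touched = pivot, True
        else:
            upper, upper_touched = pivot, True
        nxt = (lower + upper) / 2.0
        if abs(nxt - pivot) <= threshold:
            break
        if trace.n_presentations >= max_presentations:
            break
        pivot = int(round(nxt))

    if not upper_touched and trace.n_presentations < max_presentations:
        # every stimulus was seen: test the top row itself
        if _respond(responder, azimuth_deg,
                    px_to_deg(upper, geometry), trace):
            trace.boundary_deg = geometry.elevation_max_deg
            return trace
        upper_touched = True
    if not lower_touched and trace.n_presentations < max_presentations:
        # nothing was seen: test the bottom row itself
        if not _respond(responder, azimuth_deg,
                        px_to_deg(lower, geometry), trace):
            trace.boundary_deg = 0.0
            return trace
        lower_touched = True

    trace.boundary_deg = px_to_deg((lower + upper) / 2.0, geometry)
    return trace


def verify_boundary(responder: Responder, azimuth_deg: float,
                    boundary_deg: float,
                    geometry: FieldGeometry = DEFAULT_GEOMETRY,
                    delta_deg: Optional[float] = None) -> VerificationResult:
    """Probe just above and just below a boundary estimate.

    The probe above the boundary should be unseen and the probe below seen.
    Probes are clamped into the field; a clamped probe that collapses onto
    the boundary itself (a boundary at 0 has no "below", one at the top
    row no "above") is uninformative and skipped.  A mismatched probe is
    retested once; a persistent mismatch flags the column unreliable (the
    boundary estimate is kept).
    """
    if not (0.0 <= boundary_deg <= geometry.elevation_max_deg):
        raise ValueError("boundary_deg outside the field")
    if delta_deg is None:
        delta_deg = 2.0 * geometry.stop_threshold_px / geometry.pixels_per_degree

    probes = (
        min(boundary_deg + delta_deg, geometry.elevation_max_deg),
        max(boundary_deg - delta_deg, 0.0),
    )
    log: List[Tuple[float, bool]] = []
    ok = True
    retested = False
    reliable = True
    for probe in probes:
        if probe == boundary_deg:
            continue
        expected = probe < boundary_deg
        trace = ColumnTrace(azimuth_deg=azimuth_deg)
        seen = _respond(responder, azimuth_deg, probe, trace)
        log.extend(trace.presentations)
        if seen != expected:
            ok = False
            retested = True
            trace2 = ColumnTrace(azimuth_deg=azimuth_deg)
            seen2 = _respond(responder, azimuth_deg, probe, trace2)
            log.extend(trace2.presentations)
            if seen2 != expected:
                reliable = False
    return VerificationResult(ok=ok, retested=retested, reliable=reliable,
                              presentations=tuple(log))


def run_hemifield_exam(responder: Responder,
                       geometry: FieldGeometry = DEFAULT_GEOMETRY,
                       rng_seed: int = 0,
                       verify: bool = True) -> ExamResult:
    """Bisect and verify every column, in seeded random order.

    With a fixed seed and a deterministic responder the result — including
    the full presentation log — is bit-identical across runs.
    """
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(geometry.column_azimuths_deg))
    traces: Dict[float, ColumnTrace] = {}
    for idx in order:
        az = geometry.column_azimuths_deg[idx]
        trace = bisect_column(responder, az, geometry)
        if verify:
            ver = verify_boundary(responder, az, trace.boundary_deg, geometry)
            trace.verification_ok = ver.ok
            trace.retested = ver.retested
            trace.reliable = ver.reliable
            trace.presentations.extend(ver.presentations)
        else:
            trace.verification_ok = True
        traces[az] = trace

    meridian = field_metrics.Meridian.from_dict(
        {az: traces[az].boundary_deg for az in geometry.column_azimuths_deg})
    aum = field_metrics.aum_trapezoid(meridian)
    pct = field_metrics.percent_visible(aum, geometry)
    total = sum(t.n_presentations for t in traces.values())
    return ExamResult(geometry=geometry, column_traces=traces,
                      meridian=meridian, aum_deg2=aum, percent_visible=pct,
                      total_presentations=total, seed=rng_seed)
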