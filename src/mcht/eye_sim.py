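"""Synthetic ptotic eyes: lid occlusion ground truth and stochastic responders.

The generator's occlusion model is deliberately simple and fully stated:
the drooping upper lid truncates the superior field at an elevation that
is *linear* in MRD1 (margin-to-reflex distance), with a fully open 48°
field at MRD1 = 4.8 mm — i.e. 10° of superior field per millimetre of lid
elevation, consistent with the clinical range of 0–40° of superior loss
over pathological MRD1 values.  An optional quadratic term bows the lid
profile away from fixation; taping lifts the effective MRD1 by a fixed
amount (capped at the 5 mm anatomic maximum), emulating the presurgical
taping manoeuvre.

On top of the geometric ground truth sit the observation models:

* a stochastic seen/not-seen responder for the hemifield exam, with
  false-positive/false-negative rates and an optional cumulative-normal
  psychometric transition, and
* a synthesized central-field sensitivity grid emulating static
  threshold perimetry output (hill-of-vision baseline minus an
  eccentricity slope, near-0 dB under the lid, Gaussian measurement
  noise), including the forehead-bar artifact by which a chin/forehead
  rest can mechanically lift a ptotic lid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy.stats import norm

from . import field_metrics
from .geometry import (
    DEFAULT_GEOMETRY,
    FieldGeometry,
    GridPoint,
    make_grid_pattern,
)
from .field_metrics import VisualFieldGrid, classify_severity

__all__ = [
    "PtoticEye",
    "ResponseNoise",
    "ExamReliability",
    "CohortEye",
    "lid_elevation_profile",
    "make_responder",
    "LidResponder",
    "synthesize_hvfa_grid",
    "generate_cohort",
    "qc_exclude",
    "recover_mrd1",
    "MRD1_MAX_MM",
]

#: Anatomic ceiling on MRD1; taping cannot lift the lid past this.
MRD1_MAX_MM = 5.0


@dataclass(frozen=True)
class PtoticEye:
    """Ground-truth description of one (possibly taped) ptotic eye."""

    mrd1_mm: float
    lid_curve_gain: float = 0.0      # deg/deg²; 0 = flat lid
    mrd1_full_mm: float = 4.8        # MRD1 at which the field is fully open
    taped: bool = False
    tape_lift_mm: float = 2.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.mrd1_mm <= MRD1_MAX_MM):
            raise ValueError("mrd1_mm must lie in [0, 5]")
        if self.mrd1_full_mm <= 0:
            raise ValueError("mrd1_full_mm must be positive")
        if self.tape_lift_mm < 0:
            raise ValueError("tape_lift_mm must be non-negative")

    @property
    def effective_mrd1_mm(self) -> float:
        lift = self.tape_lift_mm if self.taped else 0.0
        return min(self.mrd1_mm + lift, MRD1_MAX_MM)


@dataclass(frozen=True)
class ResponseNoise:
    """Observer unreliability for the seen/not-seen oracle."""

    false_positive_rate: float = 0.0
    false_negative_rate: float = 0.0
    slope_deg: float = 0.0           # psychometric transition width; 0 = step

    def __post_init__(self) -> None:
        for r in (self.false_positive_rate, self.false_negative_rate):
            if not (0.0 <= r < 0.5):
                raise ValueError("noise rates must lie in [0, 0.5)")
        if self.slope_deg < 0:
            raise ValueError("slope_deg must be non-negative")


@dataclass(frozen=True)
class ExamReliability:
    """Perimetry reliability indices used for quality-control exclusion."""

    fixation_loss_pct: float
    false_positive_pct: float

    def __post_init__(self) -> None:
        for v in (self.fixation_loss_pct, self.false_positive_pct):
            if not (0.0 <= v <= 100.0):
                raise ValueError("reliability indices must lie in [0, 100]")


@dataclass(frozen=True)
class CohortEye:
    eye_id: str
    eye: PtoticEye
    severity: str
    reliability: ExamReliability


def lid_elevation_profile(eye: PtoticEye, azimuth_deg: float,
                          geometry: FieldGeometry = DEFAULT_GEOMETRY,
                          extra_lift_mm: float = 0.0) -> float:
    """Visible superior extent (degrees) at one azimuth.

    Central extent is ``elevation_max × clamp(effective_mrd1 / mrd1_full)``;
    the quadratic ``lid_curve_gain`` term bows the profile with azimuth.
    ``extra_lift_mm`` models mechanical lid elevation beyond taping (e.g.
    a perimeter's forehead bar), applied under the same anatomic cap.
    """
    eff = min(eye.effective_mrd1_mm + extra_lift_mm, MRD1_MAX_MM)
    frac = np.clip(eff / eye.mrd1_full_mm, 0.0, 1.0)
    e0 = geometry.elevation_max_deg * frac
    e = e0 + eye.lid_curve_gain * azimuth_deg ** 2
    return float(np.clip(e, 0.0, geometry.elevation_max_deg))


class LidResponder:
    """Stochastic seen/not-seen oracle for a ptotic eye.

    The step (or cumulative-normal, when ``slope_deg > 0``) visibility
    probability is mixed with the false-positive and false-negative rates:
    ``p(seen) = fp + (1 − fp − fn) · p_visible``.  A stimulus exactly at
    the lid margin counts as visible.  Draws come from a private seeded
    generator, so exams are reproducible; when the mixed probability is
    exactly 0 or 1 no random draw is consumed.
    """

    def __init__(self, eye: PtoticEye, noise: ResponseNoise = ResponseNoise(),
                 geometry: FieldGeometry = DEFAULT_GEOMETRY, rng_seed: int = 0):
        self.eye = eye
        self.noise = noise
        self.geometry = geometry
        self._rng = np.random.default_rng(rng_seed)

    def visible_extent(self, azimuth_deg: float) -> float:
        return lid_elevation_profile(self.eye, azimuth_deg, self.geometry)

    def respond(self, azimuth_deg: float, elevation_deg: float) -> bool:
        e = self.visible_extent(azimuth_deg)
        if self.noise.slope_deg > 0:
            p_vis = float(norm.cdf((e - elevation_deg) / self.noise.slope_deg))
        else:
            p_vis = 1.0 if elevation_deg <= e else 0.0
        fp, fn = self.noise.false_positive_rate, self.noise.false_negative_rate
        p = fp + (1.0 - fp - fn) * p_vis
        if p <= 0.0:
            return False
        if p >= 1.0:
            return True
        return bool(self._rng.random() < p)


def make_responder(eye: PtoticEye, noise: ResponseNoise = ResponseNoise(),
                   geometry: FieldGeometry = DEFAULT_GEOMETRY,
                   rng_seed: int = 0) -> LidResponder:
    """Construct the seeded stochastic responder for an eye."""
    return LidResponder(eye, noise, geometry, rng_seed)


def synthesize_hvfa_grid(eye: PtoticEye,
                         baseline_db: float = 33.0,
                         ecc_slope_db_per_deg: float = 0.05,
                         noise_sd_db: float = 1.0,
                         forehead_bar_lift_mm: float = 0.0,
                         rng_seed: int = 0,
                         geometry: FieldGeometry = DEFAULT_GEOMETRY,
                         eye_id: str = "") -> VisualFieldGrid:
    """Emulate a central-field static perimetry sensitivity grid.

    Unoccluded points follow a hill of vision — ``baseline_db`` minus an
    eccentricity slope plus Gaussian noise, clipped to [0, 50] dB.  Points
    under the lid read near 0 dB (dense grayscale defect).  The default
    eccentricity slope keeps unoccluded points above the 10 asb (30 dB)
    grayscale visibility cutoff across the 30° pattern.
    ``forehead_bar_lift_mm`` mechanically raises the lid, emulating the
    artifactual ptosis improvement a forehead rest can induce.
    """
    rng = np.random.default_rng(rng_seed)
    pts: List[GridPoint] = []
    for p in make_grid_pattern():
        occluded = False
        if p.elevation_deg > 0:
            e = lid_elevation_profile(eye, p.azimuth_deg, geometry,
                                      extra_lift_mm=forehead_bar_lift_mm)
            occluded = p.elevation_deg > e
        if occluded:
            s = max(0.0, rng.normal(0.0, noise_sd_db)) if noise_sd_db > 0 else 0.0
        else:
            s = baseline_db - ecc_slope_db_per_deg * p.eccentricity_deg
            if noise_sd_db > 0:
                s += rng.normal(0.0, noise_sd_db)
        pts.append(GridPoint(p.azimuth_deg, p.elevation_deg,
                             float(np.clip(s, 0.0, 50.0))))
    return VisualFieldGrid(points=pts, eye_id=eye_id,
                           condition="taped" if eye.taped else "untaped",
                           device="hvfa_sim")


# Within-stratum MRD1 ranges (mm): the anatomic grading boundaries.
_STRATA = ((field_metrics.SEVERE, 0.0, 2.0),
           (field_metrics.MILD, 2.0, 4.0),
           (field_metrics.NORMAL, 4.0, 5.0))


def _default_reliability(rng: np.random.Generator) -> ExamReliability:
    # Beta-distributed indices: most exams comfortably reliable, a tail of
    # fixation-loss-heavy and trigger-happy exams that the QC rule removes.
    fl = 100.0 * rng.beta(2.0, 8.0)
    fp = 100.0 * rng.beta(1.5, 15.0)
    return ExamReliability(min(fl, 100.0), min(fp, 100.0))


def generate_cohort(n_severe: int = 18, n_mild: int = 6, n_normal: int = 6,
                    rng_seed: int = 0,
                    reliability_sampler: Optional[
                        Callable[[np.random.Generator], ExamReliability]] = None
                    ) -> List[CohortEye]:
    """Draw a stratified cohort of ptotic eyes.

    MRD1 is uniform within each severity stratum (severe [0, 2), mild
    [2, 4), normal [4, 5]); per-eye reliability indices are drawn from
    ``reliability_sampler`` (default: beta-tailed indices).
    """
    if min(n_severe, n_mild, n_normal) < 0:
        raise ValueError("cohort counts must be non-negative")
    sampler = reliability_sampler or _default_reliability
    rng = np.random.default_rng(rng_seed)
    counts = {field_metrics.SEVERE: n_severe, field_metrics.MILD: n_mild,
              field_metrics.NORMAL: n_normal}
    cohort: List[CohortEye] = []
    for label, lo, hi in _STRATA:
        for _ in range(counts[label]):
            mrd1 = float(rng.uniform(lo, hi))
            assert classify_severity(mrd1) == label
            cohort.append(CohortEye(
                eye_id=f"eye{len(cohort):03d}",
                eye=PtoticEye(mrd1_mm=mrd1),
                severity=label,
                reliability=sampler(rng),
            ))
    return cohort


def qc_exclude(rel: ExamReliability,
               fl_cutoff_pct: float = 50.0, fp_cutoff_pct: float = 15.0) -> bool:
    """Reliability exclusion: fixation loss ≥ 50% or false positives ≥ 15%."""
    return (rel.fixation_loss_pct >= fl_cutoff_pct
            or rel.false_positive_pct >= fp_cutoff_pct)


def recover_mrd1(meridian: field_metrics.Meridian,
                 geometry: FieldGeometry = DEFAULT_GEOMETRY,
                 mrd1_full_mm: float = 4.8) -> float:
    """Invert the linear lid model: mean meridian elevation → MRD1 estimate.

    Valid for flat lids with MRD1 at or below ``mrd1_full_mm`` (above it
    the field saturates and the map is not invertible).
    """
    mean_e = float(np.mean(meridian.elevations_deg))
    return mean_e / geometry.elevation_max_deg * mrd1_full_mm
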