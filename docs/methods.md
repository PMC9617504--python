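# Methods

## The boundary-search model

Suprathreshold hemifield perimetry for ptosis asks one question per
stimulus — seen or not seen — and relies on the monotone structure of lid
occlusion: at a fixed azimuth, everything below the lid margin is visible
and everything above is not. Each tested column therefore reduces to
locating a single transition elevation, and bisection is the optimal
noise-free strategy.

The engine works in display-pixel space (default 15 px/°, the angular
resolution scale of consumer VR headsets; the 48° superior extent spans
720 px). Running bounds start at the bottom (fixation) and top stimulus
rows; the first stimulus is the column middle; *seen* raises the lower
bound to the stimulus, *not seen* lowers the upper bound; the next
stimulus is the midpoint of the surviving bracket. The search stops when
consecutive pivots differ by at most the stop threshold (10 px), and the
boundary estimate is the midpoint of the final bracket.

Numerical choices that matter:

- **The stop check uses the exact (unrounded) midpoint.** This caps the
  final bracket at `2 × stop_px`, so a monotone responder's true boundary
  (always inside the bracket) is within `stop_px / ppd = 0.67°` of the
  estimate. Rounding before the check would admit a bracket of
  `2·stop + 1` px and break that bound by half a pixel.
- **Monotone escapes present the extreme row.** If the search converges
  with one bound untouched (every response went one way), the engine
  presents that extreme row once: a seen top row pins the boundary at the
  full extent, an unseen bottom row at 0. This yields exact 48°/0°
  results for fully open/closed columns at the cost of at most one extra
  presentation, inside the `⌈log₂(extent/stop)⌉ + 2` budget.
- **Stimulus visibility is inclusive** (a stimulus exactly at the lid
  margin is seen), so a fully open eye pins at exactly 48°.
- **Verification** probes `boundary ± 2·stop_px/ppd` (1.33° default),
  expecting *seen* below and *not seen* above. A probe that clamps onto
  the boundary itself (a 0° boundary has no "below", a 48° one no
  "above") is uninformative and skipped. A mismatched probe is retested
  once; a persistent mismatch flags the column unreliable. Flagged
  columns keep their boundary — the flag is reported, not acted on —
  since discarding or retesting whole columns is a policy choice the
  deployed instrument would own.
- **Column order** is a seeded random permutation (the within-column
  start is deterministically the middle); with a fixed seed and
  deterministic responder the exam, including its presentation log, is
  byte-identical across runs. A guard of 30 presentations per column
  bounds pathological stochastic responders; the bracket halves every
  presentation regardless of response correctness, so termination never
  depends on the guard for sane inputs.

## The synthetic eye

The generator *defines* the simulated study conditions; it emulates the
screening situation, not lid anatomy:

- **Lid occlusion is linear in MRD1**: visible central extent
  `48° × clamp(MRD1 / 4.8 mm, 0, 1)`, i.e. 10°/mm, consistent with the
  clinical range of 0–40° superior loss over pathological MRD1. An
  optional quadratic azimuth term bows the profile; the default is a flat
  lid. No published per-patient MRD1→field map exists; this is the
  package's synthetic-data model, and parameter-recovery results quantify
  the *algorithm*, not clinical accuracy.
- **Taping** lifts effective MRD1 by 2.5 mm (configurable), capped at the
  5 mm anatomic maximum. Real taping effects vary per patient; the fixed
  lift makes taped/untaped contrasts deterministic.
- **Responder noise**: `p(seen) = fp + (1 − fp − fn)·p_visible`, with
  `p_visible` a step (default) or cumulative-normal transition. Rates are
  capped below 0.5 (beyond that the response channel is uninformative).
- **Synthesized grids** place a hill of vision `33 dB − 0.05 dB/° × ecc`
  plus Gaussian noise (σ = 1 dB) above the lid margin and near-0 dB below
  it, on an 80-point ±30° lattice (eccentricity-filtered 10×10 grid at
  ±3..±27°; the clinical pattern has 76 points — the approximation is
  deliberate and only feeds synthetic data). The eccentricity slope keeps
  unoccluded points above the 30 dB visibility cutoff across the pattern
  (31.5 dB at 30° eccentricity); a steeper, more anatomically typical
  slope would push normal periphery below the 10 asb grayscale cutoff and
  conflate eccentricity with occlusion. With the default 1 dB noise,
  edge points sit 1.5 σ above the cutoff, so occasional single-cell flips
  occur — deliberate, as static perimetry's test–retest variability is a
  real feature of the screening problem.
- **Forehead-bar lift**: grids can be synthesized with an extra
  mechanical MRD1 lift, emulating the artifactual ptosis improvement a
  perimeter's forehead rest induces; the hemifield exam (periorbital
  headset) has no such term.
- **Cohorts** draw MRD1 uniformly within severity strata (severe [0, 2),
  mild [2, 4), normal [4, 5] mm; default 18/6/6 eyes) — the within-stratum
  distribution of real cohorts is unpublished, so uniform is a stand-in.
  Reliability indices come from beta distributions with realistic tails;
  the exclusion rule (fixation loss ≥ 50% or false positives ≥ 15%)
  typically removes a handful of eyes per cohort.

## Quantification conventions

- **AUM** is the trapezoid rule over the meridian samples, with no
  extrapolation beyond the first/last azimuth. **Percent visible**
  normalizes by the frame: superior extent × column span (48 × 48° for
  the hemifield exam, 30 × 54° for the grid). The two devices therefore
  measure on different frames — percent and ratio quantities are
  comparable, raw areas are not.
- **Grayscale cutoff**: visible ⇔ threshold luminance < 10 asb ⇔
  sensitivity > 30 dB. (Lower threshold luminance means better
  sensitivity; the opposite reading would label blind regions visible.)
- **Grid tracing** walks each column's available elevations upward from
  the lowest superior row while points stay visible; the extent is the
  highest contiguously seen elevation + 3° (half a cell), so a fully
  visible 27°-top column reads the full 30°. Islands of vision above a
  gap do not extend the boundary — the tracer mirrors the exam's own
  scotoma guard. A column whose *every* available point is seen is
  credited the full 30°: outer columns (±21°, ±27°) reach only 21° or 9°
  of elevation before leaving the 30° circle, so they cannot resolve
  high lid margins, and crediting the frame extent avoids biasing
  full-field eyes downward. Consequently the tracer resolves lid extent
  to within one 6° cell only on the full five-point columns (±3°, ±9°);
  tests assert recovery there.
- **Percent degrees visible** averages the two columns adjacent to the
  midline (±3°; the lattice has no x = 0 column) over the 30° frame; for
  exam meridians it interpolates at x = 0 over the 48° frame.
- **Percent improvement** is `(taped − untaped)/untaped × 100`; a zero
  baseline that opens at all maps to +∞ (eligible), two zero fields to
  0%. Eligibility is inclusive at the 30% threshold.
- **Quartiles** in the IQR outlier rule use linear interpolation between
  order statistics (the numpy default).

## Statistics

All tests target pilot-scale samples. McNemar is the exact binomial
version, `p = min(1, 2·P(X ≤ min(b, c)))` — the χ² form cannot return
p = 1 for a (1, 2) discordant split. Fisher's exact test uses the
two-sided probability-mass rule (alternative conventions differ in the
third decimal). The accuracy test is a one-sided exact binomial tail
against a 90% null. Conover–Iman post hocs use the pooled-rank variance
deflated by the Kruskal–Wallis H on N − k degrees of freedom, with Holm
step-down adjustment. Wilcoxon signed-rank drops zero differences and
uses the exact distribution for small tie-free samples, the
tie-corrected normal approximation otherwise. Scipy/statsmodels provide
the standard machinery behind this module's surface; the exact-test
conventions are pinned by enumeration oracles in the test suite.

The 2×2 agreement table is oriented reference × test, with the grid
device as the reference axis (gold-standard framing). The reconstruction
utility inverts printed (n, reference positives, TPR, precision) margins;
the solution is unique and non-integral margins raise an error.

## Simulated-cohort behaviour, and what it does not show

A noise-free default cohort separates percent visible by severity at
Kruskal–Wallis p < 10⁻³ on both devices and agrees on eligibility for
every severe and normal eye. Mild eyes with lid margins between ~30° and
~37° can split: the 30°-capped grid already reads them as full fields
(0% improvement) while the 48° exam frame still shows a ≥ 30% gain. This
frame mismatch is a real property of the two instruments, not a
simulation artifact, and it produces test-positive/reference-negative
disagreements concentrated in the mild band — the simulated cohorts also
reproduce the observed direction that the hemifield exam reads lower
percent-visible than the grid.

Passing tests show the algorithmic claims (boundary error bounds,
logarithmic presentation counts, exact-statistic values, recovery of the
generator's own parameters). They do not validate clinical performance:
the generator has flat lids, no refractive or retinal comorbidity, no
fatigue or learning effects (a fatigue knob exists but defaults to 0),
and its linear MRD1 map is an idealization. Problem sizes in the test
suite and acceptance script (100-boundary oracle sweeps, 200-eye noise
studies, 30-eye cohorts) were chosen to match the pilot-study scale the
package models.
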