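"""End-to-end orchestration: cohorts, paired exams, and the statistical battery.

A single master seed drives every randomized step through labelled
substreams (seed = hash(master, labels...)), so adding or reordering an
analysis step never perturbs the draws of another, and a fixed master
seed reproduces the full report byte for byte.

The cohort pipeline mirrors a paired-device eligibility study: each eye
is measured untaped and taped on both the hemifield exam (48° superior
frame) and the synthesized central-field grid (30° frame, with an
optional forehead-bar lid lift), unreliable exams are excluded by the
fixation-loss/false-positive rule, percent AUM improvement is thresholded
into surgical eligibility on each device, and the agreement and
group-comparison statistics are computed with the grid device as the
reference axis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import eye_sim, field_metrics, stats
from .engine import run_hemifield_exam
from .eye_sim import CohortEye, PtoticEye, ResponseNoise, make_responder
from .field_metrics import GRID_FRAME
from .geometry import DEFAULT_GEOMETRY, FieldGeometry

__all__ = [
    "RunConfig",
    "substream_seed",
    "measure_eye",
    "run_cohort",
    "analyze_eye_table",
    "reproduce_reported_agreement",
    "REPORTED_PILOT_SUMMARY",
]

#: Headline summary statistics of the published pilot validation cohort
#: (18 analyzable eyes, 4 reference-eligible), against which the
#: reconstruction utilities check themselves.
REPORTED_PILOT_SUMMARY = {
    "n": 18,
    "ref_positives": 4,
    "tpr": 0.75,
    "precision": 0.60,
    "agreement_pct": 83.3,
    "mcnemar_p": 1.0,
    "binomial_p": 0.27,
    "fisher_alpha": 0.05,
    "accuracy_null": 0.9,
}


def substream_seed(master_seed: int, *labels: str) -> int:
    """Deterministic per-stage seed derived from the master seed + labels."""
    text = f"{master_seed}/" + "/".join(labels)
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """All knobs of a simulated trial run."""

    geometry: FieldGeometry = field(default_factory=FieldGeometry)
    noise: ResponseNoise = field(default_factory=ResponseNoise)
    n_severe: int = 18
    n_mild: int = 6
    n_normal: int = 6
    tape_lift_mm: float = 2.5
    forehead_bar_lift_mm: float = 0.0
    baseline_db: float = 33.0
    ecc_slope_db_per_deg: float = 0.05
    grid_noise_sd_db: float = 1.0
    cutoff_asb: float = field_metrics.DEFAULT_CUTOFF_ASB
    improvement_threshold_pct: float = 30.0
    qc_fl_cutoff_pct: float = 50.0
    qc_fp_cutoff_pct: float = 15.0
    accuracy_null: float = 0.9
    fatigue_noise_increment: float = 0.0
    apply_qc: bool = True
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "geometry" in kwargs:
            kwargs["geometry"] = FieldGeometry(**kwargs["geometry"])
        if "noise" in kwargs:
            kwargs["noise"] = ResponseNoise(**kwargs["noise"])
        return cls(**kwargs)

    @classmethod
    def default(cls) -> "RunConfig":
        """The packaged default configuration."""
        from importlib.resources import files
        raw = yaml.safe_load(files("mcht.data")
                             .joinpath("default_config.yaml").read_text())
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"] = dataclasses.asdict(self.geometry)
        d["geometry"]["column_azimuths_deg"] = list(
            self.geometry.column_azimuths_deg)
        d["noise"] = dataclasses.asdict(self.noise)
        return d


def measure_eye(cohort_eye: CohortEye, config: RunConfig, sequence: str = "B"
                ) -> Dict[str, object]:
    """Run both devices, untaped and taped, on one eye.

    ``sequence`` 'A' tests the grid device first, 'B' the hemifield exam
    first; the later device's noise is inflated by
    ``fatigue_noise_increment`` (0 by default, so the sequences are
    statistically identical unless the knob is turned).
    """
    eye = dataclasses.replace(cohort_eye.eye, tape_lift_mm=config.tape_lift_mm)
    mrd1 = eye.mrd1_mm
    ms = config.master_seed
    eid = cohort_eye.eye_id
    fat = config.fatigue_noise_increment if sequence == "A" else 0.0
    mcht_noise = dataclasses.replace(
        config.noise,
        false_positive_rate=min(config.noise.false_positive_rate + fat, 0.499),
        false_negative_rate=min(config.noise.false_negative_rate + fat, 0.499))
    grid_sd = config.grid_noise_sd_db + (
        config.fatigue_noise_increment if sequence == "B" else 0.0)

    row: Dict[str, object] = {
        "eye_id": eid, "mrd1_mm": mrd1, "severity": cohort_eye.severity,
        "sequence": sequence,
        "fixation_loss_pct": cohort_eye.reliability.fixation_loss_pct,
        "false_positive_pct": cohort_eye.reliability.false_positive_pct,
    }

    for condition in ("untaped", "taped"):
        e = dataclasses.replace(eye, taped=(condition == "taped"))
        responder = make_responder(
            e, mcht_noise, config.geometry,
            rng_seed=substream_seed(ms, "mcht", eid, condition, "responder"))
        exam = run_hemifield_exam(
            responder, config.geometry,
            rng_seed=substream_seed(ms, "mcht", eid, condition, "exam"))
        row[f"mcht_aum_{condition}"] = exam.aum_deg2
        row[f"mcht_pct_visible_{condition}"] = exam.percent_visible
        if condition == "untaped":
            row["mcht_pdv_untaped"] = field_metrics.percent_degrees_visible(
                exam.meridian, config.geometry)
            row["mcht_presentations_untaped"] = exam.total_presentations

        grid = eye_sim.synthesize_hvfa_grid(
            e, baseline_db=config.baseline_db,
            ecc_slope_db_per_deg=config.ecc_slope_db_per_deg,
            noise_sd_db=grid_sd,
            forehead_bar_lift_mm=config.forehead_bar_lift_mm,
            rng_seed=substream_seed(ms, "hvfa", eid, condition, "grid"),
            geometry=config.geometry, eye_id=eid)
        meridian = field_metrics.trace_grid_meridian(grid, config.cutoff_asb)
        aum = field_metrics.aum_trapezoid(meridian)
        row[f"hvfa_aum_{condition}"] = aum
        row[f"hvfa_pct_visible_{condition}"] = field_metrics.percent_visible(
            aum, GRID_FRAME)
        if condition == "untaped":
            row["hvfa_pdv_untaped"] = field_metrics.percent_degrees_visible(
                grid, cutoff_asb=config.cutoff_asb)

    for dev in ("mcht", "hvfa"):
        imp = field_metrics.percent_improvement(
            row[f"{dev}_aum_untaped"], row[f"{dev}_aum_taped"])
        row[f"{dev}_improvement_pct"] = imp
        row[f"{dev}_eligible"] = stats.classify_eligibility(
            imp, config.improvement_threshold_pct)
    return row


def _maybe(fn, *args, **kwargs):
    """Run a statistic; degenerate inputs yield None rather than aborting."""
    try:
        return fn(*args, **kwargs)
    except ValueError:
        return None


def analyze_eye_table(df: pd.DataFrame, config: Optional[RunConfig] = None
                      ) -> Dict[str, object]:
    """The statistical battery over a per-eye measurement table."""
    config = config or RunConfig()
    out: Dict[str, object] = {"n_eyes": int(len(df))}
    if len(df) == 0:
        raise ValueError("no eyes to analyze (empty post-QC cohort)")

    cs = stats.ConfusionSummary(
        tp=int(((df.hvfa_eligible) & (df.mcht_eligible)).sum()),
        fn=int(((df.hvfa_eligible) & (~df.mcht_eligible)).sum()),
        fp=int(((~df.hvfa_eligible) & (df.mcht_eligible)).sum()),
        tn=int(((~df.hvfa_eligible) & (~df.mcht_eligible)).sum()),
    )
    out["confusion"] = {"tp": cs.tp, "fn": cs.fn, "fp": cs.fp, "tn": cs.tn}
    out["agreement_pct"] = 100.0 * cs.agreement
    out["tpr_pct"] = None if cs.tpr is None else 100.0 * cs.tpr
    out["precision_pct"] = None if cs.precision is None else 100.0 * cs.precision
    out["mcnemar_p"] = stats.mcnemar_exact(*cs.discordant)
    out["fisher_p"] = _maybe(stats.fisher_exact_2x2, cs)
    out["binomial_accuracy_p"] = stats.binomial_accuracy_test(
        cs.tp + cs.tn, cs.n, config.accuracy_null)

    by_severity = {
        dev: [df.loc[df.severity == s, f"{dev}_pct_visible_untaped"].to_numpy()
              for s in (field_metrics.SEVERE, field_metrics.MILD,
                        field_metrics.NORMAL)
              if (df.severity == s).any()]
        for dev in ("mcht", "hvfa")
    }
    for dev, groups in by_severity.items():
        kw = _maybe(stats.kruskal_wallis, *groups)
        out[f"kw_{dev}"] = (None if kw is None
                            else {"H": kw[0], "p": kw[1]})
        ch = _maybe(stats.conover_holm, *groups)
        out[f"conover_{dev}"] = (None if ch is None
                                 else ch.to_dict(orient="records"))

    out["wilcoxon_untaped_p"] = _maybe(
        stats.wilcoxon_signed_rank,
        df.mcht_pct_visible_untaped, df.hvfa_pct_visible_untaped)

    for dev in ("mcht", "hvfa"):
        corr = _maybe(stats.correlations, df.mrd1_mm, df[f"{dev}_pdv_untaped"])
        out[f"corr_pdv_mrd1_{dev}"] = (
            None if corr is None
            else dict(zip(("pearson_r", "spearman_rho", "r_squared"), corr)))
        severe = df[df.severity == field_metrics.SEVERE]
        corr_s = _maybe(stats.correlations, severe.mrd1_mm,
                        severe[f"{dev}_pdv_untaped"])
        out[f"corr_pdv_mrd1_severe_{dev}"] = (
            None if corr_s is None
            else dict(zip(("pearson_r", "spearman_rho", "r_squared"), corr_s)))
    return out


def run_cohort(config: Optional[RunConfig] = None) -> Dict[str, object]:
    """Simulate and analyze a full paired-device cohort.

    Returns a report dict with the configuration, per-eye table
    (``eyes`` key, list of records) and the statistical battery under
    ``analysis``.
    """
    config = config or RunConfig()
    cohort = eye_sim.generate_cohort(
        config.n_severe, config.n_mild, config.n_normal,
        rng_seed=substream_seed(config.master_seed, "cohort"))
    if not cohort:
        raise ValueError("configured cohort is empty")

    seq_rng = np.random.default_rng(substream_seed(config.master_seed, "sequence"))
    seqs = np.array((["A", "B"] * ((len(cohort) + 1) // 2))[:len(cohort)])
    seq_rng.shuffle(seqs)

    rows = []
    for ce, seq in zip(cohort, seqs):
        row = measure_eye(ce, config, sequence=str(seq))
        row["excluded"] = bool(
            config.apply_qc and eye_sim.qc_exclude(
                ce.reliability, config.qc_fl_cutoff_pct, config.qc_fp_cutoff_pct))
        rows.append(row)
    df = pd.DataFrame(rows)
    kept = df[~df.excluded].reset_index(drop=True)
    if len(kept) == 0:
        raise ValueError("empty post-QC cohort: every exam was excluded")

    return {
        "config": config.to_dict(),
        "n_total": int(len(df)),
        "n_excluded": int(df.excluded.sum()),
        "eyes": df.to_dict(orient="records"),
        "analysis": analyze_eye_table(kept, config),
    }


def write_report(report: Dict[str, object], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    pd.DataFrame(report["eyes"]).to_csv(outdir / "eyes.csv", index=False)
    conf = report["analysis"]["confusion"]
    pd.DataFrame([conf]).to_csv(outdir / "confusion.csv", index=False)


def reproduce_reported_agreement(summary: Optional[dict] = None
                                 ) -> List[Dict[str, object]]:
    """Recompute the eligibility-agreement statistics from printed margins.

    The reconstruction inverts (n, reference positives, TPR, precision)
    into the 2×2 table, then recomputes every agreement statistic from
    that table and checks it against the reported value at its printed
    precision.  Returns one record per statistic with a pass flag.
    """
    rep = dict(REPORTED_PILOT_SUMMARY)
    if summary:
        rep.update(summary)
    cs = stats.reconstruct_confusion(rep["n"], rep["ref_positives"],
                                     rep["tpr"], rep["precision"])
    mcnemar = stats.mcnemar_exact(*cs.discordant)
    fisher = stats.fisher_exact_2x2(cs)
    binom = stats.binomial_accuracy_test(cs.tp + cs.tn, cs.n,
                                         rep["accuracy_null"])
    lines = [
        {"name": "table", "computed": [cs.tp, cs.fn, cs.fp, cs.tn],
         "reported": None, "pass": True},
        {"name": "agreement_pct", "computed": 100.0 * cs.agreement,
         "reported": rep["agreement_pct"],
         "pass": abs(100.0 * cs.agreement - rep["agreement_pct"]) < 0.05},
        {"name": "tpr_pct", "computed": 100.0 * cs.tpr,
         "reported": 100.0 * rep["tpr"],
         "pass": abs(cs.tpr - rep["tpr"]) < 1e-9},
        {"name": "precision_pct", "computed": 100.0 * cs.precision,
         "reported": 100.0 * rep["precision"],
         "pass": abs(cs.precision - rep["precision"]) < 1e-9},
        {"name": "mcnemar_p", "computed": mcnemar, "reported": rep["mcnemar_p"],
         "pass": mcnemar == rep["mcnemar_p"]},
        {"name": "binomial_accuracy_p", "computed": binom,
         "reported": rep["binomial_p"],
         "pass": abs(binom - rep["binomial_p"]) < 0.005},
        {"name": "fisher_p", "computed": fisher,
         "reported": f"< {rep['fisher_alpha']}",
         "pass": fisher < rep["fisher_alpha"]},
    ]
    return lines
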