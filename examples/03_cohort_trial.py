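"""Simulate a full paired-device eligibility trial.

Thirty eyes (18 severe / 6 mild / 6 normal) are measured untaped and
taped on both devices; unreliable exams are excluded; percent AUM
improvement over 30% marks surgical eligibility; and the agreement and
severity-separation statistics are computed with the grid device as the
reference.
"""

import pandas as pd

from mcht.pipeline import RunConfig, run_cohort

report = run_cohort(RunConfig(master_seed=1))
analysis = report["analysis"]

print(f"eyes simulated: {report['n_total']}, "
      f"excluded by QC: {report['n_excluded']}")
print(f"confusion (ref=grid): {analysis['confusion']}")
print(f"eligibility agreement: {analysis['agreement_pct']:.1f}%")
print(f"exact McNemar p:       {analysis['mcnemar_p']:.3f}")
print(f"Kruskal-Wallis p (exam/grid): "
      f"{analysis['kw_mcht']['p']:.2e} / {analysis['kw_hvfa']['p']:.2e}")

df = pd.DataFrame(report["eyes"])
print("\nmean percent visible by severity:")
print(df.groupby("severity")[["mcht_pct_visible_untaped",
                              "hvfa_pct_visible_untaped"]].mean().round(1))
# Severity separates cleanly on both devices (tiny Kruskal-Wallis p), and
# the hemifield exam reads systematically lower than the 30-degree-capped
# grid -- the same scale difference the two real devices exhibit.
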