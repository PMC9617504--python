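"""Agreement and group-comparison statistics with exact small-sample conventions.

Designed for the cohort sizes of a pilot diagnostic-agreement study
(tens of eyes), where asymptotic tests are inappropriate:

* McNemar's test in its *exact binomial* form (the χ² version with
  continuity correction cannot return the p = 1 that 3 discordant pairs
  produce under the exact convention);
* Fisher's exact test with the probability-mass two-sided rule;
* a one-sided exact binomial test of observed accuracy against a
  null accuracy (90% by default);
* Kruskal–Wallis with tie correction, Conover–Iman rank post hocs under
  Holm step-down adjustment, and the exact-when-possible Wilcoxon
  signed-rank test for the paired device comparison.

The 2×2 agreement table is oriented with the reference (gold-standard)
device on the rows and the test device on the columns:
rows/cols = eligible, not-eligible, cells = (tp, fn / fp, tn).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConfusionSummary",
    "InconsistentSummaryError",
    "classify_eligibility",
    "reconstruct_confusion",
    "mcnemar_exact",
    "fisher_exact_2x2",
    "binomial_accuracy_test",
    "kruskal_wallis",
    "conover_holm",
    "wilcoxon_signed_rank",
    "correlations",
]


class InconsistentSummaryError(ValueError):
    """Printed summary statistics do not correspond to an integer table."""


@dataclass(frozen=True)
class ConfusionSummary:
    """2×2 eligibility agreement table (reference rows × test columns)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def agreement(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def tpr(self) -> Optional[float]:
        """Sensitivity against the reference; None when no reference positives."""
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else None

    @property
    def precision(self) -> Optional[float]:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp > 0 else None

    @property
    def discordant(self) -> Tuple[int, int]:
        """(reference-only positives, test-only positives) = (fn, fp)."""
        return self.fn, self.fp

    def as_table(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


def classify_eligibility(percent_improvement: float,
                         threshold_pct: float = 30.0) -> bool:
    """Surgical eligibility: taping improvement at or above the threshold."""
    return percent_improvement >= threshold_pct


def reconstruct_confusion(n: int, ref_positives: int, tpr: float,
                          precision: float, tol: float = 1e-6
                          ) -> ConfusionSummary:
    """Invert printed (n, reference positives, TPR, precision) to a 2×2 table.

    The three rates determine the table uniquely; non-integral solutions
    raise :class:`InconsistentSummaryError`.
    """
    tp_f = tpr * ref_positives
    tp = round(tp_f)
    if abs(tp_f - tp) > tol:
        raise InconsistentSummaryError(
            f"TPR × positives = {tp_f} is not an integer")
    if precision <= 0:
        raise InconsistentSummaryError("precision must be positive")
    fp_f = tp / precision - tp
    fp = round(fp_f)
    if abs(fp_f - fp) > tol:
        raise InconsistentSummaryError(
            f"tp/precision − tp = {fp_f} is not an integer")
    fn = ref_positives - tp
    tn = n - tp - fp - fn
    if min(tp, fn, fp, tn) < 0:
        raise InconsistentSummaryError("summary implies a negative cell count")
    return ConfusionSummary(tp=int(tp), fn=int(fn), fp=int(fp), tn=int(tn))


def mcnemar_exact(b: int, c: int) -> float:
    """Exact binomial McNemar test on the discordant pair counts.

    p = min(1, 2 · P(X ≤ min(b, c))), X ~ Binomial(b + c, ½); p = 1 when
    there is no discordance.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * sps.binom.cdf(min(b, c), n, 0.5)))


def fisher_exact_2x2(table: Union[ConfusionSummary, Sequence[Sequence[int]]]
                     ) -> float:
    """Two-sided Fisher's exact test (probability-mass rule, fixed margins)."""
    if isinstance(table, ConfusionSummary):
        arr = table.as_table()
    else:
        arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if arr.sum() == 0:
        raise ValueError("all-zero table")
    return float(sps.fisher_exact(arr, alternative="two-sided").pvalue)


def binomial_accuracy_test(successes: int, n: int, p0: float = 0.9,
                           alternative: str = "less") -> float:
    """One-sided exact binomial test of observed accuracy against p0.

    ``alternative='less'`` tests whether the data are compatible with a
    true accuracy of at least p0 (the noninferiority framing):
    p = P(X ≤ successes), X ~ Binomial(n, p0).
    """
    if not (0 <= successes <= n):
        raise ValueError("successes must lie in [0, n]")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie in (0, 1)")
    if alternative == "less":
        return float(sps.binom.cdf(successes, n, p0))
    if alternative == "greater":
        return float(sps.binom.sf(successes - 1, n, p0))
    raise ValueError("alternative must be 'less' or 'greater'")


def _check_groups(groups: Sequence[Sequence[float]]) -> List[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in gs):
        raise ValueError("groups must be non-empty")
    return gs


def kruskal_wallis(*groups: Sequence[float]) -> Tuple[float, float]:
    """Kruskal–Wallis rank-sum test with tie correction.

    Returns (H, p) with p from the χ² distribution on k − 1 degrees of
    freedom.  An input whose pooled values are all identical has H = 0 and
    p = 1 by convention.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) \
            and groups[0] and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    gs = _check_groups(groups)
    pooled = np.concatenate(gs)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    res = sps.kruskal(*gs)
    return float(res.statistic), float(res.pvalue)


def conover_holm(*groups: Sequence[float],
                 labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Conover–Iman rank post hocs after Kruskal–Wallis, Holm-adjusted.

    The pairwise t statistics use the pooled-rank variance deflated by the
    Kruskal–Wallis H, on N − k degrees of freedom.  Returns one row per
    pair with the statistic, raw p and Holm-adjusted p.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) \
            and groups[0] and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    gs = _check_groups(groups)
    k = len(gs)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    sizes = np.array([len(g) for g in gs])
    N = int(sizes.sum())
    if N - k <= 0:
        raise ValueError("need more observations than groups")
    pooled = np.concatenate(gs)
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum(sizes)[:-1]
    group_ranks = np.split(ranks, bounds)
    mean_ranks = np.array([r.mean() for r in group_ranks])

    H, _ = kruskal_wallis(*gs)
    s2 = (np.sum(ranks ** 2) - N * (N + 1) ** 2 / 4.0) / (N - 1)
    scale = s2 * (N - 1 - H) / (N - k)

    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = abs(mean_ranks[i] - mean_ranks[j])
        denom2 = scale * (1.0 / sizes[i] + 1.0 / sizes[j])
        if denom2 <= 0:
            p_raw = 0.0 if diff > 0 else 1.0
            t = np.inf if diff > 0 else 0.0
        else:
            t = diff / np.sqrt(denom2)
            p_raw = float(2.0 * sps.t.sf(t, df=N - k))
        rows.append((labels[i], labels[j], float(t), min(1.0, p_raw)))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p_raw"])
    df["p_holm"] = multipletests(df["p_raw"], method="holm")[1]
    return df


def wilcoxon_signed_rank(paired_a: Sequence[float],
                         paired_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank test on paired measurements.

    Zero differences are dropped; at least 5 informative pairs are
    required.  The exact null distribution is used for small samples
    without ties, the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero")
    if len(d) < 5:
        raise ValueError("need at least 5 nonzero paired differences")
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                       method="auto")
    return float(res.pvalue)


def correlations(x: Sequence[float], y: Sequence[float]
                 ) -> Tuple[float, float, float]:
    """(Pearson r, Spearman ρ, r²) of two equal-length samples."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or len(xa) < 3:
        raise ValueError("need equal-length samples of at least 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero-variance input")
    r = float(sps.pearsonr(xa, ya).statistic)
    rho = float(sps.spearmanr(xa, ya).statistic)
    return r, rho, r * r
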