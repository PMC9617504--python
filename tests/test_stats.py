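import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps

from mcht.stats import (
    ConfusionSummary,
    InconsistentSummaryError,
    binomial_accuracy_test,
    classify_eligibility,
    conover_holm,
    correlations,
    fisher_exact_2x2,
    kruskal_wallis,
    mcnemar_exact,
    reconstruct_confusion,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------- oracles

def fisher_two_sided_enumeration(a, b, c, d):
    """Sum hypergeometric probabilities ≤ the observed table's, margins fixed."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))

    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def mcnemar_exact_enumeration(b, c):
    """Two-sided exact binomial tail by direct pmf summation."""
    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    tail = sum(math.comb(n, i) for i in range(k + 1)) / 2 ** n
    return min(1.0, 2 * tail)


# ----------------------------------------------------------------- tests

class TestEligibility:
    @pytest.mark.parametrize("improvement,eligible", [
        (30.0, True),     # boundary inclusive
        (29.9, False),
        (float("inf"), True),
    ])
    def test_threshold(self, improvement, eligible):
        assert classify_eligibility(improvement) is eligible


class TestConfusion:
    def test_pilot_summary_reconstruction(self):
        cs = reconstruct_confusion(18, 4, 0.75, 0.60)
        assert (cs.tp, cs.fn, cs.fp, cs.tn) == (3, 1, 2, 12)
        assert cs.agreement == pytest.approx(15 / 18)
        assert cs.tpr == pytest.approx(0.75)
        assert cs.precision == pytest.approx(0.60)

    def test_inconsistent_summary_rejected(self):
        with pytest.raises(InconsistentSummaryError):
            reconstruct_confusion(10, 4, 0.77, 0.6)

    def test_round_trip_over_small_tables(self):
        # every table with defined TPR/precision reconstructs itself
        rng = np.random.default_rng(2)
        for _ in range(200):
            tp, fn, fp, tn = rng.integers(0, 8, size=4)
            cs = ConfusionSummary(int(tp), int(fn), int(fp), int(tn))
            if cs.tpr is None or cs.precision is None or cs.tp == 0:
                continue
            back = reconstruct_confusion(cs.n, cs.tp + cs.fn, cs.tpr,
                                         cs.precision)
            assert back == cs

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionSummary(-1, 0, 0, 0)


class TestMcNemar:
    @pytest.mark.parametrize("b,c,expected", [
        (1, 2, 1.0),                 # the pilot cohort's discordant pair
        (0, 0, 1.0),
        (0, 8, 2 / 256),
    ])
    def test_known_values(self, b, c, expected):
        assert mcnemar_exact(b, c) == pytest.approx(expected)

    def test_matches_enumeration_up_to_12_discordant(self):
        for b in range(13):
            for c in range(13 - b):
                assert mcnemar_exact(b, c) == pytest.approx(
                    mcnemar_exact_enumeration(b, c))


class TestFisher:
    def test_pilot_table(self):
        p = fisher_exact_2x2([[3, 1], [2, 12]])
        assert p == pytest.approx(0.0441176470588, abs=1e-9)
        assert p < 0.05

    def test_independent_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == 1.0

    def test_diagonal_table_hand_enumeration(self):
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_matches_enumeration_on_all_small_tables(self):
        cells = [t for t in itertools.product(range(4), repeat=4)
                 if 0 < sum(t) <= 12]
        for a, b, c, d in cells:
            assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                fisher_two_sided_enumeration(a, b, c, d), abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])


class TestBinomialAccuracy:
    def test_pilot_accuracy(self):
        p = binomial_accuracy_test(15, 18, 0.9)
        assert p == pytest.approx(0.2662040052, abs=1e-9)
        assert round(p, 2) == 0.27

    def test_full_tail(self):
        assert binomial_accuracy_test(18, 18, 0.9) == 1.0

    def test_zero_successes_closed_form(self):
        assert binomial_accuracy_test(0, 18, 0.9) == pytest.approx(0.1 ** 18)

    def test_direct_summation(self):
        p = binomial_accuracy_test(15, 18, 0.9)
        direct = sum(math.comb(18, k) * 0.9 ** k * 0.1 ** (18 - k)
                     for k in range(16))
        assert p == pytest.approx(direct)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_accuracy_test(19, 18, 0.9)


class TestKruskalWallis:
    def test_identical_groups_null(self):
        H, p = kruskal_wallis([1, 2, 3], [1, 2, 3], [1, 2, 3])
        assert H == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_constant_data_convention(self):
        H, p = kruskal_wallis([5, 5], [5, 5], [5, 5])
        assert (H, p) == (0.0, 1.0)

    def test_separated_groups_hand_value(self):
        H, p = kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert H == pytest.approx(7.2)
        assert p == pytest.approx(1 - sps.chi2.cdf(7.2, df=2))

    def test_ties_match_reference_implementation(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            groups = [rng.integers(0, 5, size=rng.integers(3, 8)).astype(float)
                      for _ in range(3)]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            H, p = kruskal_wallis(*groups)
            ref = sps.kruskal(*groups)
            assert H == pytest.approx(ref.statistic, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3])


class TestConoverHolm:
    def test_identical_groups_all_unity(self):
        df = conover_holm([1, 2, 3], [1, 2, 3], [1, 2, 3])
        assert (df.p_holm == 1.0).all()

    def test_most_separated_pair_smallest_p(self):
        df = conover_holm([1, 2, 3], [4, 5, 6], [7, 8, 9])
        best = df.loc[df.p_holm.idxmin()]
        assert {best.group_a, best.group_b} == {"group1", "group3"}

    def test_two_groups_holm_is_identity(self):
        df = conover_holm([1, 2, 3], [4, 5, 6])
        assert len(df) == 1
        assert df.p_holm.iloc[0] == pytest.approx(df.p_raw.iloc[0])

    def test_holm_never_decreases_and_preserves_order(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            groups = [rng.normal(m, 1, size=6) for m in (0.0, 0.5, 2.0, 3.0)]
            df = conover_holm(*groups)
            assert (df.p_holm >= df.p_raw - 1e-12).all()
            by_raw = df.sort_values("p_raw")
            assert by_raw.p_holm.is_monotonic_increasing


class TestWilcoxon:
    def test_all_ties_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0],
                                 [1.0, 2.0, 3.0, 4.0, 5.0])

    def test_constant_shift_extreme_tail(self):
        a = np.arange(1.0, 11.0)
        assert wilcoxon_signed_rank(a, a - 3.0) == pytest.approx(2 / 1024)

    def test_antisymmetric_differences_null(self):
        a = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0, 4.0, -4.0, 5.0, -5.0])
        assert wilcoxon_signed_rank(a, np.zeros_like(a)) == pytest.approx(1.0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCorrelations:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, rho, r2 = correlations(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert rho == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.linspace(-2, 2, 20)
        r, rho, _ = correlations(x, -x ** 3)
        assert rho == pytest.approx(-1.0)
        assert abs(r) < 1.0

    def test_shuffled_pairs_uncorrelated(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=1000)
        y = rng.permutation(x)
        r, _, _ = correlations(x, y)
        assert abs(r) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlations([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
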