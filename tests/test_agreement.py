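"""Concordance, agreement classes, signed-rank test and summary tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lungqct import (
    classify_agreement,
    compare_algorithms,
    concordance_correlation,
    median_iqr,
    wilcoxon_signed_rank,
)


def brute_force_signed_rank_p(d: np.ndarray) -> float:
    """Exhaustive sign-flip enumeration of the two-sided signed-rank p."""
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    sums = np.array(
        [sum(r for s, r in zip(signs, ranks) if s)
         for signs in itertools.product([0, 1], repeat=d.size)]
    )
    p_le = np.mean(sums <= w + 1e-9)
    p_ge = np.mean(sums >= w - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestConcordanceCorrelation:
    def test_identity_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert concordance_correlation(x, x) == pytest.approx(1.0)

    def test_anticoncordance(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert concordance_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_example_n_denominator(self):
        assert concordance_correlation([1, 2, 3], [2, 2, 4]) == pytest.approx(
            2.0 / 3.0, abs=1e-12
        )

    def test_matches_direct_formula_on_random_pairs(self):
        """Implementation against an independent spelled-out evaluation of
        Lin's moment formula."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x = rng.normal(0, rng.uniform(0.5, 3), n)
            y = x * rng.uniform(0.5, 1.5) + rng.normal(0, 1, n)
            sx2 = ((x - x.mean()) ** 2).sum() / n
            sy2 = ((y - y.mean()) ** 2).sum() / n
            sxy = ((x - x.mean()) * (y - y.mean())).sum() / n
            expected = 2 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)
            assert concordance_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_common_shift_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 20), rng.normal(0.3, 1.2, 20)
        assert concordance_correlation(x, y) == pytest.approx(
            concordance_correlation(y, x), abs=1e-12
        )
        assert concordance_correlation(x + 5, y + 5) == pytest.approx(
            concordance_correlation(x, y), abs=1e-12
        )

    def test_never_exceeds_pearson_magnitude(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x, y = rng.normal(0, 1, 15), rng.normal(1, 2, 15)
            pc = concordance_correlation(x, y)
            r = stats.pearsonr(x, y).statistic
            assert abs(pc) <= abs(r) + 1e-12

    def test_errors(self):
        with pytest.raises(ValueError):
            concordance_correlation([1, 2], [1, 2])
        with pytest.raises(ValueError):
            concordance_correlation([3, 3, 3], [3, 3, 3])


class TestClassifyAgreement:
    @pytest.mark.parametrize(
        "pc,expected",
        [
            (0.89, "poor"),
            (0.90, "moderate"),
            (0.95, "moderate"),
            (0.96, "substantial"),
            (0.99, "substantial"),
            (0.998, "almost perfect"),
            (-0.5, "poor"),
        ],
    )
    def test_scale_boundaries(self, pc, expected):
        assert classify_agreement(pc) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_agreement(1.5)


class TestWilcoxonSignedRank:
    def test_constant_shift_n8(self):
        x = np.arange(8.0)
        res = wilcoxon_signed_rank(x + 3.0, x)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2.0 / 256.0, abs=1e-15)

    def test_identical_series_degenerate(self):
        x = np.arange(6.0)
        res = wilcoxon_signed_rank(x, x)
        assert res.degenerate
        assert res.p_value == 1.0

    def test_exact_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 50:
            n = int(rng.integers(5, 13))
            x = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            d = x - y
            if np.count_nonzero(d) < 5:
                continue
            res = wilcoxon_signed_rank(x, y)
            assert res.p_value == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)
            checked += 1

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(6, 20))
            x = rng.normal(0, 1, n)
            y = x + rng.normal(0.4, 1, n)
            res = wilcoxon_signed_rank(x, y)
            ref = stats.wilcoxon(x, y, mode="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_crossover(self):
        """Just past the exact/approximate switch the two answers agree."""
        from lungqct.agreement import _exact_signed_rank_p

        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 26)
        y = x + rng.normal(0.3, 1, 26)
        res = wilcoxon_signed_rank(x, y)
        assert res.method == "normal"
        d = x - y
        ranks = stats.rankdata(np.abs(d))
        p_exact = _exact_signed_rank_p(ranks, float(ranks[d > 0].sum()))
        assert res.p_value == pytest.approx(p_exact, abs=0.02)

    def test_too_few_nonzero_differences_rejected(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = x.copy()
        y[0] += 1
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(x, y)


class TestMedianIqr:
    def test_hand_example(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)

    def test_constant_and_singleton(self):
        assert median_iqr([7, 7, 7]) == (7.0, 7.0, 7.0)
        assert median_iqr([4.2]) == (4.2, 4.2, 4.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])


class TestCompareAlgorithms:
    @staticmethod
    def _long_frame(values_a, values_b, measures=("m1", "m2")):
        rows = []
        for m in measures:
            for i, (a, b) in enumerate(zip(values_a, values_b)):
                rows.append({"subject": f"S{i}", "recon": "FBP", "measure": m, "value": a})
                rows.append({"subject": f"S{i}", "recon": "IR", "measure": m, "value": b})
        return pd.DataFrame(rows)

    def test_duplicated_cohort_gives_perfect_agreement(self):
        v = np.arange(10.0)
        table, results = compare_algorithms(self._long_frame(v, v))
        assert len(table) == 2
        for r in results:
            assert r.pc == pytest.approx(1.0)
            assert r.wilcoxon_degenerate
            assert r.wilcoxon_p == 1.0

    def test_one_row_per_measure_and_consistency(self):
        rng = np.random.default_rng(5)
        a = rng.normal(10, 2, 12)
        b = a + rng.normal(0.5, 0.5, 12)
        names = [f"m{k}" for k in range(9)]
        table, results = compare_algorithms(self._long_frame(a, b, names))
        assert list(table["measure"]) == names
        assert len(table) == 9
        direct = concordance_correlation(a, b)
        for r in results:
            assert r.pc == pytest.approx(direct, abs=1e-12)
            assert r.n == 12

    def test_unpaired_subjects_dropped(self):
        frame = self._long_frame(np.arange(8.0), np.arange(8.0) + 1, ("m1",))
        frame = frame.drop(frame[(frame.subject == "S0") & (frame.recon == "IR")].index)
        _, results = compare_algorithms(frame)
        assert results[0].n == 7
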