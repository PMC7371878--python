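"""Chi-square group comparison and Holm-Bonferroni correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from fnnm.comparison import (
    ContingencyCounts,
    chi_square_2x2,
    compare_sets,
    contingency_for_set,
    holm_bonferroni,
)
from fnnm.graph_io import NeighborhoodTable

from conftest import random_table


def table_of(rows, candidates):
    m = np.zeros((len(rows), len(candidates)), dtype=bool)
    col = {v: j for j, v in enumerate(candidates)}
    for i, row in enumerate(rows):
        for v in row:
            m[i, col[v]] = True
    return NeighborhoodTable([f"s{i}" for i in range(len(rows))], list(candidates), m)


class TestContingency:
    def test_row_by_row_subset_check(self):
        high = table_of([{"a", "b"}, {"a", "b"}, {"a"}], ["a", "b"])
        low = table_of([{"a"}, {"b"}], ["a", "b"])
        c = contingency_for_set(("a", "b"), high, low)
        assert (c.a, c.b, c.c, c.d) == (2, 1, 0, 2)

    def test_ubiquitous_set_fills_margins(self):
        high = table_of([{"a"}, {"a"}], ["a"])
        low = table_of([{"a"}], ["a"])
        c = contingency_for_set(("a",), high, low)
        assert (c.b, c.d) == (0, 0)

    def test_empty_set_counts_everyone(self):
        high = table_of([{"a"}, set()], ["a"])
        low = table_of([set()], ["a"])
        c = contingency_for_set((), high, low)
        assert (c.a, c.c) == (2, 1)

    def test_empty_group_rejected(self):
        high = table_of([{"a"}], ["a"])
        low = table_of([], ["a"])
        with pytest.raises(ValueError):
            contingency_for_set(("a",), high, low)


class TestChiSquare:
    def test_known_value(self):
        chi2, p = chi_square_2x2(ContingencyCounts(30, 10, 10, 30))
        assert chi2 == pytest.approx(20.0, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(20.0, 1), rel=1e-12)

    def test_equal_proportions_give_zero(self):
        chi2, p = chi_square_2x2(ContingencyCounts(20, 20, 10, 10))
        assert chi2 == 0.0
        assert p == 1.0

    def test_group_label_swap_invariance(self):
        c1, _ = chi_square_2x2(ContingencyCounts(25, 15, 9, 31))
        c2, _ = chi_square_2x2(ContingencyCounts(9, 31, 25, 15))
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_zero_presence_margin_is_null(self):
        assert chi_square_2x2(ContingencyCounts(0, 10, 0, 20)) == (0.0, 1.0)
        assert chi_square_2x2(ContingencyCounts(10, 0, 20, 0)) == (0.0, 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyCounts(-1, 2, 3, 4)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(1, 80, size=4))
        chi2, p = chi_square_2x2(ContingencyCounts(a, b, c, d))
        ref = stats.chi2_contingency([[a, b], [c, d]], correction=False)
        assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_yates_correction_option(self):
        counts = ContingencyCounts(12, 8, 5, 15)
        chi2, p = chi_square_2x2(counts, yates=True)
        ref = stats.chi2_contingency([[12, 8], [5, 15]], correction=True)
        assert chi2 == pytest.approx(ref.statistic, abs=1e-10)


class TestHolm:
    def test_single_test_plain_alpha(self):
        assert holm_bonferroni([0.009], 0.01) == [True]
        assert holm_bonferroni([0.011], 0.01) == [False]

    def test_step_down_thresholds(self):
        # thresholds: 0.01/3, 0.01/2, 0.01 -> third comparison fails
        assert holm_bonferroni([0.001, 0.004, 0.02], 0.01) == [True, True, False]

    def test_stop_at_first_failure(self):
        # rank-2 p (0.006) fails its threshold 0.01/2, so the rank-3 p
        # (0.009 <= 0.01) is not even considered
        assert holm_bonferroni([0.009, 0.001, 0.006], 0.01) == [False, True, False]

    def test_all_ones_reject_nothing(self):
        assert holm_bonferroni([1.0] * 5, 0.01) == [False] * 5

    def test_empty_list(self):
        assert holm_bonferroni([], 0.01) == []

    def test_decisions_in_input_order(self):
        p = [0.5, 0.0001, 0.9, 0.002]
        out = holm_bonferroni(p, 0.01)
        assert out == [False, True, False, True]

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_between_bonferroni_and_uncorrected(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 40))
        p = rng.uniform(0, 1, m) ** 2  # skew toward small values
        alpha = 0.05
        holm = np.array(holm_bonferroni(list(p), alpha))
        bonf = p <= alpha / m
        assert np.all(holm[bonf])           # Holm rejects whatever Bonferroni does
        assert np.all(p[holm] <= alpha)     # and never an uncorrected-acceptable p

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, int(rng.integers(1, 30))) ** 3
        ours = holm_bonferroni(list(p), 0.01)
        ref = multipletests(p, alpha=0.01, method="holm")[0]
        assert ours == ref.tolist()


class TestCompareSets:
    def test_equal_frequencies_not_significant(self):
        high = table_of([{"a"}, {"a"}, set(), set()], ["a"])
        low = table_of([{"a"}, set()], ["a"])
        (res,) = compare_sets([("a",)], high, low, alpha=0.01)
        assert not res.significant and res.direction is None

    def test_planted_difference_flagged_good(self):
        rng = np.random.default_rng(11)
        high = table_of(
            [{"a"} if rng.random() < 0.95 else set() for _ in range(200)], ["a"]
        )
        low = table_of(
            [{"a"} if rng.random() < 0.55 else set() for _ in range(200)], ["a"]
        )
        (res,) = compare_sets([("a",)], high, low, alpha=0.01)
        assert res.significant and res.direction == "good"
        assert res.chi2 > 6.635  # 1-df critical value at alpha = 0.01

    def test_direction_partition_identity(self):
        rng = np.random.default_rng(23)
        high = random_table(rng, 80, 6, density=0.9)
        low = random_table(rng, 80, 6, density=0.5)
        cands = [(v,) for v in high.candidate_nodes]
        results = compare_sets(cands, high, low, alpha=0.05)
        n_sig = sum(r.significant for r in results)
        n_good = sum(r.significant and r.direction == "good" for r in results)
        n_bad = sum(r.significant and r.direction == "bad" for r in results)
        assert n_good + n_bad == n_sig

    def test_duplicate_candidates_rejected(self):
        high = table_of([{"a"}], ["a"])
        low = table_of([{"a"}], ["a"])
        with pytest.raises(ValueError, match="duplicate"):
            compare_sets([("a",), ("a",)], high, low, alpha=0.01)

    def test_empty_family_rejected(self):
        high = table_of([{"a"}], ["a"])
        with pytest.raises(ValueError, match="empty"):
            compare_sets([], high, high, alpha=0.01)
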