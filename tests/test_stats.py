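"""Non-parametric tests: hand-checked statistics, oracles and null calibration."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taxid_eval import stats
from taxid_eval.datamodel import ValidationError


def kruskal_oracle(groups):
    """Independent transcription of the H formula (no tie correction).

    H = 12 / (N (N + 1)) * sum(R_i^2 / n_i) - 3 (N + 1), computed from
    first principles with naive average ranks.
    """
    pooled = sorted((v, i) for i, g in enumerate(groups) for v in g)
    n_total = len(pooled)
    ranks = {}
    k = 0
    while k < n_total:
        j = k
        while j < n_total and pooled[j][0] == pooled[k][0]:
            j += 1
        avg = (k + 1 + j) / 2.0
        for idx in range(k, j):
            ranks.setdefault(idx, avg)
        k = j
    sums = [0.0] * len(groups)
    for idx, (_, gi) in enumerate(pooled):
        sums[gi] += ranks[idx]
    h = 12.0 / (n_total * (n_total + 1)) * sum(
        s * s / len(g) for s, g in zip(sums, groups)
    ) - 3 * (n_total + 1)
    return h


class TestKruskalWallis:
    def test_hand_computed_two_groups(self):
        h, p = stats.kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(3.857, abs=0.001)
        assert h == pytest.approx(kruskal_oracle([[1, 2, 3], [4, 5, 6]]))

    def test_identical_groups_are_fully_tied(self):
        h, p = stats.kruskal_wallis([[5, 5, 5], [5, 5, 5]])
        assert h == 0.0 and p == 1.0

    def test_empty_group_raises(self):
        with pytest.raises(ValidationError):
            stats.kruskal_wallis([[1, 2], []])

    def test_type_one_error_rate_under_null(self):
        """Three same-distribution groups reject at about the nominal rate."""
        rng = np.random.default_rng(20240917)
        n_sims, alpha = 4000, 0.05
        rejections = 0
        for _ in range(n_sims):
            groups = rng.normal(size=(3, 10))
            _, p = stats.kruskal_wallis(list(groups))
            rejections += p < alpha
        rate = rejections / n_sims
        se = np.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(rate - alpha) < 3 * se + 0.005  # KW is slightly conservative


class TestDunnLetters:
    def test_well_separated_groups_get_distinct_letters(self):
        groups = [[1, 2, 3] * 10, [50, 51, 52] * 10, [100, 101, 102] * 10]
        letters = stats.pairwise_letters(groups, ["lo", "mid", "hi"])
        assert len({letters["lo"], letters["mid"], letters["hi"]}) == 3
        assert letters["lo"] == "a"

    def test_overlapping_chain_shares_middle_letter(self):
        """A ~ B and B ~ C but A != C yields the classic a / ab / b display."""
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 30)
        b = rng.normal(0.5, 1.0, 30)
        c = rng.normal(1.0, 1.0, 30)
        pmat = stats.dunn_pairwise([a, b, c], ["A", "B", "C"])
        # engineered configuration: verify the sharing relation, then letters
        assert pmat.loc["A", "C"] < 0.05 <= min(pmat.loc["A", "B"], pmat.loc["B", "C"])
        letters = stats.assign_letters(pmat, 0.05)
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_identical_groups_share_one_letter(self):
        groups = [[1, 2, 3], [1, 2, 3], [1, 2, 3]]
        letters = stats.pairwise_letters(groups)
        assert set(letters.values()) == {"a"}

    def test_single_group_gets_letter_a(self):
        assert stats.pairwise_letters([[1, 2, 3]], ["only"]) == {"only": "a"}

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_letter_sharing_matches_adjusted_p_matrix(self, data):
        """Sharing a letter <=> adjusted p >= alpha, on arbitrary p matrices."""
        k = data.draw(st.integers(min_value=2, max_value=7))
        labels = [f"g{i}" for i in range(k)]
        mat = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
        for i, j in itertools.combinations(range(k), 2):
            p = data.draw(st.sampled_from([0.001, 0.03, 0.2, 1.0]))
            mat.iat[i, j] = mat.iat[j, i] = p
        letters = stats.assign_letters(mat, alpha=0.05)
        for a, b in itertools.combinations(labels, 2):
            shares = bool(set(letters[a]) & set(letters[b]))
            assert shares == (mat.loc[a, b] >= 0.05), (letters, mat.values)


class TestNMinus1Chi2:
    def test_hand_computed_value(self):
        stat, p = stats.n_minus_1_chi2(30, 50, 20, 50)
        assert stat == pytest.approx(3.96)

    def test_equal_proportions_give_zero(self):
        stat, _ = stats.n_minus_1_chi2(10, 20, 20, 40)
        assert stat == pytest.approx(0.0)

    def test_row_swap_symmetry(self):
        s1, _ = stats.n_minus_1_chi2(7, 19, 3, 11)
        s2, _ = stats.n_minus_1_chi2(3, 11, 7, 19)
        assert s1 == pytest.approx(s2)

    def test_degenerate_margins(self):
        assert stats.n_minus_1_chi2(5, 5, 3, 3) == (0.0, 1.0)
        assert stats.n_minus_1_chi2(0, 5, 0, 3) == (0.0, 1.0)

    def test_matches_scaled_pearson_on_exhaustive_small_tables(self):
        """(n-1) statistic == (N-1)/N x independently computed Pearson chi2."""
        import scipy.stats

        for n1 in range(1, 13):
            for n2 in range(1, 13):
                for a in range(n1 + 1):
                    for b in range(n2 + 1):
                        stat, _ = stats.n_minus_1_chi2(a, n1, b, n2)
                        table = np.array([[a, n1 - a], [b, n2 - b]])
                        if table.sum(axis=0).min() == 0:
                            assert stat == 0.0
                            continue
                        pearson = scipy.stats.chi2_contingency(table, correction=False)[0]
                        n_total = n1 + n2
                        assert stat == pytest.approx((n_total - 1) / n_total * pearson)


def brute_force_w(matrix):
    """Direct evaluation of the concordance formula, written independently."""
    matrix = np.asarray(matrix, float)
    m, n = matrix.shape
    col_sums = matrix.sum(axis=0)
    s = ((col_sums - col_sums.mean()) ** 2).sum()
    ties = 0.0
    for row in matrix:
        for v in set(row):
            t = (row == v).sum()
            ties += t**3 - t
    return 12 * s / (m * m * (n**3 - n) - m * ties)


class TestKendallW:
    def test_identical_rankings_reach_one(self):
        matrix = [[1, 2, 3, 4]] * 5
        res = stats.kendall_w(matrix)
        assert res.W == pytest.approx(1.0)
        assert res.chi2 == pytest.approx(res.m * (res.n - 1))

    def test_two_reversed_rankings(self):
        matrix = [[1, 2, 3], [3, 2, 1]]
        res = stats.kendall_w(matrix)
        assert res.W == pytest.approx(brute_force_w(matrix))
        assert res.W == pytest.approx(0.0)

    def test_matches_brute_force_with_ties(self):
        matrix = [[1.5, 1.5, 3, 4], [2, 1, 3.5, 3.5], [1, 2, 3, 4]]
        res = stats.kendall_w(matrix)
        assert res.W == pytest.approx(brute_force_w(matrix))

    def test_invariant_to_object_relabeling_and_judge_order(self):
        rng = np.random.default_rng(3)
        matrix = np.array([rng.permutation(6) + 1 for _ in range(4)], float)
        base = stats.kendall_w(matrix).W
        perm = rng.permutation(6)
        assert stats.kendall_w(matrix[:, perm]).W == pytest.approx(base)
        assert stats.kendall_w(matrix[::-1]).W == pytest.approx(base)

    def test_rejects_non_rankings(self):
        with pytest.raises(ValidationError):
            stats.kendall_w([[1, 1, 1], [1, 2, 3]])
        with pytest.raises(ValidationError):
            stats.kendall_w([[1, 2, 3]])
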