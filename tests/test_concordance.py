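"""Rater agreement, effect sizes and correlation significance tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpmkit.concordance import (
    RaterPair,
    cohens_d,
    concordance_rate,
    confidence_agreement,
    pearson_test,
    pearson_test_from_data,
    read_pairs_csv,
    spearman_test,
)
from dpmkit.core import ConfidenceLevel, DomainError


def pair(resident, expert, concordant=True, case_id="c"):
    return RaterPair(case_id, ConfidenceLevel(resident), ConfidenceLevel(expert), concordant)


class TestConcordanceRate:
    def test_all_and_none(self):
        assert concordance_rate([pair(4, 4, True)] * 3) == 1.0
        assert concordance_rate([pair(4, 4, False)] * 3) == 0.0

    def test_51_of_55(self):
        pairs = [pair(4, 4, i < 51, case_id=str(i)) for i in range(55)]
        assert concordance_rate(pairs) == pytest.approx(0.927, abs=0.001)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            concordance_rate([])


class TestConfidenceAgreement:
    def test_identical_ratings(self):
        summary = confidence_agreement([pair(3, 3), pair(-1, -1)])
        assert summary.perfect_match_pct == 100.0
        assert summary.max_discrepancy == 0

    def test_hand_enumerated_mixture(self):
        # (resident, expert): (4,3) under by 1; (4,4) perfect; (2,4) over by 2
        summary = confidence_agreement([pair(4, 3), pair(4, 4), pair(2, 4)])
        assert summary.perfect_match_pct == pytest.approx(100 / 3)
        assert summary.expert_underconfident_pct == pytest.approx(100 / 3)
        assert summary.expert_overconfident_pct == pytest.approx(100 / 3)
        assert summary.max_discrepancy == 2

    def test_two_step_gap_not_within_one(self):
        summary = confidence_agreement([pair(4, 2)])
        assert summary.within_one_pct == 0.0
        assert summary.farther_pct == 100.0

    def test_shares_sum_to_100(self):
        rng = np.random.default_rng(5)
        pairs = [pair(int(rng.integers(-4, 5)), int(rng.integers(-4, 5))) for _ in range(40)]
        s = confidence_agreement(pairs)
        assert s.perfect_match_pct + s.within_one_pct + s.farther_pct == pytest.approx(100.0)


class TestCohensD:
    def test_published_group_summaries(self):
        # residents 3.5 (SD 0.7) vs expert 3.1 (SD 0.8), 51 cases per group
        effect = cohens_d(3.5, 0.7, 51, 3.1, 0.8, 51)
        assert round(effect.d, 2) == 0.53
        assert effect.ci_low <= effect.d <= effect.ci_high

    def test_equal_means_give_zero(self):
        assert cohens_d(2.0, 1.0, 5, 2.0, 1.5, 5).d == 0.0

    def test_unit_pooled_sd(self):
        assert cohens_d(1.0, 1.0, 10, 0.0, 1.0, 10).d == pytest.approx(1.0)

    def test_zero_pooled_sd_with_unequal_means_is_undefined(self):
        with pytest.raises(DomainError):
            cohens_d(1.0, 0.0, 5, 0.0, 0.0, 5)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        m1=st.floats(-5, 5),
        m2=st.floats(-5, 5),
        s1=st.floats(0.1, 3),
        s2=st.floats(0.1, 3),
        n1=st.integers(2, 60),
        n2=st.integers(2, 60),
    )
    def test_antisymmetry(self, m1, m2, s1, s2, n1, n2):
        a = cohens_d(m1, s1, n1, m2, s2, n2)
        b = cohens_d(m2, s2, n2, m1, s1, n1)
        assert a.d == pytest.approx(-b.d)
        assert a.ci_low == pytest.approx(-b.ci_high)


class TestPearson:
    def test_published_experience_correlation(self):
        result = pearson_test(-0.35, 55)
        assert round(result.p, 3) == 0.009

    def test_zero_correlation_has_p_one(self):
        assert pearson_test(0.0, 20).p == pytest.approx(1.0)

    def test_perfect_correlation_flagged(self):
        result = pearson_test(1.0, 10)
        assert result.p == 0.0 and result.approximate

    def test_p_monotone_in_coefficient_and_n(self):
        ps = [pearson_test(r, 30).p for r in (0.1, 0.3, 0.5, 0.7)]
        assert ps == sorted(ps, reverse=True)
        pn = [pearson_test(0.4, n).p for n in (10, 20, 40, 80)]
        assert pn == sorted(pn, reverse=True)

    def test_from_data_matches_summary_form(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        result = pearson_test_from_data(x, y)
        assert result.p == pytest.approx(pearson_test(result.coefficient, 30).p)
        # scipy as an independent cross-check of the t transform
        from scipy.stats import pearsonr

        ref = pearsonr(x, y)
        assert result.coefficient == pytest.approx(ref.statistic)
        assert result.p == pytest.approx(ref.pvalue)


class TestSpearman:
    def test_monotone_data(self):
        assert spearman_test([1, 2, 3, 4], [10, 20, 30, 40]).coefficient == 1.0
        assert spearman_test([1, 2, 3, 4], [4, 3, 2, 1]).coefficient == -1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(DomainError):
            spearman_test([1, 1, 1, 1], [1, 2, 3, 4])

    def test_midranks_for_ties_match_scipy(self):
        from scipy.stats import spearmanr

        x = [1, 2, 2, 3, 5, 5, 7]
        y = [2, 1, 4, 4, 6, 5, 7]
        ours = spearman_test(x, y)
        ref = spearmanr(x, y)
        assert ours.coefficient == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue)


def exhaustive_permutation_p(x, y, rank_based=False):
    """Exact two-sided permutation p-value of the correlation coefficient."""
    from scipy.stats import rankdata

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if rank_based:
        x, y = rankdata(x), rankdata(y)
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    hits = total = 0
    for perm in itertools.permutations(y):
        hits += abs(np.corrcoef(x, perm)[0, 1]) >= r_obs - 1e-12
        total += 1
    return hits / total


class TestPermutationOracle:
    """The t-transform p-values against exact enumeration at n <= 7.

    Expected oracle values were computed once by exhaustive enumeration
    (720 resp. 5040 permutations) and frozen; the t approximation is
    required to agree within 0.05 absolute, the deviation band observed
    for these sample sizes.
    """

    CASES = [
        # (x, y, frozen exact pearson p, frozen exact spearman p)
        ([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5], 42 / 720, 42 / 720),
        ([1, 2, 3, 4, 5, 6, 7], [1, 3, 2, 5, 4, 7, 6], 62 / 5040, 62 / 5040),
        ([3, 1, 4, 1, 5, 9, 2], [2, 7, 1, 8, 2, 8, 1], 4432 / 5040, 4320 / 5040),
    ]

    @pytest.mark.parametrize("x,y,exact_pearson,exact_spearman", CASES)
    def test_oracle_reproduces_frozen_values(self, x, y, exact_pearson, exact_spearman):
        assert exhaustive_permutation_p(x, y) == pytest.approx(exact_pearson)
        assert exhaustive_permutation_p(x, y, rank_based=True) == pytest.approx(exact_spearman)

    @pytest.mark.parametrize("x,y,exact_pearson,exact_spearman", CASES)
    def test_t_transform_close_to_exact(self, x, y, exact_pearson, exact_spearman):
        assert pearson_test_from_data(x, y).p == pytest.approx(exact_pearson, abs=0.05)
        assert spearman_test(x, y).p == pytest.approx(exact_spearman, abs=0.05)


def test_pairs_csv_loader(tmp_path):
    path = tmp_path / "pairs.csv"
    path.write_text(
        "case_id,resident_level,expert_level,concordant\n"
        "a,4,3,true\n"
        "b,2,2,false\n",
        encoding="utf-8",
    )
    pairs = read_pairs_csv(path)
    assert len(pairs) == 2
    assert pairs[0].resident_final_confidence.value == 4
    assert not pairs[1].diagnosis_concordant
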