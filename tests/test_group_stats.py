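import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from saltphen.stats import (
    compact_letter_display,
    fisher_exact_2x2,
    fisher_lsd,
    one_way_anova,
)


class TestAnova:
    def test_identical_groups(self):
        res = one_way_anova({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_sums_of_squares(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res.ss_between == pytest.approx(13.5)
        assert res.ss_within == pytest.approx(4.0)
        assert res.f_statistic == pytest.approx(13.5)
        assert res.df_between == 1 and res.df_within == 4

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        groups = {f"g{i}": rng.normal(i * 0.3, 1, size=6).tolist() for i in range(4)}
        res = one_way_anova(groups)
        f, p = sps.f_oneway(*groups.values())
        assert res.f_statistic == pytest.approx(f)
        assert res.p_value == pytest.approx(p)

    def test_null_p_values_are_uniform(self):
        """Under H0 the ANOVA p-value is Uniform(0,1): K-S check over replicates."""
        rng = np.random.default_rng(42)
        pvals = [
            one_way_anova(
                {g: rng.normal(0, 1, size=5).tolist() for g in "abc"}
            ).p_value
            for _ in range(500)
        ]
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_underpowered_level_rejected(self):
        with pytest.raises(ValueError, match="single"):
            one_way_anova({"single": [1.0], "b": [1.0, 2.0]})


class TestFisherLsd:
    def test_identical_groups_have_no_significant_pairs(self):
        res = fisher_lsd({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert not any(res.significant.values())
        assert set(res.letters.values()) == {"a"}

    def test_two_groups_match_pooled_t_test(self):
        """With two equal-n groups the LSD decision equals a pooled-variance
        two-sample t-test at the same alpha (F = t^2 makes protection moot)."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = rng.integers(3, 8)
            shift = rng.normal(0, 1.5)
            x = rng.normal(0, 1, n)
            y = rng.normal(shift, 1, n)
            res = fisher_lsd({"x": x.tolist(), "y": y.tolist()}, alpha=0.05)
            t_p = sps.ttest_ind(x, y, equal_var=True).pvalue
            assert res.is_significant("x", "y") == (t_p < 0.05)

    def test_outlier_group_is_the_only_significant_one(self):
        groups = {
            "a": [10.0, 10.1, 9.9],
            "b": [10.2, 10.0, 10.1],
            "c": [20.0, 20.1, 19.9],
        }
        res = fisher_lsd(groups)
        assert res.is_significant("a", "c") and res.is_significant("b", "c")
        assert not res.is_significant("a", "b")
        # hand check of the threshold: t(0.975, 6) * sqrt(MSE * 2/3)
        t_crit = sps.t.ppf(0.975, res.anova.df_within)
        assert res.lsd_value == pytest.approx(
            t_crit * math.sqrt(res.anova.ms_error * (2 / 3))
        )

    def test_protected_gate_blocks_pairwise_calls(self):
        rng = np.random.default_rng(3)
        groups = {g: rng.normal(0, 1, 4).tolist() for g in "abcd"}
        protected = fisher_lsd(groups, protected=True)
        if protected.anova.p_value > 0.05:
            assert not any(protected.significant.values())
        unprotected = fisher_lsd(groups, protected=False)
        assert all(
            unprotected.significant[k] or not protected.significant[k]
            for k in protected.significant
        )

    def test_unprotected_null_pair_rate_near_alpha(self):
        """Unprotected LSD per-comparison false-positive rate ≈ alpha."""
        rng = np.random.default_rng(11)
        hits = trials = 0
        for _ in range(400):
            groups = {g: rng.normal(0, 1, 3).tolist() for g in "abc"}
            res = fisher_lsd(groups, protected=False)
            hits += sum(res.significant.values())
            trials += len(res.significant)
        rate = hits / trials
        assert 0.02 < rate < 0.09


class TestCompactLetterDisplay:
    def test_all_same(self):
        letters = compact_letter_display({"a": 1.0, "b": 1.1}, lambda x, y: False)
        assert letters == {"a": "a", "b": "a"}

    def test_all_different_in_mean_order(self):
        means = {"low": 1.0, "mid": 2.0, "high": 3.0}
        letters = compact_letter_display(means, lambda x, y: True)
        assert letters == {"high": "a", "mid": "b", "low": "c"}

    def test_chain_case(self):
        """A~B, B~C but A≠C needs the bridging 'ab' letter set."""
        means = {"A": 3.0, "B": 2.0, "C": 1.0}
        sig = lambda x, y: {x, y} == {"A", "C"}
        letters = compact_letter_display(means, sig)
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_asymmetric_matrix_rejected(self):
        matrix = {"a": {"b": True}, "b": {"a": False}}
        with pytest.raises(ValueError, match="symmetric"):
            compact_letter_display({"a": 1.0, "b": 2.0}, matrix)

    def test_share_letter_iff_not_significant_on_random_patterns(self):
        """Exhaustive check of the defining CLD property over random patterns."""
        rng = np.random.default_rng(5)
        levels = ["g1", "g2", "g3", "g4", "g5"]
        means = {g: float(i) for i, g in enumerate(levels)}
        for _ in range(50):
            sig_pairs = {
                frozenset(p)
                for p in itertools.combinations(levels, 2)
                if rng.random() < 0.4
            }
            letters = compact_letter_display(
                means, lambda x, y: frozenset((x, y)) in sig_pairs
            )
            for x, y in itertools.combinations(levels, 2):
                share = bool(set(letters[x]) & set(letters[y]))
                assert share != (frozenset((x, y)) in sig_pairs), (
                    f"pair {x},{y}: letters {letters}, sig={sig_pairs}"
                )


def _fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration with exact rational arithmetic."""
    from fractions import Fraction

    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = math.comb(n, c1)
    k_lo, k_hi = max(0, c1 - (c + d)), min(r1, c1)
    probs = {
        k: Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)
        for k in range(k_lo, k_hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFisherExact:
    def test_degenerate_margin(self):
        assert fisher_exact_2x2(0, 0, 3, 7) == 1.0

    def test_diagonal_table_enumeration(self):
        assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / math.comb(10, 5), rel=1e-12)

    def test_matches_exact_enumeration_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 9, size=4))
            if a + b + c + d == 0:
                continue
            ours = fisher_exact_2x2(a, b, c, d)
            oracle = _fisher_two_sided_oracle(a, b, c, d)
            assert ours == pytest.approx(oracle, rel=1e-7)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            _, p_ref = sps.fisher_exact([[a, b], [c, d]])
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(p_ref, rel=1e-6)

    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
    def test_invariance_under_row_and_column_swap(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_2x2(a, b, c, d)
        assert 0 < p <= 1
        assert fisher_exact_2x2(d, c, b, a) == pytest.approx(p, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)
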