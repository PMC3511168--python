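"""Shannon expression breadth and the Mann–Whitney rank-sum test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from snoleca.expression import (
    Sided,
    compare_host_vs_nonhost,
    expression_entropy,
    median_signal,
    rank_sum_test,
)


class TestEntropy:
    @pytest.mark.parametrize("k", [2, 3, 10, 50])
    def test_uniform_is_ln_k(self, k):
        assert expression_entropy([1.0] * k) == pytest.approx(math.log(k), abs=1e-12)

    def test_single_tissue_is_zero(self):
        assert expression_entropy([0, 5.0, 0]) == 0.0

    def test_two_one_one(self):
        # -(1/2 ln 1/2 + 2 * 1/4 ln 1/4) = 3/2 ln 2
        assert expression_entropy([2, 1, 1]) == pytest.approx(1.5 * math.log(2))

    @pytest.mark.parametrize("c", [0.1, 1.0, 10.0])
    def test_scale_invariance(self, c, rng):
        e = rng.random(8) + 0.01
        assert expression_entropy(c * e) == pytest.approx(expression_entropy(e))

    def test_bounds(self, rng):
        for _ in range(50):
            e = rng.random(int(rng.integers(1, 12))) * rng.random()
            if e.sum() == 0:
                continue
            s = expression_entropy(e)
            assert -1e-12 <= s <= math.log(len(e)) + 1e-12

    def test_errors(self):
        with pytest.raises(ValueError):
            expression_entropy([0.0, 0.0])
        with pytest.raises(ValueError):
            expression_entropy([1.0, -0.5])

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1e6), min_size=1, max_size=15).filter(
            lambda e: sum(e) > 0
        )
    )
    def test_bounds_property(self, e):
        s = expression_entropy(e)
        assert -1e-9 <= s <= math.log(len(e)) + 1e-9


class TestMedianSignal:
    def test_plain_median(self):
        s = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        assert median_signal(s) == 2.0

    def test_duplicate_collapse(self):
        s = pd.Series([4.0, 6.0, 1.0, 9.0], index=["br1", "br2", "x", "y"])
        dup = {"br1": "brain", "br2": "brain"}
        assert median_signal(s, dup) == 5.0  # median of (5, 1, 9)

    def test_identity_map_idempotent(self):
        s = pd.Series([3.0, 1.0, 7.0], index=list("abc"))
        assert median_signal(s, {t: t for t in s.index}) == median_signal(s)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_signal(pd.Series(dtype=float))


def exact_p_enumeration(a, b, sided):
    """Oracle: enumerate all C(n, n1) group assignments explicitly."""
    combined = list(a) + list(b)
    n1 = len(a)
    order = sorted(range(len(combined)), key=lambda i: combined[i])
    ranks = [0.0] * len(combined)
    i = 0
    vals = sorted(combined)
    # midranks
    pos = {}
    for v in set(combined):
        idxs = [k + 1 for k, x in enumerate(vals) if x == v]
        pos[v] = sum(idxs) / len(idxs)
    u_obs = sum(pos[x] for x in a) - n1 * (n1 + 1) / 2
    n2 = len(b)
    mid = n1 * n2 / 2
    count = total = 0
    for subset in itertools.combinations(range(len(combined)), n1):
        u = sum(pos[combined[i]] for i in subset) - n1 * (n1 + 1) / 2
        total += 1
        if sided is Sided.GREATER:
            count += u >= u_obs - 1e-9
        elif sided is Sided.LESS:
            count += u <= u_obs + 1e-9
        else:
            count += abs(u - mid) >= abs(u_obs - mid) - 1e-9
    return count / total


class TestRankSum:
    def test_identical_multisets(self):
        r = rank_sum_test([1, 2, 3], [1, 2, 3], Sided.TWO_SIDED)
        assert r.u_statistic == pytest.approx(4.5)
        assert r.p_value == pytest.approx(1.0)

    def test_textbook_one_sided(self):
        r = rank_sum_test([1, 2], [3, 4], Sided.LESS)
        assert r.u_statistic == 0
        assert r.p_value == pytest.approx(1 / 6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    @pytest.mark.parametrize("sided", list(Sided))
    def test_exact_matches_enumeration_small_groups(self, sided, rng):
        """All n1, n2 ≤ 5 on integer draws with ties: the DP null
        distribution equals the explicit combination enumeration."""
        for n1 in range(1, 6):
            for n2 in range(1, 6):
                a = rng.integers(0, 6, size=n1).tolist()
                b = rng.integers(0, 6, size=n2).tolist()
                r = rank_sum_test(a, b, sided)
                assert r.exact
                assert r.p_value == pytest.approx(exact_p_enumeration(a, b, sided), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(10):
            a = rng.random(6).tolist()
            b = rng.random(5).tolist()
            r = rank_sum_test(a, b, Sided.TWO_SIDED)
            ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert r.u_statistic == pytest.approx(ref.statistic)
            assert r.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact(self, rng):
        a = rng.normal(0, 1, size=15).tolist()
        b = rng.normal(0.4, 1, size=15).tolist()
        exact = rank_sum_test(a, b, Sided.GREATER, exact_limit=1000)
        approx = rank_sum_test(a, b, Sided.GREATER, exact_limit=0)
        assert not approx.exact and exact.exact
        assert abs(exact.p_value - approx.p_value) < 0.01


class TestHostComparison:
    def matrix(self, host_rows, nonhost_rows, k=4):
        rows = {}
        for i, r in enumerate(host_rows):
            rows[f"h{i}"] = r
        for i, r in enumerate(nonhost_rows):
            rows[f"n{i}"] = r
        return pd.DataFrame.from_dict(rows, orient="index", columns=[f"T{j}" for j in range(k)])

    def test_complete_separation(self):
        host = [[1, 1, 1, 1]] * 8
        non = [[4, 0, 0, 0]] * 8
        m = self.matrix(host, non)
        out = compare_host_vs_nonhost(m, {f"h{i}" for i in range(8)})
        assert out["host_median_entropy"] == pytest.approx(math.log(4))
        assert out["nonhost_median_entropy"] == 0.0
        assert out["rank_sum"].p_value < 1e-3

    def test_identical_profiles_p_one(self):
        m = self.matrix([[1, 2, 3, 4]] * 5, [[1, 2, 3, 4]] * 5)
        out = compare_host_vs_nonhost(m, {f"h{i}" for i in range(5)})
        assert out["rank_sum"].p_value == pytest.approx(1.0)

    def test_empty_host_set_rejected(self):
        m = self.matrix([[1, 1, 1, 1]], [[1, 0, 0, 0]])
        with pytest.raises(ValueError):
            compare_host_vs_nonhost(m, set())
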