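import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from dyadkit.stats import (cohen_kappa, correlation_matrix, holm_adjust,
                           permutation_group_compare, wilcoxon_rank_sum,
                           wilcoxon_signed_rank)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_signed_rank_p(diffs, sidedness="two-sided"):
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([False, True], repeat=len(d))]
    total = len(ws)
    ge = sum(w >= w_obs - 1e-9 for w in ws) / total
    le = sum(w <= w_obs + 1e-9 for w in ws) / total
    if sidedness == "greater":
        return ge
    if sidedness == "less":
        return le
    return min(1.0, 2 * min(ge, le))


def brute_rank_sum_p(x, y):
    x, y = list(x), list(y)
    pooled = x + y
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        r = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        us.append(r)
    total = len(us)
    ge = sum(u >= u_obs - 1e-9 for u in us) / total
    le = sum(u <= u_obs + 1e-9 for u in us) / total
    return min(1.0, 2 * min(ge, le))


# ---------------------------------------------------------------------------
# Wilcoxon tests
# ---------------------------------------------------------------------------

class TestSignedRank:
    def test_hand_example_one_sided(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], sidedness="greater")
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(0.125)

    def test_symmetric_pair_p_one(self):
        res = wilcoxon_signed_rank([2.0, -2.0])
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.integers(min_value=-9, max_value=9).filter(bool),
                    min_size=1, max_size=8))
    def test_exact_matches_brute_force(self, diffs):
        res = wilcoxon_signed_rank([float(d) for d in diffs])
        assert res.p_value == pytest.approx(brute_signed_rank_p(diffs))

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(20):
            d = rng.permutation(np.arange(1, 13))[:10] * \
                rng.choice([-1, 1], 10)
            ours = wilcoxon_signed_rank(d.astype(float))
            ref = sps.wilcoxon(d, mode="exact")
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_normal_approx_close_to_exact_at_n30(self, rng):
        d = rng.normal(0.3, 1.0, 30)
        approx = wilcoxon_signed_rank(d, exact_max_n=25)
        exact = wilcoxon_signed_rank(d, exact_max_n=40)
        assert approx.p_value == pytest.approx(exact.p_value, abs=0.02)


class TestRankSum:
    def test_hand_example(self):
        res = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_exact_matches_brute_force(self, data):
        n1 = data.draw(st.integers(2, 6))
        n2 = data.draw(st.integers(2, 6))
        vals = data.draw(st.permutations(range(20)))
        x = [float(v) for v in vals[:n1]]
        y = [float(v) for v in vals[n1:n1 + n2]]
        res = wilcoxon_rank_sum(x, y)
        assert res.p_value == pytest.approx(brute_rank_sum_p(x, y))

    def test_exact_matches_scipy(self, rng):
        for _ in range(20):
            vals = rng.permutation(np.arange(30, dtype=float))
            x, y = vals[:6], vals[6:14]
            ours = wilcoxon_rank_sum(list(x), list(y))
            ref = sps.mannwhitneyu(x, y, method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_shift_alternative_detected(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(3, 1, 30)
        assert wilcoxon_rank_sum(x, y).p_value < 1e-6


# ---------------------------------------------------------------------------
# correlations and adjustment
# ---------------------------------------------------------------------------

class TestCorrelationMatrix:
    def _table(self, rng, n=40):
        x = rng.normal(size=n)
        return pd.DataFrame({
            "a": x, "b": 0.6 * x + rng.normal(size=n),
            "c": rng.normal(size=n)})

    def test_diagonal_and_symmetry(self, rng):
        cm = correlation_matrix(self._table(rng))
        assert np.allclose(np.diag(cm.r), 1.0)
        assert np.allclose(cm.r, cm.r.T)

    def test_spearman_equals_pearson_on_ranks(self, rng):
        t = self._table(rng)
        cm = correlation_matrix(t, method="spearman")
        ref = sps.spearmanr(t["a"], t["b"]).statistic
        assert cm.r.loc["a", "b"] == pytest.approx(ref)

    def test_adjusted_p_not_below_raw(self, rng):
        cm = correlation_matrix(self._table(rng), adjust="holm")
        iu = np.triu_indices(3, 1)
        assert np.all(cm.p_adj.values[iu] >= cm.p_raw.values[iu] - 1e-15)

    def test_constant_column_flagged(self, rng):
        t = self._table(rng)
        t["d"] = 1.0
        cm = correlation_matrix(t)
        assert "d" in cm.flagged
        assert math.isnan(cm.r.loc["a", "d"])

    def test_holm_hand_example(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_holm_matches_manual_step_down(self, rng):
        p = rng.uniform(size=6)
        order = np.argsort(p)
        manual = np.empty_like(p)
        running = 0.0
        for k, i in enumerate(order):
            running = max(running, (6 - k) * p[i])
            manual[i] = min(1.0, running)
        assert holm_adjust(p) == pytest.approx(list(manual))


# ---------------------------------------------------------------------------
# kappa
# ---------------------------------------------------------------------------

class TestKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(list("aabb"), list("aabb")) == pytest.approx(1.0)

    def test_hand_2x2(self):
        a = ["x"] * 25 + ["y"] * 25
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
        assert cohen_kappa(a, b) == pytest.approx(0.4)

    def test_independent_labels_near_zero(self, rng):
        ks = []
        for _ in range(200):
            a = rng.choice(["p", "q"], 50)
            b = rng.choice(["p", "q"], 50)
            ks.append(cohen_kappa(a, b))
        assert abs(np.mean(ks)) < 0.05

    def test_single_shared_category_undefined(self):
        with pytest.raises(ValueError):
            cohen_kappa(["a", "a"], ["a", "a"])


# ---------------------------------------------------------------------------
# cluster permutation test
# ---------------------------------------------------------------------------

class TestPermutation:
    def _data(self, rng, shift=0.0, n_clusters=15, per=3):
        metric, lab, cid = [], [], []
        for g, gname in enumerate(["a", "b"]):
            for c in range(n_clusters):
                mu = rng.normal(g * shift, 0.5)
                for _ in range(per):
                    metric.append(mu + rng.normal(0, 0.5))
                    lab.append(gname)
                    cid.append(f"{gname}{c}")
        return metric, lab, cid

    def test_identical_groups_high_p(self, rng):
        m, g, c = self._data(rng, shift=0.0)
        res = permutation_group_compare(m, g, c, n_perm=400, seed=1)
        assert res.p_value > 0.05

    def test_deterministic_under_seed(self, rng):
        m, g, c = self._data(rng, shift=0.5)
        r1 = permutation_group_compare(m, g, c, n_perm=300, seed=7)
        r2 = permutation_group_compare(m, g, c, n_perm=300, seed=7)
        assert r1.p_value == r2.p_value

    def test_power_under_mean_shift(self, rng):
        hits = 0
        for _ in range(25):
            m, g, c = self._data(rng, shift=1.0)
            if permutation_group_compare(m, g, c, n_perm=300,
                                         seed=3).p_value < 0.05:
                hits += 1
        assert hits >= 20   # >= 80% detection

    def test_few_permutations_warns_in_note(self, rng):
        m, g, c = self._data(rng, n_clusters=2)
        res = permutation_group_compare(m, g, c, n_perm=100, seed=0)
        assert "distinct" in res.note

    def test_null_type1_within_binomial_ci(self, rng):
        n_rep, alpha = 400, 0.05
        hits = sum(
            permutation_group_compare(*self._data(rng), n_perm=200,
                                      seed=k).p_value < alpha
            for k in range(n_rep))
        ci = 1.96 * math.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(hits / n_rep - alpha) <= ci + 0.015  # add-one discreteness
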