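import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bsvm.data_model import summarize_variants
from bsvm.weighting import (NONRISK, RISK, WeightScheme, classify_variant,
                            collapse, compute_weights, erec_weight,
                            fp_weight, rbt_weight, rm_weight, weights_table,
                            wst_weight)
from tests.conftest import make_dataset


class TestClassification:
    @pytest.mark.parametrize("mc,mu,expected", [
        (7, 23, NONRISK),   # minor allele enriched in controls
        (5, 2, RISK),
        (3, 3, NONRISK),    # tie falls to the nonrisk branch
    ])
    def test_count_rule(self, mc, mu, expected):
        assert classify_variant(mc, mu) == expected


class TestRmWeight:
    def test_balanced_equal_counts_reduce_to_correction(self):
        # rate ratio 1, so RM = (m+2)/(m+1), slightly above 1
        assert rm_weight(3, 3, 100, 100, NONRISK) == pytest.approx(8 / 7)

    def test_hand_evaluated_example(self):
        # (10/1002)/(2/1002) * 12/11 = 60/11
        assert rm_weight(9, 1, 500, 500, RISK) == pytest.approx(60 / 11)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            rm_weight(0, 0, 10, 10, RISK)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.integers(0, 60), st.integers(0, 60), st.integers(5, 2000))
    def test_balanced_rm_above_one(self, mc, mu, n_half):
        # on balanced designs 1 < RM < inf for every polymorphic variant
        if mc + mu == 0:
            return
        cat = classify_variant(mc, mu)
        w = rm_weight(mc, mu, n_half, n_half, cat)
        assert 1.0 < w < np.inf


class TestComparisonWeights:
    def test_wst_hand_value(self):
        # q = 1/1002 -> 1/sqrt(1000 * q * (1-q)) = 1.00150
        assert wst_weight(0, 500, 1000) == pytest.approx(1.0014994, abs=1e-6)

    def test_wst_decreasing_in_control_count(self):
        ws = [wst_weight(m, 500, 1000) for m in range(0, 400, 25)]
        assert all(a > b for a, b in zip(ws, ws[1:]))

    def test_fp_half_frequency_gives_two(self):
        # smoothed pooled frequency 0.5 -> 1/sqrt(0.25) = 2
        assert fp_weight(2, 2, 4) == pytest.approx(2.0)

    def test_fp_published_count_layout(self):
        assert fp_weight(7, 23, 960) == pytest.approx(
            1 / np.sqrt((31 / 1922) * (1 - 31 / 1922)))

    def test_rbt_binomial_tail_enumeration(self):
        # P(Bin(10, 1/2) >= 9) = 11/1024, enumerated directly
        tail = sum(stats.binom.pmf(k, 10, 0.5) for k in (9, 10))
        assert tail == pytest.approx(11 / 1024)
        assert rbt_weight(9, 1, 500, 500, RISK) == pytest.approx(
            -np.log(11 / 1024))

    def test_rbt_grows_with_imbalance(self):
        ws = [rbt_weight(m, 10 - m, 500, 500, RISK) for m in (6, 8, 10)]
        assert ws[0] < ws[1] < ws[2]

    def test_erec_null_variant_weight_near_delta(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.2, 400)
        labels = np.concatenate([np.ones(200), -np.ones(200)])
        mc = int(g[:200].sum())
        w, _ = erec_weight(mc, int(g.sum()) - mc, 200, 200, g, labels,
                           delta=1.0)
        assert w == pytest.approx(1.0, abs=0.35)

    def test_erec_zero_delta_guard_is_finite(self):
        g = np.array([1, 0, 0, 0, 1, 0, 0, 0])
        labels = np.array([1, 1, 1, 1, -1, -1, -1, -1])
        w, cat = erec_weight(1, 1, 4, 4, g, labels, delta=0.0)
        assert np.isfinite(w) and w > 0

    def test_erec_risk_variant_exceeds_delta_on_average(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(50):
            g_case = rng.binomial(2, 0.12, 150)  # enriched in cases
            g_ctrl = rng.binomial(2, 0.04, 150)
            g = np.concatenate([g_case, g_ctrl])
            labels = np.concatenate([np.ones(150), -np.ones(150)])
            w, cat = erec_weight(int(g_case.sum()), int(g_ctrl.sum()),
                                 150, 150, g, labels)
            hits += (w > 1.0) and (cat == RISK)
        assert hits >= 45


class TestComputeWeightsKernelConsistency:
    """The compiled weight kernel used inside permutations must agree with
    the plain-python weight functions."""

    @pytest.mark.parametrize("scheme", ["RM", "WSt", "RBt", "Fp"])
    def test_schemes_match_reference_functions(self, scheme):
        rng = np.random.default_rng(23)
        counts = rng.binomial(2, 0.08, size=(60, 6))
        counts[0] = np.maximum(counts[0], 1)  # no monomorphic columns
        data = make_dataset(counts[:30], counts[30:])
        summaries = compute_weights(data, scheme=scheme)
        n1, n2 = data.n1, data.n2
        for s in summaries:
            cat = classify_variant(s.m_case, s.m_ctrl)
            assert s.category == cat
            if scheme == "RM":
                ref = rm_weight(s.m_case, s.m_ctrl, n1, n2, cat)
            elif scheme == "WSt":
                ref = wst_weight(s.m_ctrl, n2, n1 + n2)
            elif scheme == "RBt":
                ref = rbt_weight(s.m_case, s.m_ctrl, n1, n2, cat)
            else:
                ref = fp_weight(s.m_case, s.m_ctrl, n1 + n2)
            assert s.weight == pytest.approx(ref, rel=1e-9)

    def test_erec_scheme_matches_reference(self):
        rng = np.random.default_rng(29)
        counts = rng.binomial(2, 0.1, size=(80, 4)) % 3
        counts[0] = np.maximum(counts[0], 1)
        data = make_dataset(counts[:40], counts[40:])
        summaries = compute_weights(data, scheme=WeightScheme("EREC"))
        for j, s in enumerate(summaries):
            ref_w, ref_cat = erec_weight(s.m_case, s.m_ctrl, 40, 40,
                                         data.counts[:, j], data.labels)
            assert s.weight == pytest.approx(ref_w, rel=1e-9)
            assert s.category == ref_cat

    def test_all_schemes_positive_finite(self):
        rng = np.random.default_rng(31)
        counts = np.maximum(rng.binomial(2, 0.05, size=(50, 8)), 0)
        counts[0] = 1  # no monomorphic columns
        data = make_dataset(counts[:25], counts[25:])
        for scheme in ["RM", "WSt", "RBt", "Fp", "EREC"]:
            for s in compute_weights(data, scheme=scheme):
                assert np.isfinite(s.weight) and s.weight > 0


class TestCollapse:
    def _weighted(self, data):
        return compute_weights(data, summarize_variants(data), "RM")

    def test_single_risk_variant(self):
        data = make_dataset([[2], [1]], [[0], [0]])
        s = self._weighted(data)
        pair = collapse(data, s)
        np.testing.assert_allclose(pair.s_risk,
                                   s[0].weight * data.counts[:, 0])
        assert not pair.s_nonrisk.any()
        assert pair.members_risk == {"v0"}

    def test_removal_touches_only_own_category(self):
        data = make_dataset([[2, 0], [1, 0]], [[0, 1], [0, 2]])
        s = self._weighted(data)
        full = collapse(data, s)
        reduced = collapse(data, s, active_set={"v0"})
        # v1 is nonrisk: removing it leaves the risk covariate untouched
        np.testing.assert_array_equal(full.s_risk, reduced.s_risk)
        assert not reduced.s_nonrisk.any()

    def test_unit_weights_recover_burden(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 3, size=(20, 5))
        counts[0] = np.maximum(counts[0], 1)
        data = make_dataset(counts[:10], counts[10:])
        s = self._weighted(data)
        for x in s:
            x.weight = 1.0
        pair = collapse(data, s)
        np.testing.assert_allclose(pair.s_risk + pair.s_nonrisk,
                                   data.counts.sum(axis=1))

    def test_empty_active_set_rejected(self):
        data = make_dataset([[1]], [[0]])
        with pytest.raises(ValueError, match="empty"):
            collapse(data, self._weighted(data), active_set=set())

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_collapse_is_linear_over_disjoint_sets(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 3, size=(16, 6))
        counts[0] = np.maximum(counts[0], 1)
        data = make_dataset(counts[:8], counts[8:])
        s = self._weighted(data)
        ids = [x.variant_id for x in s]
        left, right = set(ids[:3]), set(ids[3:])
        both = collapse(data, s, left | right)
        a, b = collapse(data, s, left), collapse(data, s, right)
        np.testing.assert_allclose(both.s_risk, a.s_risk + b.s_risk)
        np.testing.assert_allclose(both.s_nonrisk,
                                   a.s_nonrisk + b.s_nonrisk)

    def test_weights_table_layout(self):
        data = make_dataset([[1, 1]], [[0, 1]])
        tab = weights_table(self._weighted(data), "RM")
        assert list(tab.columns) == ["variant_id", "m_case", "m_ctrl",
                                     "category", "scheme", "weight"]
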