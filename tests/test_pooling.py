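"""Fixed/random pooling, heterogeneity statistics and model selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.meta_analysis import combine_effects

from snpmeta import (ContrastTable, cochran_q, dl_random, iv_fixed, mh_fixed,
                     select_model, z_test)

from conftest import make_effect

effects_st = st.lists(
    st.tuples(st.floats(-2, 2), st.floats(0.01, 1.0)),
    min_size=2, max_size=8,
).map(lambda ps: [make_effect(y, v, f"s{i}") for i, (y, v) in enumerate(ps)])


def direct_summation_pool(pairs):
    """Independent plain-Python IV/DL pooling by direct summation."""
    w = [1.0 / v for _, v in pairs]
    sw = sum(w)
    theta_f = sum(wi * y for wi, (y, _) in zip(w, pairs)) / sw
    q = sum(wi * (y - theta_f) ** 2 for wi, (y, _) in zip(w, pairs))
    k = len(pairs)
    denom = sw - sum(wi * wi for wi in w) / sw
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    ws = [1.0 / (v + tau2) for _, v in pairs]
    theta_r = sum(wi * y for wi, (y, _) in zip(ws, pairs)) / sum(ws)
    return (theta_f, sw ** -0.5, q, tau2, theta_r, sum(ws) ** -0.5)


class TestIvFixed:
    def test_single_study_identity(self):
        r = iv_fixed([make_effect(math.log(2), 0.25)])
        assert r.log_or == pytest.approx(math.log(2))
        assert r.se == pytest.approx(0.5)
        assert r.q == 0.0 and r.p_q == 1.0 and r.i2 == 0.0

    def test_two_study_hand_arithmetic(self):
        r = iv_fixed([make_effect(0.0, 0.04), make_effect(0.2, 0.01)])
        assert r.log_or == pytest.approx(0.16)
        assert r.se == pytest.approx(0.089443, abs=1e-6)
        assert r.q == pytest.approx(0.8)
        assert r.z == pytest.approx(1.789, abs=1e-3)
        assert r.p == pytest.approx(0.0736, abs=1e-3)

    def test_replication_law(self):
        one = iv_fixed([make_effect(0.3, 0.09)])
        nine = iv_fixed([make_effect(0.3, 0.09, f"s{i}") for i in range(9)])
        assert nine.log_or == pytest.approx(0.3)
        assert nine.se == pytest.approx(one.se / 3)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            iv_fixed([])


class TestMhFixed:
    def test_common_stratum_or(self):
        r = mh_fixed([ContrastTable(10, 10, 5, 15), ContrastTable(20, 20, 10, 30)])
        assert r.odds_ratio == pytest.approx(3.0)

    def test_single_table_equals_crude_or(self):
        t = ContrastTable(12, 5, 8, 9)
        r = mh_fixed([t])
        assert r.odds_ratio == pytest.approx((12 * 9) / (5 * 8))

    @given(st.lists(st.tuples(st.integers(1, 80), st.integers(1, 80),
                              st.integers(1, 80)), min_size=1, max_size=6),
           st.floats(0.25, 4.0))
    @settings(max_examples=100, deadline=None)
    def test_shared_or_recovered_exactly(self, cells, ratio):
        # construct strata with a_i d_i = ratio * b_i c_i termwise
        tables = [ContrastTable(ratio * b * c / d, b, c, d) for b, c, d in cells]
        r = mh_fixed(tables)
        assert r.odds_ratio == pytest.approx(ratio, rel=1e-9)

    def test_rbg_variance_on_known_example(self):
        # single 2x2: RBG variance reduces to the Woolf variance
        t = ContrastTable(10, 20, 30, 40)
        r = mh_fixed([t])
        woolf = 1 / 10 + 1 / 20 + 1 / 30 + 1 / 40
        assert r.se**2 == pytest.approx(woolf, rel=1e-12)


class TestCochranQ:
    def test_hand_example(self):
        q, p_q, i2 = cochran_q([make_effect(0, 0.1), make_effect(1, 0.1)], 0.5)
        assert q == pytest.approx(5.0)
        assert i2 == pytest.approx((1 - 1 / 5) * 100)

    def test_homogeneous_effects(self):
        q, p_q, i2 = cochran_q([make_effect(0.4, v, f"s{v}") for v in (0.1, 0.2, 0.3)], 0.4)
        assert q == pytest.approx(0.0, abs=1e-15)
        assert i2 == 0.0

    def test_q_below_df_truncates_i2(self):
        q, p_q, i2 = cochran_q([make_effect(0, 0.04), make_effect(0.2, 0.01)], 0.16)
        assert q == pytest.approx(0.8)
        assert i2 == 0.0


class TestDlRandom:
    def test_hand_example(self):
        r = dl_random([make_effect(0, 0.1), make_effect(1, 0.1)])
        assert r.tau2 == pytest.approx(0.4)
        assert r.log_or == pytest.approx(0.5)
        assert r.se == pytest.approx(0.5)

    def test_collapses_to_fixed_when_q_small(self):
        effects = [make_effect(0, 0.04), make_effect(0.2, 0.01)]
        rd, rf = dl_random(effects), iv_fixed(effects)
        assert rd.tau2 == 0.0
        assert (rd.log_or, rd.se, rd.q) == (rf.log_or, rf.se, rf.q)

    def test_requires_two_studies(self):
        with pytest.raises(ValueError):
            dl_random([make_effect(0.1, 0.1)])

    @given(effects_st)
    @settings(max_examples=150, deadline=None)
    def test_random_se_dominates_fixed(self, effects):
        assert dl_random(effects).se >= iv_fixed(effects).se - 1e-15

    @given(effects_st)
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariance(self, effects):
        rev = list(reversed(effects))
        a, b = dl_random(effects), dl_random(rev)
        assert a.log_or == pytest.approx(b.log_or, rel=1e-12, abs=1e-12)
        assert a.tau2 == pytest.approx(b.tau2, rel=1e-12, abs=1e-12)

    @given(effects_st)
    @settings(max_examples=100, deadline=None)
    def test_sign_equivariance(self, effects):
        neg = [make_effect(-e.log_or, e.var, e.study_id) for e in effects]
        a, b = iv_fixed(effects), iv_fixed(neg)
        assert b.log_or == pytest.approx(-a.log_or, abs=1e-12)
        assert b.z == pytest.approx(-a.z, abs=1e-9)
        assert b.ci_low == pytest.approx(1 / a.ci_high, rel=1e-9)
        assert b.ci_high == pytest.approx(1 / a.ci_low, rel=1e-9)

    @given(effects_st)
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_direct_summation(self, effects):
        pairs = [(e.log_or, e.var) for e in effects]
        tf, sef, q, tau2, tr, ser = direct_summation_pool(pairs)
        rf, rr = iv_fixed(effects), dl_random(effects)
        assert rf.log_or == pytest.approx(tf, rel=1e-12, abs=1e-12)
        assert rf.se == pytest.approx(sef, rel=1e-12)
        assert rr.tau2 == pytest.approx(tau2, rel=1e-12, abs=1e-12)
        assert rr.log_or == pytest.approx(tr, rel=1e-12, abs=1e-12)
        assert rr.se == pytest.approx(ser, rel=1e-12)

    def test_cross_check_against_statsmodels(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            k = int(rng.integers(3, 9))
            y = rng.normal(0, 0.8, size=k)
            v = rng.uniform(0.02, 0.5, size=k)
            effects = [make_effect(float(yi), float(vi), f"s{i}")
                       for i, (yi, vi) in enumerate(zip(y, v))]
            ref = combine_effects(y, v, method_re="dl")
            rf = iv_fixed(effects)
            assert rf.log_or == pytest.approx(float(ref.mean_effect_fe), rel=1e-10)
            assert rf.se == pytest.approx(float(ref.sd_eff_w_fe), rel=1e-10)
            assert rf.q == pytest.approx(float(ref.q), rel=1e-10)
            if ref.tau2 > 0:  # statsmodels does not truncate negative tau2
                rr = dl_random(effects)
                assert rr.tau2 == pytest.approx(float(ref.tau2), rel=1e-10)
                assert rr.log_or == pytest.approx(float(ref.mean_effect_re), rel=1e-10)


class TestSelectModelAndZ:
    @pytest.mark.parametrize("p_q,expected", [
        (0.371, "fixed"),
        (0.05, "random"),   # boundary: "greater than" is strict
        (1.0, "fixed"),
        (0.01, "random"),
    ])
    def test_selection_rule(self, p_q, expected):
        assert select_model(p_q) == expected

    def test_z_null(self):
        z, p = z_test(0.0, 0.3)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_z_quantile_identity(self):
        z, p = z_test(1.959964 * 0.4, 0.4)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_z_rejects_bad_se(self):
        with pytest.raises(ValueError):
            z_test(0.1, 0.0)
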