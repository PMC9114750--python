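"""Egger regression, Begg rank correlation, funnel data export."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from snpmeta import begg_test, egger_test, funnel_data, iv_fixed

from conftest import make_effect


class TestEgger:
    def test_equal_effects_give_zero_intercept(self):
        effects = [make_effect(math.log(2), v, f"s{v}") for v in (0.04, 0.09, 0.25, 0.5)]
        r = egger_test(effects)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_perfect_line_through_origin(self):
        # y_i = 1 at precisions (1, 2, 3): t = (1, 2, 3) on x = (1, 2, 3),
        # a perfect fit through the origin
        effects = [make_effect(1.0, 1 / p**2, f"s{p}") for p in (1, 2, 3)]
        r = egger_test(effects)
        assert r.statistic == 0.0
        assert r.p == 1.0

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 0.5, 10)
        v = rng.uniform(0.02, 0.4, 10)
        effects = [make_effect(float(a), float(b), f"s{i}")
                   for i, (a, b) in enumerate(zip(y, v))]
        t = y / np.sqrt(v)
        x = 1 / np.sqrt(v)
        # textbook simple-regression intercept and its standard error
        b1 = np.sum((x - x.mean()) * (t - t.mean())) / np.sum((x - x.mean()) ** 2)
        b0 = t.mean() - b1 * x.mean()
        resid = t - b0 - b1 * x
        s2 = np.sum(resid ** 2) / (len(x) - 2)
        se0 = math.sqrt(s2 * (1 / len(x) + x.mean() ** 2 / np.sum((x - x.mean()) ** 2)))
        r = egger_test(effects)
        assert r.statistic == pytest.approx(b0, rel=1e-10)
        assert r.se == pytest.approx(se0, rel=1e-10)
        assert r.p == pytest.approx(2 * stats.t.sf(abs(b0 / se0), 8), rel=1e-10)

    def test_too_few_studies(self):
        with pytest.raises(ValueError, match="at least 3"):
            egger_test([make_effect(0, 0.1), make_effect(0.1, 0.2)])

    def test_identical_precisions_singular(self):
        with pytest.raises(ValueError, match="singular"):
            egger_test([make_effect(y, 0.1, f"s{y}") for y in (0.0, 0.1, 0.2)])

    def test_sign_equivariance(self):
        rng = np.random.default_rng(7)
        effects = [make_effect(float(y), float(v), f"s{i}") for i, (y, v) in
                   enumerate(zip(rng.normal(0, 1, 8), rng.uniform(0.05, 0.5, 8)))]
        neg = [make_effect(-e.log_or, e.var, e.study_id) for e in effects]
        a, b = egger_test(effects), egger_test(neg)
        assert b.statistic == pytest.approx(-a.statistic, rel=1e-10)
        assert b.p == pytest.approx(a.p, rel=1e-10)


def brute_force_cd(u, v):
    c = d = 0
    for (ui, vi), (uj, vj) in itertools.combinations(zip(u, v), 2):
        s = (ui - uj) * (vi - vj)
        c += s > 0
        d += s < 0
    return c, d


class TestBegg:
    def test_monotone_concordance(self):
        # u strictly increasing with v over k=4: all 6 pairs concordant
        effects = [make_effect(y, v, f"s{i}") for i, (y, v) in
                   enumerate([(0.0, 0.1), (0.3, 0.2), (0.7, 0.4), (1.4, 0.9)])]
        r = begg_test(effects)
        assert r.statistic == pytest.approx(1.0)
        expected_z = 6 / math.sqrt(4 * 3 * 13 / 18)
        assert r.t_or_z == pytest.approx(expected_z)

    def test_mirror_gives_negative_tau(self):
        # negate the concordant example: u flips sign, v unchanged
        effects = [make_effect(-y, v, f"s{i}") for i, (y, v) in
                   enumerate([(0.0, 0.1), (0.3, 0.2), (0.7, 0.4), (1.4, 0.9)])]
        r = begg_test(effects)
        assert r.statistic == pytest.approx(-1.0)

    def test_pair_counts_match_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            k = int(rng.integers(3, 11))
            y = rng.normal(0, 1, k)
            v = rng.uniform(0.05, 1.0, k)
            effects = [make_effect(float(a), float(b), f"s{i}")
                       for i, (a, b) in enumerate(zip(y, v))]
            pooled = iv_fixed(effects)
            v_bar = pooled.se ** 2
            u = (y - pooled.log_or) / np.sqrt(v - v_bar)
            c, d = brute_force_cd(u, v)
            r = begg_test(effects)
            assert r.t_or_z == pytest.approx(
                (c - d) / math.sqrt(k * (k - 1) * (2 * k + 5) / 18), rel=1e-12)

    def test_tau_cross_checked_against_scipy(self):
        rng = np.random.default_rng(9)
        y = rng.normal(0, 1, 9)
        v = rng.uniform(0.05, 1.0, 9)
        effects = [make_effect(float(a), float(b), f"s{i}")
                   for i, (a, b) in enumerate(zip(y, v))]
        pooled = iv_fixed(effects)
        u = (y - pooled.log_or) / np.sqrt(v - pooled.se ** 2)
        tau_ref = stats.kendalltau(u, v).statistic
        assert begg_test(effects).statistic == pytest.approx(tau_ref, rel=1e-10)

    def test_requires_two_studies(self):
        with pytest.raises(ValueError):
            begg_test([make_effect(0.2, 0.1)])


class TestSelectionSensitivity:
    def test_egger_detects_selection_with_nonnull_effect(self):
        """With a modest true effect, p-value selection suppresses the
        imprecise null-looking studies and leaves a genuinely asymmetric
        funnel; Egger's rejection rate rises far above its no-selection
        level."""
        from snpmeta.experiments import selection_bias_contrast
        import numpy as np
        from snpmeta.simulate import (SimulationConfig, apply_selection_bias,
                                      simulate_meta_dataset)
        from snpmeta.meta import MetaAnalysis
        seeds = np.random.SeedSequence(20).generate_state(150) % (2 ** 31)
        rej_full = rej_sel = n_sel = 0
        for s in seeds:
            config = SimulationConfig(k=40, true_log_or=math.log(1.2),
                                      selection_prob=0.9, seed=int(s))
            records = simulate_meta_dataset(config)
            effects = MetaAnalysis.from_records(records, "allelic").effects
            rej_full += egger_test(effects).p < 0.05
            surv = apply_selection_bias(records, config,
                                        np.random.default_rng(int(s) + 1))
            if len(surv) >= 3:
                n_sel += 1
                sel = MetaAnalysis.from_records(surv, "allelic").effects
                rej_sel += egger_test(sel).p < 0.05
        assert n_sel == 150
        assert rej_sel / n_sel > rej_full / 150 + 0.10


class TestFunnel:
    def test_cardinality_and_precision(self):
        effects = [make_effect(y, 0.1 + 0.1 * i, f"s{i}")
                   for i, y in enumerate((0.1, -0.2, 0.4))]
        pooled = iv_fixed(effects)
        points, guides = funnel_data(effects, pooled)
        assert len(points) == 3
        for p in points:
            assert p.precision * p.se == pytest.approx(1.0)
        assert (guides["upper"] - guides["lower"] >= 0).all()

    def test_symmetric_effects_symmetric_points(self):
        effects = [make_effect(0.5 + d, 0.1, f"s{d}") for d in (-0.3, 0.3)]
        pooled = iv_fixed(effects)
        points, _ = funnel_data(effects, pooled)
        assert points[0].log_or - pooled.log_or == pytest.approx(
            -(points[1].log_or - pooled.log_or))

    def test_empty_input(self):
        pooled = iv_fixed([make_effect(0.1, 0.1)])
        points, guides = funnel_data([], pooled)
        assert points == [] and len(guides) == 0
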