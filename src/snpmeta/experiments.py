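"""Seeded Monte-Carlo experiments for statistical calibration checks.

These routines exercise the analytic machinery against its own sampling
distributions: type-I error of the HWE and Egger tests under null
generation, confidence-interval coverage of the pooled odds ratio,
meta-regression slope recovery, agreement of the analytic power formula
with simulated rejection rates, and the directional effect of
publication selection on Egger's test.  Every routine takes an explicit
seed and is deterministic given it.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .bias import egger_test
from .meta import MetaAnalysis
from .metareg import PowerSpec, metareg_fit, power_two_proportions
from .models import GeneticModel, GenotypeCounts, hwe_chisq
from .simulate import (SimulationConfig, apply_selection_bias, genotype_probs,
                       simulate_meta_dataset)

__all__ = [
    "hwe_type1_rate",
    "egger_type1_rate",
    "pooled_ci_coverage",
    "metareg_slope_coverage",
    "power_mc_check",
    "selection_bias_contrast",
]


def hwe_type1_rate(n_reps: int = 2000, n: int = 500,
                   freq_range: tuple[float, float] = (0.35, 0.65),
                   alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the HWE chi-square test under exact HW sampling."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        q = rng.uniform(*freq_range)
        counts = rng.multinomial(n, genotype_probs(q))
        if hwe_chisq(GenotypeCounts(*map(int, counts))).p < alpha:
            rejections += 1
    return rejections / n_reps


def egger_type1_rate(n_reps: int = 200, k: int = 20, alpha: float = 0.05,
                     seed: int = 0) -> float:
    """Egger rejection rate over null (no-effect, no-selection) meta-datasets."""
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    rejections = 0
    for s in seeds:
        records = simulate_meta_dataset(
            SimulationConfig(k=k, true_log_or=0.0, tau2=0.0, seed=int(s)))
        ma = MetaAnalysis.from_records(records, GeneticModel.ALLELIC)
        if egger_test(ma.effects).p < alpha:
            rejections += 1
    return rejections / n_reps


def pooled_ci_coverage(n_reps: int = 500, k: int = 50,
                       true_or: float = 0.85, tau2: float = 0.0,
                       seed: int = 0) -> float:
    """Fraction of replicates whose pooled 95% CI covers the true odds ratio.

    Each replicate simulates ``k`` studies, pools the allelic contrast
    under the heterogeneity-selected model, and checks the CI.
    """
    theta = math.log(true_or)
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    covered = 0
    for s in seeds:
        records = simulate_meta_dataset(
            SimulationConfig(k=k, true_log_or=theta, tau2=tau2, seed=int(s)))
        pooled = MetaAnalysis.from_records(records, GeneticModel.ALLELIC).fit().pooled
        if pooled.ci_low <= true_or <= pooled.ci_high:
            covered += 1
    return covered / n_reps


def metareg_slope_coverage(n_reps: int = 300, k: int = 40,
                           intercept: float = 0.3, slope: float = 0.1,
                           seed: int = 0) -> float:
    """Wald-interval coverage of a known meta-regression slope.

    Per replicate: x_i uniform on (0, 10), known within-study variances
    v_i uniform on (0.01, 0.1), y_i = intercept + slope x_i + e_i with
    e_i ~ N(0, v_i); the fitted slope's 95% Wald interval is checked
    against the generating slope.
    """
    from .models import EffectEstimate, Z_975
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_reps):
        x = rng.uniform(0, 10, k)
        v = rng.uniform(0.01, 0.1, k)
        y = intercept + slope * x + rng.normal(0.0, np.sqrt(v))
        effects = []
        for i in range(k):
            half = Z_975 * math.sqrt(v[i])
            effects.append(EffectEstimate(
                log_or=float(y[i]), var=float(v[i]),
                odds_ratio=math.exp(y[i]), ci_low=math.exp(y[i] - half),
                ci_high=math.exp(y[i] + half), study_id=f"s{i}"))
        res = metareg_fit(effects, {f"s{i}": float(x[i]) for i in range(k)},
                          kind="continuous")
        term = res.coefficients[1]
        if abs(term.beta - slope) <= Z_975 * term.se:
            covered += 1
    return covered / n_reps


def power_mc_check(alpha: float = 0.05, or_alt: float = 2.0,
                   p_control: float = 0.5, n_alleles: int = 200,
                   n_sims: int = 20000, seed: int = 0) -> tuple[float, float]:
    """(analytic power, Monte-Carlo rejection rate) for the two-proportion test.

    The simulation applies the same unpooled-variance Wald Z-test the
    analytic formula describes to binomial allele-count draws.
    """
    spec = power_two_proportions(PowerSpec(
        alpha=alpha, or_alt=or_alt, p_control=p_control,
        n_case_alleles=n_alleles, n_control_alleles=n_alleles))
    p1 = or_alt * p_control / (1.0 + p_control * (or_alt - 1.0))
    rng = np.random.default_rng(seed)
    x1 = rng.binomial(n_alleles, p1, size=n_sims) / n_alleles
    x0 = rng.binomial(n_alleles, p_control, size=n_sims) / n_alleles
    se = np.sqrt(x1 * (1 - x1) / n_alleles + x0 * (1 - x0) / n_alleles)
    z_crit = float(stats.norm.isf(alpha / 2.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (x1 - x0) / se, np.inf * np.sign(x1 - x0))
    rate = float(np.mean(np.abs(z) > z_crit))
    return spec.power, rate


def selection_bias_contrast(n_reps: int = 300, k: int = 60,
                            selection_prob: float = 0.9, alpha: float = 0.05,
                            seed: int = 0) -> tuple[float, float]:
    """(selected, unselected) Egger rejection rates under null effects.

    Paired design: each replicate generates one null meta-dataset, runs
    Egger's test on it, then applies p-value-based publication selection
    and reruns the test on the survivors (skipped if fewer than three
    studies survive).
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    rej_full = rej_sel = n_sel = 0
    for s in seeds:
        config = SimulationConfig(k=k, true_log_or=0.0, tau2=0.0,
                                  selection_prob=selection_prob, seed=int(s))
        records = simulate_meta_dataset(config)
        effects = MetaAnalysis.from_records(records, GeneticModel.ALLELIC).effects
        if egger_test(effects).p < alpha:
            rej_full += 1
        rng = np.random.default_rng(int(s) + 1)
        survivors = apply_selection_bias(records, config, rng)
        if len(survivors) >= 3:
            n_sel += 1
            sel_effects = MetaAnalysis.from_records(
                survivors, GeneticModel.ALLELIC).effects
            if egger_test(sel_effects).p < alpha:
                rej_sel += 1
    return (rej_sel / max(n_sel, 1), rej_full / n_reps)
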