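"""Fixed-effect and random-effects pooling of study odds ratios.

Implements inverse-variance (IV) and Mantel-Haenszel (MH) fixed-effect
estimators, DerSimonian-Laird (DL) method-of-moments random effects,
Cochran's Q with I-squared, the heterogeneity-driven model-selection
rule (random effects when the Q-test p-value is 0.05 or below), and the
Z-test on the pooled log odds ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .models import ContrastTable, EffectEstimate, Z_975, study_odds_ratio

__all__ = [
    "PooledResult",
    "iv_fixed",
    "mh_fixed",
    "cochran_q",
    "dl_random",
    "select_model",
    "z_test",
]


@dataclass(frozen=True)
class PooledResult:
    """A pooled odds ratio with heterogeneity and significance statistics.

    ``q``/``p_q``/``i2`` describe between-study heterogeneity; ``tau2``
    is the between-study variance (zero under a fixed-effect model);
    ``z``/``p`` test the pooled log odds ratio against zero.
    """

    method: str                 # fixed_MH | fixed_IV | random_DL
    k: int
    log_or: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    q: float
    p_q: float
    i2: float
    tau2: float


def z_test(log_or: float, se: float) -> tuple[float, float]:
    """Two-sided standard-normal test of a pooled log odds ratio."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = log_or / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return z, p


def cochran_q(effects: Sequence[EffectEstimate],
              theta_fixed: float) -> tuple[float, float, float]:
    """Cochran's Q around ``theta_fixed`` with IV weights; returns (Q, p, I2).

    I-squared re-expresses Q as the percent of total variation
    attributable to heterogeneity: max(0, (Q - (k-1)) / Q) * 100.
    A single study yields Q=0, p=1, I2=0 by convention.
    """
    k = len(effects)
    if k == 0:
        raise ValueError("no effects")
    w = np.array([1.0 / e.var for e in effects])
    y = np.array([e.log_or for e in effects])
    q = float(np.sum(w * (y - theta_fixed) ** 2))
    if k < 2:
        return q, 1.0, 0.0
    p_q = float(stats.chi2.sf(q, df=k - 1))
    i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    return q, p_q, i2


def _finish(method: str, k: int, theta: float, se: float,
            q: float, p_q: float, i2: float, tau2: float) -> PooledResult:
    z, p = z_test(theta, se)
    half = Z_975 * se
    return PooledResult(
        method=method, k=k, log_or=theta, se=se,
        odds_ratio=math.exp(theta),
        ci_low=math.exp(theta - half), ci_high=math.exp(theta + half),
        z=z, p=p, q=q, p_q=p_q, i2=i2, tau2=tau2,
    )


def iv_fixed(effects: Sequence[EffectEstimate]) -> PooledResult:
    """Inverse-variance fixed-effect pooled odds ratio."""
    k = len(effects)
    if k == 0:
        raise ValueError("cannot pool an empty set of effects")
    w = np.array([1.0 / e.var for e in effects])
    y = np.array([e.log_or for e in effects])
    theta = float(np.sum(w * y) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q, p_q, i2 = cochran_q(effects, theta)
    return _finish("fixed_IV", k, theta, se, q, p_q, i2, 0.0)


def mh_fixed(tables: Sequence[ContrastTable],
             study_ids: Optional[Sequence[str]] = None,
             correction: float = 0.5) -> PooledResult:
    """Mantel-Haenszel fixed-effect pooled odds ratio.

    The MH estimator sums a_i d_i / n_i over b_i c_i / n_i on the raw
    tables; the variance of its log follows Robins, Breslow and
    Greenland.  Heterogeneity statistics are attached from the per-study
    Woolf estimates (continuity-corrected where needed) around the MH
    log odds ratio.
    """
    k = len(tables)
    if k == 0:
        raise ValueError("cannot pool an empty set of tables")
    R = S = 0.0
    sPR = sPSQR = sQS = 0.0
    for t in tables:
        n = t.n
        if n <= 0 or (t.a + t.c) == 0 or (t.b + t.d) == 0:
            raise ValueError("each stratum needs positive margins")
        P, Q = (t.a + t.d) / n, (t.b + t.c) / n
        Ri, Si = t.a * t.d / n, t.b * t.c / n
        R += Ri
        S += Si
        sPR += P * Ri
        sPSQR += P * Si + Q * Ri
        sQS += Q * Si
    if S == 0 or R == 0:
        raise ValueError("Mantel-Haenszel odds ratio undefined: zero numerator "
                         "or denominator sum (apply a continuity correction upstream)")
    theta = math.log(R / S)
    var = sPR / (2 * R * R) + sPSQR / (2 * R * S) + sQS / (2 * S * S)
    se = math.sqrt(var)
    ids = study_ids or [""] * k
    effects = [study_odds_ratio(t, correction=correction, study_id=i)
               for t, i in zip(tables, ids)]
    q, p_q, i2 = cochran_q(effects, theta)
    return _finish("fixed_MH", k, theta, se, q, p_q, i2, 0.0)


def dl_random(effects: Sequence[EffectEstimate]) -> PooledResult:
    """DerSimonian-Laird random-effects pooled odds ratio.

    tau2 is the method-of-moments estimate max(0, (Q-(k-1)) / (Sw -
    Sw2/Sw)) from the IV construction; when Q <= k-1 the estimate
    truncates to zero and the result coincides with :func:`iv_fixed`
    except for the method label.
    """
    k = len(effects)
    if k < 2:
        raise ValueError("random-effects pooling needs at least two studies")
    w = np.array([1.0 / e.var for e in effects])
    y = np.array([e.log_or for e in effects])
    theta_f = float(np.sum(w * y) / np.sum(w))
    q, p_q, i2 = cochran_q(effects, theta_f)
    denom = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (np.array([e.var for e in effects]) + tau2)
    theta = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    return _finish("random_DL", k, theta, se, q, p_q, i2, tau2)


def select_model(p_q: float, alpha_het: float = 0.05) -> str:
    """Heterogeneity-driven estimator choice: 'fixed' iff p_q > alpha_het.

    The inequality is strict, so a Q-test p exactly at the threshold
    selects the random-effects model.
    """
    if not (0.0 <= p_q <= 1.0 and 0.0 <= alpha_het <= 1.0):
        raise ValueError("p_q and alpha_het must lie in [0, 1]")
    return "fixed" if p_q > alpha_het else "random"


def with_heterogeneity(result: PooledResult, q: float, p_q: float,
                       i2: float) -> PooledResult:
    """Attach externally computed heterogeneity statistics to a result."""
    return replace(result, q=q, p_q=p_q, i2=i2)
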