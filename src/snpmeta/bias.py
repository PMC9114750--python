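"""Publication-bias diagnostics: Egger regression, Begg rank correlation,
and funnel-plot data export.

Small-study effects leave a funnel plot asymmetric.  Egger's test
regresses the standardized effect y_i/se_i on precision 1/se_i by
ordinary least squares and tests the intercept; Begg-Mazumdar computes
Kendall's rank correlation between variance-standardized effect
deviates and the study variances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .models import EffectEstimate, Z_975
from .pooling import PooledResult

__all__ = [
    "BiasTestResult",
    "FunnelPoint",
    "egger_test",
    "begg_test",
    "funnel_data",
]


@dataclass(frozen=True)
class BiasTestResult:
    """Outcome of one publication-bias test.

    For Egger, ``statistic`` is the regression intercept and ``se`` its
    OLS standard error with ``t_or_z`` Student-t on k-2 df; for Begg,
    ``statistic`` is Kendall's tau (tie-adjusted) and ``t_or_z`` the
    normal deviate of the concordance count.
    """

    test: str                   # "egger" | "begg"
    statistic: float
    se: Optional[float]
    t_or_z: float
    p: float
    k: int


@dataclass(frozen=True)
class FunnelPoint:
    study_id: str
    log_or: float
    se: float
    precision: float


def egger_test(effects: Sequence[EffectEstimate]) -> BiasTestResult:
    """Egger's weighted-regression intercept test for funnel asymmetry.

    OLS of t_i = y_i / se_i on x_i = 1 / se_i (the 1997 formulation);
    the intercept's departure from zero is tested against Student-t with
    k - 2 degrees of freedom.
    """
    k = len(effects)
    if k < 3:
        raise ValueError(f"Egger's test needs at least 3 studies, got {k}")
    se_i = np.array([e.se for e in effects])
    x = 1.0 / se_i
    if np.ptp(x) == 0:
        raise ValueError("all precisions identical: Egger design matrix singular")
    y = np.array([e.log_or for e in effects])
    if np.ptp(y) == 0:
        # t_i = y * x_i is an exact line through the origin: the intercept
        # is identically zero and the test degenerates to its null
        return BiasTestResult(test="egger", statistic=0.0, se=0.0,
                              t_or_z=0.0, p=1.0, k=k)
    t = y / se_i
    fit = sm.OLS(t, sm.add_constant(x)).fit()
    b0 = float(fit.params[0])
    se0 = float(fit.bse[0])
    if se0 == 0.0:
        # exact fit through some intercept; degenerate but well-defined null
        tstat, p = (0.0, 1.0) if b0 == 0.0 else (math.inf, 0.0)
    else:
        tstat = b0 / se0
        p = 2.0 * float(stats.t.sf(abs(tstat), df=k - 2))
    return BiasTestResult(test="egger", statistic=b0, se=se0, t_or_z=tstat, p=p, k=k)


def _kendall_counts(u: np.ndarray, v: np.ndarray) -> tuple[int, int]:
    """Concordant and discordant pair counts over all k(k-1)/2 pairs."""
    c = d = 0
    k = len(u)
    for i in range(k):
        for j in range(i + 1, k):
            s = (u[i] - u[j]) * (v[i] - v[j])
            if s > 0:
                c += 1
            elif s < 0:
                d += 1
    return c, d


def begg_test(effects: Sequence[EffectEstimate]) -> BiasTestResult:
    """Begg-Mazumdar rank-correlation test for publication bias.

    Effects are standardized against the IV fixed pooled estimate:
    u_i = (y_i - theta) / sqrt(v_i - v_bar) with v_bar the pooled
    variance; the statistic is tie-adjusted Kendall's tau between u_i
    and v_i, and the normal deviate uses the exact null variance of the
    concordance count, z = (C - D) / sqrt(k(k-1)(2k+5)/18).
    """
    k = len(effects)
    if k < 2:
        raise ValueError("Begg's test needs at least 2 studies")
    v = np.array([e.var for e in effects])
    y = np.array([e.log_or for e in effects])
    w = 1.0 / v
    theta = float(np.sum(w * y) / np.sum(w))
    v_bar = 1.0 / float(np.sum(w))
    bad = np.nonzero(v <= v_bar)[0]
    if bad.size:
        sid = effects[int(bad[0])].study_id or f"index {int(bad[0])}"
        raise ValueError(f"degenerate variance: study {sid} has v_i <= pooled variance")
    u = (y - theta) / np.sqrt(v - v_bar)
    c, d = _kendall_counts(u, v)
    n_pairs = k * (k - 1) // 2
    ties_u = n_pairs - _n_distinct_pairs(u)
    ties_v = n_pairs - _n_distinct_pairs(v)
    denom = math.sqrt((n_pairs - ties_u) * (n_pairs - ties_v))
    tau = (c - d) / denom if denom > 0 else 0.0
    z = (c - d) / math.sqrt(k * (k - 1) * (2 * k + 5) / 18.0)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return BiasTestResult(test="begg", statistic=tau, se=None, t_or_z=z, p=p, k=k)


def _n_distinct_pairs(x: np.ndarray) -> int:
    """Number of pairs whose two values differ (tie adjustment helper)."""
    k = len(x)
    total = k * (k - 1) // 2
    _, counts = np.unique(x, return_counts=True)
    tied = int(np.sum(counts * (counts - 1) // 2))
    return total - tied


def funnel_data(effects: Sequence[EffectEstimate], pooled: PooledResult,
                n_grid: int = 50) -> tuple[list[FunnelPoint], pd.DataFrame]:
    """Per-study funnel points plus pseudo-95%-CI guide lines.

    Guide lines trace theta +- 1.96 se over an se grid from 0 to the
    largest observed standard error, the usual funnel overlay.
    """
    points = [FunnelPoint(study_id=e.study_id, log_or=e.log_or,
                          se=e.se, precision=1.0 / e.se)
              for e in effects]
    if points:
        se_grid = np.linspace(0.0, max(p.se for p in points), n_grid)
    else:
        se_grid = np.array([])
    guides = pd.DataFrame({
        "se": se_grid,
        "lower": pooled.log_or - Z_975 * se_grid,
        "upper": pooled.log_or + Z_975 * se_grid,
    })
    return points, guides


def export_funnel(effects: Sequence[EffectEstimate], pooled: PooledResult,
                  path, guides_path=None) -> None:
    """Write funnel points as TSV; guide lines go to a sidecar TSV."""
    points, guides = funnel_data(effects, pooled)
    pd.DataFrame([p.__dict__ for p in points]).to_csv(path, sep="\t", index=False)
    if guides_path is not None:
        guides.to_csv(guides_path, sep="\t", index=False)
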