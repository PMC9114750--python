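"""Random-effects meta-regression and allele-based power calculation.

Meta-regression explains between-study variation in log odds ratios by
study-level covariates (publication year, ethnicity, control source,
genotyping method) under the mixed-effects model

    y_i = x_i' beta + u_i + e_i,   u_i ~ N(0, tau2),  e_i ~ N(0, v_i),

with v_i the known within-study variances.  The residual tau2 comes
from the method of moments generalizing DerSimonian-Laird (optionally
REML); coefficients from weighted least squares with weights
1/(v_i + tau2) and Wald z tests.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .models import EffectEstimate

__all__ = [
    "MetaRegResult",
    "MetaRegTerm",
    "PowerSpec",
    "MetaRegression",
    "metareg_fit",
    "power_two_proportions",
]


@dataclass(frozen=True)
class MetaRegTerm:
    term: str
    beta: float
    se: float
    z: float
    p: float


@dataclass(frozen=True)
class MetaRegResult:
    covariate: str
    coefficients: tuple[MetaRegTerm, ...]
    tau2: float
    q_e: float
    k: int
    tau2_method: str = "dl"


def _design_matrix(effects: Sequence[EffectEstimate],
                   covariate_values: Mapping[str, object],
                   kind: str,
                   rare_level_min: Optional[int] = None,
                   rare_label: str = "other_method"):
    """Intercept-plus-covariate design; categoricals dummy-coded against
    the most frequent level; levels rarer than ``rare_level_min`` merged."""
    ids = [e.study_id for e in effects]
    missing = [i for i in ids if i not in covariate_values]
    if missing:
        raise ValueError(f"missing covariate value for study {missing[0]!r}")
    vals = [covariate_values[i] for i in ids]
    k = len(ids)
    if kind == "continuous":
        x = np.column_stack([np.ones(k), np.asarray(vals, dtype=float)])
        return x, ["intercept", "slope"]
    if kind != "categorical":
        raise ValueError(f"kind must be 'continuous' or 'categorical', got {kind!r}")
    levels = [str(v) for v in vals]
    if rare_level_min is not None:
        counts = Counter(levels)
        levels = [lv if counts[lv] >= rare_level_min else rare_label for lv in levels]
    counts = Counter(levels)
    # reference = most frequent level; ties broken alphabetically for determinism
    ref = min(counts, key=lambda lv: (-counts[lv], lv))
    others = sorted(lv for lv in counts if lv != ref)
    cols = [np.ones(k)] + [np.array([1.0 if lv == o else 0.0 for lv in levels])
                           for o in others]
    names = ["intercept"] + [f"[{o} vs {ref}]" for o in others]
    x = np.column_stack(cols)
    return x, names


def _mom_tau2(y: np.ndarray, v: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Method-of-moments residual tau2 and the residual heterogeneity Q_E.

    With FE weights W = diag(1/v) and hat projection onto the column
    space of X, Q_E is the weighted residual sum of squares and
    tau2 = max(0, (Q_E - (k - p)) / tr(P)) with P = W - W X (X'WX)^-1 X'W.
    """
    k, p = x.shape
    w = 1.0 / v
    W = np.diag(w)
    xtwx_inv = np.linalg.inv(x.T @ W @ x)
    beta = xtwx_inv @ (x.T @ (w * y))
    resid = y - x @ beta
    q_e = float(np.sum(w * resid ** 2))
    P = W - W @ x @ xtwx_inv @ x.T @ W
    tr_p = float(np.trace(P))
    tau2 = max(0.0, (q_e - (k - p)) / tr_p) if tr_p > 0 else 0.0
    return tau2, q_e


def _reml_tau2(y: np.ndarray, v: np.ndarray, x: np.ndarray) -> float:
    """Residual-maximum-likelihood tau2 by 1-d bounded optimization."""
    def neg_restricted_ll(tau2: float) -> float:
        wi = 1.0 / (v + tau2)
        W = np.diag(wi)
        xtwx = x.T @ W @ x
        beta = np.linalg.solve(xtwx, x.T @ (wi * y))
        resid = y - x @ beta
        ll = -0.5 * (np.sum(np.log(v + tau2)) + np.sum(wi * resid ** 2)
                     + np.log(np.linalg.det(xtwx)))
        return -ll
    upper = max(10.0 * float(np.var(y)), 1.0)
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(0.0, upper),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    return max(0.0, float(res.x))


def metareg_fit(effects: Sequence[EffectEstimate],
                covariate_values: Mapping[str, object],
                kind: str = "continuous",
                covariate: str = "covariate",
                tau2_method: str = "dl",
                rare_level_min: Optional[int] = None) -> MetaRegResult:
    """Univariable random-effects meta-regression of log odds ratios.

    ``covariate_values`` maps study_id to the covariate value (every
    study must be covered).  Requires k >= number of design columns + 2
    so the residual tau2 is estimable with at least one spare degree of
    freedom.
    """
    x, names = _design_matrix(effects, covariate_values, kind,
                              rare_level_min=rare_level_min)
    k, p = x.shape
    if k < p + 2:
        raise ValueError(f"need at least {p + 2} studies for {p} design columns, got {k}")
    if np.linalg.matrix_rank(x) < p:
        raise ValueError(f"rank-deficient design for covariate {covariate!r}: "
                         f"collinear columns among {names}")
    y = np.array([e.log_or for e in effects])
    v = np.array([e.var for e in effects])
    tau2, q_e = _mom_tau2(y, v, x)
    if tau2_method == "reml":
        tau2 = _reml_tau2(y, v, x)
    elif tau2_method != "dl":
        raise ValueError(f"unknown tau2_method {tau2_method!r}")
    w_star = 1.0 / (v + tau2)
    W = np.diag(w_star)
    cov = np.linalg.inv(x.T @ W @ x)
    beta = cov @ (x.T @ (w_star * y))
    terms = []
    for j, name in enumerate(names):
        se = math.sqrt(cov[j, j])
        z = beta[j] / se
        terms.append(MetaRegTerm(term=name, beta=float(beta[j]), se=se,
                                 z=float(z), p=2.0 * float(stats.norm.sf(abs(z)))))
    return MetaRegResult(covariate=covariate, coefficients=tuple(terms),
                         tau2=tau2, q_e=q_e, k=k, tau2_method=tau2_method)


class MetaRegression:
    """Model object for a univariable random-effects meta-regression.

    Mirrors the Model/Results convention: construct from per-study
    effects and a covariate, then ``fit()`` for a :class:`MetaRegResult`
    whose ``summary()``-style content lives in its coefficient terms.
    """

    def __init__(self, effects: Sequence[EffectEstimate],
                 covariate_values: Mapping[str, object],
                 kind: str = "continuous", covariate: str = "covariate",
                 rare_level_min: Optional[int] = None):
        self.effects = list(effects)
        self.covariate_values = dict(covariate_values)
        self.kind = kind
        self.covariate = covariate
        self.rare_level_min = rare_level_min

    @classmethod
    def from_records(cls, records, effects: Sequence[EffectEstimate],
                     covariate: str, rare_level_min: Optional[int] = None
                     ) -> "MetaRegression":
        """Build from study records using a named metadata field.

        ``covariate`` is one of ``year`` (continuous), ``ethnicity``,
        ``source`` or ``method`` (categorical).
        """
        kind = "continuous" if covariate == "year" else "categorical"
        values = {r.study_id: getattr(r, covariate) for r in records}
        return cls(effects, values, kind=kind, covariate=covariate,
                   rare_level_min=rare_level_min)

    def fit(self, tau2_method: str = "dl") -> MetaRegResult:
        return metareg_fit(self.effects, self.covariate_values, kind=self.kind,
                           covariate=self.covariate, tau2_method=tau2_method,
                           rare_level_min=self.rare_level_min)


def metareg_frame(result: MetaRegResult):
    """One row per coefficient term with beta, se, z, p, tau2, q_e."""
    import pandas as pd
    return pd.DataFrame([{
        "covariate": result.covariate, "term": t.term, "beta": t.beta,
        "se": t.se, "z": t.z, "p": t.p, "tau2": result.tau2,
        "q_e": result.q_e, "k": result.k,
    } for t in result.coefficients])


@dataclass(frozen=True)
class PowerSpec:
    """Inputs and result of an allele-based two-proportion power analysis.

    ``p_control`` is the control-arm G-allele frequency; under odds
    ratio ``or_alt`` the case-arm frequency is OR p0 / (1 + p0 (OR-1)).
    Sample sizes are allele counts (2N per arm).
    """

    alpha: float
    or_alt: float
    p_control: float
    n_case_alleles: int
    n_control_alleles: int
    power: Optional[float] = None


def power_two_proportions(spec: PowerSpec) -> PowerSpec:
    """Power of the two-sided two-proportion Z-test at the given allele counts.

    Uses the unpooled-variance normal approximation without continuity
    correction: with delta = p1 - p0 and se the unpooled standard error,
    power = Phi(-z_{1-a/2} + delta/se) + Phi(-z_{1-a/2} - delta/se),
    which reduces exactly to alpha at OR = 1.
    """
    if not (0.0 < spec.alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if not (0.0 < spec.p_control < 1.0):
        raise ValueError("p_control must lie in (0, 1)")
    if spec.or_alt <= 0:
        raise ValueError("or_alt must be positive")
    if spec.n_case_alleles < 2 or spec.n_control_alleles < 2:
        raise ValueError("need at least 2 alleles per arm")
    p0 = spec.p_control
    p1 = spec.or_alt * p0 / (1.0 + p0 * (spec.or_alt - 1.0))
    if not (0.0 < p1 < 1.0):
        raise ValueError(f"degenerate case allele frequency {p1}")
    se = math.sqrt(p1 * (1 - p1) / spec.n_case_alleles
                   + p0 * (1 - p0) / spec.n_control_alleles)
    z_crit = float(stats.norm.isf(spec.alpha / 2.0))
    delta = p1 - p0
    power = float(stats.norm.cdf(-z_crit + delta / se)
                  + stats.norm.cdf(-z_crit - delta / se))
    return PowerSpec(alpha=spec.alpha, or_alt=spec.or_alt, p_control=p0,
                     n_case_alleles=spec.n_case_alleles,
                     n_control_alleles=spec.n_control_alleles, power=power)
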