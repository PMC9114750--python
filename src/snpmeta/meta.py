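"""Model/Results front end for a single meta-analysis.

:class:`MetaAnalysis` is built from study data (genotype counts or
precomputed effects) for one genetic-model contrast; ``fit()`` returns a
:class:`MetaAnalysisResults` carrying the pooled estimate, its
uncertainty, heterogeneity diagnostics, publication-bias tests and a
``summary()`` table, in the spirit of the classic statistical-modelling
APIs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bias import BiasTestResult, begg_test, egger_test, funnel_data
from .models import (ContrastTable, EffectEstimate, GeneticModel,
                     build_contrast, corrected_table, study_odds_ratio)
from .pooling import (PooledResult, dl_random, iv_fixed, mh_fixed,
                      select_model, with_heterogeneity)
from .studies import StudyRecord

__all__ = ["MetaAnalysis", "MetaAnalysisResults"]


class MetaAnalysis:
    """A single-contrast meta-analysis of case-control genotype studies.

    Parameters
    ----------
    effects
        Per-study log odds ratio estimates.
    tables
        The corresponding 2x2 contrast tables (required for the
        Mantel-Haenszel estimator; optional otherwise).
    correction
        Continuity correction added to all four cells of a table
        containing a zero.

    Examples
    --------
    >>> from snpmeta import MetaAnalysis, GeneticModel
    >>> from snpmeta.simulate import SimulationConfig, simulate_meta_dataset
    >>> studies = simulate_meta_dataset(SimulationConfig(k=12, seed=7))
    >>> res = MetaAnalysis.from_records(studies, GeneticModel.ALLELIC).fit()
    >>> 0 < res.pooled.odds_ratio  # doctest: +SKIP
    """

    def __init__(self, effects: Sequence[EffectEstimate],
                 tables: Optional[Sequence[ContrastTable]] = None,
                 correction: float = 0.5):
        if not effects:
            raise ValueError("MetaAnalysis needs at least one study")
        if tables is not None and len(tables) != len(effects):
            raise ValueError("tables and effects must align")
        self.effects = list(effects)
        self.tables = list(tables) if tables is not None else None
        self.correction = correction

    @classmethod
    def from_records(cls, records: Sequence[StudyRecord],
                     model: GeneticModel | str = GeneticModel.ALLELIC,
                     correction: float = 0.5) -> "MetaAnalysis":
        """Build from study records carrying genotype counts."""
        model = GeneticModel(model)
        with_counts = [r for r in records if r.has_genotype_counts]
        if not with_counts:
            raise ValueError("no study carries genotype counts")
        tables = [build_contrast(model, r.case_counts, r.control_counts)
                  for r in with_counts]
        effects = [study_odds_ratio(t, correction=correction, study_id=r.study_id)
                   for t, r in zip(tables, with_counts)]
        return cls(effects, tables=tables, correction=correction)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       log_or: str = "log_or", var: str = "var",
                       study_id: str = "study_id") -> "MetaAnalysis":
        """Build from a DataFrame of precomputed log odds ratios."""
        effects = []
        for _, row in frame.iterrows():
            y, v = float(row[log_or]), float(row[var])
            half = 1.959964 * np.sqrt(v)
            effects.append(EffectEstimate(
                log_or=y, var=v, odds_ratio=float(np.exp(y)),
                ci_low=float(np.exp(y - half)), ci_high=float(np.exp(y + half)),
                study_id=str(row[study_id]) if study_id in row else ""))
        return cls(effects)

    def fit(self, method: str = "auto", alpha_het: float = 0.05,
            fixed_estimator: str = "mh") -> "MetaAnalysisResults":
        """Pool the studies.

        ``method='auto'`` applies the heterogeneity rule: fixed effect
        when the Q-test p exceeds ``alpha_het``, DerSimonian-Laird
        random effects otherwise.  The fixed estimator is
        Mantel-Haenszel when tables are available (``fixed_estimator=
        'mh'``), inverse-variance otherwise or on request.
        """
        k = len(self.effects)
        iv = iv_fixed(self.effects)
        if method == "auto":
            method = select_model(iv.p_q, alpha_het) if k >= 2 else "fixed"
        if method == "random":
            if k < 2:
                raise ValueError("random-effects pooling needs at least two studies")
            pooled = dl_random(self.effects)
        elif method == "fixed":
            if fixed_estimator == "mh" and self.tables is not None:
                mh = mh_fixed([corrected_table(t, self.correction) for t in self.tables],
                              study_ids=[e.study_id for e in self.effects],
                              correction=self.correction)
                # report heterogeneity from the IV construction used for selection
                pooled = with_heterogeneity(mh, iv.q, iv.p_q, iv.i2)
            else:
                pooled = iv
        else:
            raise ValueError(f"unknown method {method!r}")
        return MetaAnalysisResults(self, pooled)


@dataclass
class MetaAnalysisResults:
    """Fitted pooled estimate plus diagnostics for one contrast."""

    model: MetaAnalysis
    pooled: PooledResult

    @property
    def k(self) -> int:
        return self.pooled.k

    def egger(self) -> BiasTestResult:
        return egger_test(self.model.effects)

    def begg(self) -> BiasTestResult:
        return begg_test(self.model.effects)

    def funnel(self):
        return funnel_data(self.model.effects, self.pooled)

    def forest_frame(self) -> pd.DataFrame:
        """Per-study OR/CI and percentage weights plus a summary row."""
        p = self.pooled
        if p.method == "random_DL":
            w = np.array([1.0 / (e.var + p.tau2) for e in self.model.effects])
        else:
            w = np.array([1.0 / e.var for e in self.model.effects])
        w_pct = 100.0 * w / w.sum()
        rows = [{
            "study_id": e.study_id, "or": e.odds_ratio,
            "ci_low": e.ci_low, "ci_high": e.ci_high, "weight_pct": wp,
        } for e, wp in zip(self.model.effects, w_pct)]
        rows.append({"study_id": f"pooled ({p.method})", "or": p.odds_ratio,
                     "ci_low": p.ci_low, "ci_high": p.ci_high,
                     "weight_pct": 100.0})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        p = self.pooled
        lines = [
            "Meta-analysis of odds ratios",
            "=" * 46,
            f"studies (k)        : {p.k}",
            f"method             : {p.method}",
            f"pooled OR [95% CI] : {p.odds_ratio:.3f} [{p.ci_low:.3f}, {p.ci_high:.3f}]",
            f"Z, p               : {p.z:.3f}, {p.p:.4g}",
            f"Q, p_Q (df={p.k - 1:>3})   : {p.q:.3f}, {p.p_q:.4g}",
            f"I^2                : {p.i2:.1f}%",
            f"tau^2              : {p.tau2:.4g}",
        ]
        return "\n".join(lines)
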