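"""Full stratified analysis: all five contrasts across every subgroup axis.

Produces a report shaped like the stratified-results tables of the
case-control SNP meta-analysis literature: one row per subgroup (total,
HWE-consistent subset, multi-study cancer types plus an "others" lump,
organ systems, ethnicities, control sources) with the study count, the
case/control totals, and — for rows whose studies carry genotype counts
— the five pooled genetic-model results, each pooled fixed or random
according to its own heterogeneity test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .meta import MetaAnalysis
from .models import EffectEstimate, GeneticModel
from .pooling import PooledResult
from .studies import (ETHNICITIES, SOURCES, StudyRecord, SubgroupKey,
                      aggregate_counts, filter_subgroup, group_cancer_types)

__all__ = [
    "AnalysisConfig",
    "ReportRow",
    "AnalysisReport",
    "run_full_analysis",
    "render_report",
    "export_forest_data",
]

logger = logging.getLogger(__name__)

MODEL_ORDER = (GeneticModel.ALLELIC, GeneticModel.HETEROZYGOTE,
               GeneticModel.HOMOZYGOTE, GeneticModel.DOMINANT,
               GeneticModel.RECESSIVE)


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings echoed into every report for provenance."""

    hwe_threshold: float = 0.05
    alpha_het: float = 0.05
    correction: float = 0.5
    fixed_estimator: str = "mh"   # "mh" | "iv"
    min_k: int = 1                # subgroups below this are still reported, flagged
    seed: Optional[int] = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("hwe_threshold", "alpha_het", "correction",
                 "fixed_estimator", "min_k", "seed")}


@dataclass
class ReportRow:
    key: SubgroupKey
    k: int
    case_total: int
    control_total: int
    models: dict[GeneticModel, Optional[PooledResult]]


@dataclass
class AnalysisReport:
    rows: list[ReportRow]
    settings: dict
    warnings: list[str] = field(default_factory=list)


def _subgroup_keys(records: Sequence[StudyRecord]) -> list[SubgroupKey]:
    keys = [SubgroupKey("total"), SubgroupKey("hwe_subset")]
    keys += [SubgroupKey("cancer_type", label)
             for label in group_cancer_types(records)]
    systems = sorted({r.system for r in records if r.system})
    keys += [SubgroupKey("system", s) for s in systems]
    keys += [SubgroupKey("ethnicity", e) for e in sorted(ETHNICITIES)
             if any(r.ethnicity == e for r in records)]
    keys += [SubgroupKey("source", s) for s in sorted(SOURCES)
             if any(r.source == s for r in records)]
    return keys


def run_full_analysis(records: Sequence[StudyRecord],
                      config: AnalysisConfig = AnalysisConfig()) -> AnalysisReport:
    """Analyze every subgroup under every genetic model.

    Rows lacking genotype counts contribute to the count columns only
    (with a warning); a subgroup of one genotyped study reports its
    crude odds ratio, flagged.  Deterministic given input and config.
    """
    if not records:
        raise ValueError("no records to analyze")
    report = AnalysisReport(rows=[], settings=config.as_dict())
    for key in _subgroup_keys(records):
        subset = filter_subgroup(records, key, hwe_threshold=config.hwe_threshold)
        k, n_case, n_control = aggregate_counts(subset)
        models: dict[GeneticModel, Optional[PooledResult]] = {}
        genotyped = [r for r in subset if r.has_genotype_counts]
        if not genotyped:
            report.warnings.append(f"{key}: no genotype counts; count-only row")
            models = {m: None for m in MODEL_ORDER}
        else:
            if len(genotyped) < len(subset):
                report.warnings.append(
                    f"{key}: {len(subset) - len(genotyped)} studies lack "
                    "genotype counts and enter count columns only")
            if len(genotyped) < config.min_k:
                report.warnings.append(f"{key}: only {len(genotyped)} genotyped "
                                       f"studies (min_k={config.min_k})")
            for model in MODEL_ORDER:
                ma = MetaAnalysis.from_records(genotyped, model,
                                               correction=config.correction)
                if len(ma.effects) == 1:
                    report.warnings.append(f"{key}/{model.value}: single study, crude OR")
                res = ma.fit(method="auto", alpha_het=config.alpha_het,
                             fixed_estimator=config.fixed_estimator)
                models[model] = res.pooled
        logger.info("analyzed subgroup %s (k=%d)", key, k)
        report.rows.append(ReportRow(key=key, k=k, case_total=n_case,
                                     control_total=n_control, models=models))
    return report


def report_frame(report: AnalysisReport, precision: str = "machine") -> pd.DataFrame:
    """Flatten a report to one row per subgroup with per-model columns."""
    if precision not in ("machine", "human"):
        raise ValueError("precision must be 'machine' or 'human'")
    rows = []
    for rr in report.rows:
        row: dict = {"axis": rr.key.axis, "level": rr.key.level or "",
                     "k": rr.k, "n_case": rr.case_total,
                     "n_control": rr.control_total}
        for model in MODEL_ORDER:
            p = rr.models.get(model)
            tag = model.value
            if p is None:
                for col in ("or", "ci_low", "ci_high", "p_h", "p",
                            "method", "tau2", "i2"):
                    row[f"{tag}_{col}"] = ""
                continue
            if precision == "human":
                row.update({f"{tag}_or": round(p.odds_ratio, 2),
                            f"{tag}_ci_low": round(p.ci_low, 2),
                            f"{tag}_ci_high": round(p.ci_high, 2),
                            f"{tag}_p_h": round(p.p_q, 3),
                            f"{tag}_p": round(p.p, 3)})
            else:
                row.update({f"{tag}_or": p.odds_ratio,
                            f"{tag}_ci_low": p.ci_low,
                            f"{tag}_ci_high": p.ci_high,
                            f"{tag}_p_h": p.p_q,
                            f"{tag}_p": p.p})
            row.update({f"{tag}_method": p.method, f"{tag}_tau2": p.tau2,
                        f"{tag}_i2": p.i2})
        rows.append(row)
    return pd.DataFrame(rows)


def render_report(report: AnalysisReport, path: str | Path,
                  precision: str = "machine") -> None:
    """Write the stratified report as TSV; warnings to a sidecar file."""
    path = Path(path)
    report_frame(report, precision=precision).to_csv(path, sep="\t", index=False)
    if report.warnings:
        warn_path = path.with_suffix(path.suffix + ".warnings.txt")
        warn_path.write_text("\n".join(report.warnings) + "\n", encoding="utf-8")


def export_forest_data(effects: Sequence[EffectEstimate], pooled: PooledResult,
                       path: str | Path) -> None:
    """Write per-study OR/CI/weight rows plus a pooled summary row as TSV."""
    from .meta import MetaAnalysisResults
    res = MetaAnalysisResults(MetaAnalysis(effects), pooled)
    res.forest_frame().to_csv(path, sep="\t", index=False)
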