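"""Genetic-model 2x2 contrasts, per-study odds ratios and HWE testing.

A biallelic SNP with alleles A and G yields a 3x2 genotype-by-status
table per study.  Five standard recodings collapse it to a 2x2 table
with G-bearing exposure: allelic (G vs A alleles, 2N alleles per arm),
heterozygote (AG vs AA), homozygote (GG vs AA), dominant (GG+AG vs AA)
and recessive (GG vs AG+AA).  Each 2x2 table gives a log odds ratio with
Woolf variance; zero cells receive the Haldane-Anscombe +0.5 correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from scipy import stats

from .studies import GenotypeCounts

__all__ = [
    "GeneticModel",
    "ContrastTable",
    "EffectEstimate",
    "HweResult",
    "Z_975",
    "build_contrast",
    "study_odds_ratio",
    "corrected_table",
    "hwe_chisq",
]

#: Two-sided 95% standard-normal quantile used for all confidence intervals.
Z_975 = 1.959964


class GeneticModel(str, Enum):
    """The five genetic-model contrasts, G fixed as the effect allele."""

    ALLELIC = "allelic"          # G allele vs A allele
    HETEROZYGOTE = "heterozygote"  # AG vs AA
    HOMOZYGOTE = "homozygote"    # GG vs AA
    DOMINANT = "dominant"        # GG+AG vs AA
    RECESSIVE = "recessive"      # GG vs AG+AA

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ContrastTable:
    """One 2x2 exposed/unexposed x case/control table.

    Cells are real-valued so the +0.5 continuity correction can be
    represented; ``corrected`` records whether it was applied.
    Orientation: a = exposed cases, b = unexposed cases, c = exposed
    controls, d = unexposed controls, exposure = the G-bearing category.
    """

    a: float
    b: float
    c: float
    d: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contrast cells must be nonnegative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study log odds ratio with Woolf variance and 95% CI."""

    log_or: float
    var: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    study_id: str = ""

    def __post_init__(self) -> None:
        if self.var <= 0:
            raise ValueError("effect variance must be positive")

    @property
    def se(self) -> float:
        return math.sqrt(self.var)


@dataclass(frozen=True)
class HweResult:
    """Pearson chi-square goodness-of-fit to Hardy-Weinberg proportions."""

    chi2: float
    p: float
    allele_freq_A: float
    df: int = 1


def build_contrast(model: GeneticModel | str, case: GenotypeCounts,
                   control: GenotypeCounts) -> ContrastTable:
    """Collapse per-arm genotype counts into one genetic-model 2x2 table.

    For the allelic contrast each subject contributes two alleles, so
    the case margin is exactly 2 * n_case.  Heterozygote and homozygote
    contrasts drop the excluded genotype's subjects.
    """
    model = GeneticModel(model)
    if case is None or control is None:
        raise ValueError(f"{model.value} contrast: genotype counts required")
    if case.total < 1 or control.total < 1:
        raise ValueError("each arm needs at least one genotyped subject")

    def cells(g: GenotypeCounts) -> tuple[float, float]:
        if model is GeneticModel.ALLELIC:
            return (2 * g.n_GG + g.n_AG, 2 * g.n_AA + g.n_AG)
        if model is GeneticModel.HETEROZYGOTE:
            return (g.n_AG, g.n_AA)
        if model is GeneticModel.HOMOZYGOTE:
            return (g.n_GG, g.n_AA)
        if model is GeneticModel.DOMINANT:
            return (g.n_GG + g.n_AG, g.n_AA)
        return (g.n_GG, g.n_AG + g.n_AA)  # recessive

    a, b = cells(case)
    c, d = cells(control)
    return ContrastTable(a=float(a), b=float(b), c=float(c), d=float(d))


def study_odds_ratio(table: ContrastTable, correction: float = 0.5,
                     study_id: str = "") -> EffectEstimate:
    """Odds ratio, Woolf variance and 95% CI for one 2x2 table.

    When any cell is zero, ``correction`` (Haldane-Anscombe, default
    0.5) is added to all four cells; with ``correction=0`` a zero cell
    makes the estimate undefined and raises.
    """
    if correction < 0:
        raise ValueError("correction must be >= 0")
    a, b, c, d = table.a, table.b, table.c, table.d
    if a == b == c == d == 0:
        raise ValueError("all four cells are zero; no information")
    corrected = table.corrected
    if min(a, b, c, d) == 0:
        if correction == 0:
            raise ValueError("zero cell with correction=0: odds ratio undefined")
        a, b, c, d = a + correction, b + correction, c + correction, d + correction
        corrected = True
    log_or = math.log((a * d) / (b * c))
    var = 1 / a + 1 / b + 1 / c + 1 / d
    half = Z_975 * math.sqrt(var)
    return EffectEstimate(
        log_or=log_or,
        var=var,
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - half),
        ci_high=math.exp(log_or + half),
        study_id=study_id,
    )


def corrected_table(table: ContrastTable, correction: float = 0.5) -> ContrastTable:
    """Return the table with the continuity correction applied if needed."""
    if min(table.a, table.b, table.c, table.d) > 0:
        return table
    return ContrastTable(table.a + correction, table.b + correction,
                         table.c + correction, table.d + correction, corrected=True)


def hwe_chisq(control: GenotypeCounts) -> HweResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions.

    Expected counts come from the estimated A-allele frequency
    p = (2 n_AA + n_AG) / 2n; classes with expected count zero (a
    monomorphic sample) contribute nothing when observed is also zero.
    """
    n = control.total
    if n < 1:
        raise ValueError("need at least one genotyped control")
    p_a = (2 * control.n_AA + control.n_AG) / (2 * n)
    expected = (n * p_a ** 2, 2 * n * p_a * (1 - p_a), n * (1 - p_a) ** 2)
    observed = control.as_tuple()
    chi2 = 0.0
    for obs, exp in zip(observed, expected):
        if exp == 0.0:
            # p_a in {0,1}: observed must match (guaranteed by construction)
            continue
        chi2 += (obs - exp) ** 2 / exp
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return HweResult(chi2=chi2, p=p, allele_freq_A=p_a)
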