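"""Overlap between SNP sets and the positively-selected SNP catalog.

For each genotyping platform manifest (and for the GWAS-reported SNP
set) this module computes the percentage of SNPs carrying a signature of
recent positive selection, with binomial standard errors, and compares
groups by 2x2 chi-square with Bonferroni adjustment across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .mira import binomial_se
from .stats import TestResult, chi2_2x2
from .tables_io import PlatformManifest, SelectedSnpSet

__all__ = [
    "OverlapResult",
    "overlap",
    "overlap_from_counts",
    "compare_overlap",
    "PlatformComparison",
    "compare_all_platforms",
    "mean_proportion",
]


@dataclass(frozen=True)
class OverlapResult:
    """Selected-SNP content of one SNP set, as a percentage."""

    label: str
    n_snps: int
    n_selected: int

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError(f"{self.label!r}: empty SNP set")
        if not 0 <= self.n_selected <= self.n_snps:
            raise ValueError(f"{self.label!r}: n_selected outside [0, n_snps]")

    @property
    def proportion(self) -> float:
        return self.n_selected / self.n_snps

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion

    @property
    def se_pct(self) -> float:
        return 100.0 * binomial_se(self.proportion, self.n_snps)


def overlap(manifest: PlatformManifest, selected: SelectedSnpSet) -> OverlapResult:
    """Count and proportion of manifest SNPs present in the selected set."""
    n_selected = len(manifest.snp_ids & selected.snp_ids)
    return OverlapResult(label=manifest.name, n_snps=len(manifest), n_selected=n_selected)


def overlap_from_counts(label: str, n_snps: int, n_selected: int) -> OverlapResult:
    """Build an OverlapResult from published counts instead of id sets."""
    return OverlapResult(label=label, n_snps=n_snps, n_selected=n_selected)


def compare_overlap(a: OverlapResult, b: OverlapResult) -> TestResult:
    """2x2 chi-square (selected vs not) x (group a vs b), 1 df, no
    continuity correction."""
    table = [
        [a.n_selected, a.n_snps - a.n_selected],
        [b.n_selected, b.n_snps - b.n_selected],
    ]
    return chi2_2x2(table)


@dataclass(frozen=True)
class PlatformComparison:
    platform: str
    result: OverlapResult
    statistic: float
    p_raw: float
    p_adjusted: float
    significant_raw: bool
    significant_adjusted: bool


def compare_all_platforms(
    platform_results: Sequence[OverlapResult],
    gwas_result: OverlapResult,
    alpha: float = 0.05,
) -> list[PlatformComparison]:
    """Chi-square of each platform against the GWAS-reported set, with
    Bonferroni adjustment (p_adj = min(1, p * k) for k platforms)."""
    if len(platform_results) < 2:
        raise ValueError("need at least 2 platforms")
    k = len(platform_results)
    comparisons = []
    for res in platform_results:
        test = compare_overlap(res, gwas_result)
        p_adj = min(1.0, test.p_value * k) if test.computable else float("nan")
        comparisons.append(
            PlatformComparison(
                platform=res.label,
                result=res,
                statistic=test.statistic,
                p_raw=test.p_value,
                p_adjusted=p_adj,
                significant_raw=test.computable and test.p_value < alpha,
                significant_adjusted=test.computable and p_adj < alpha,
            )
        )
    return comparisons


def mean_proportion(results: Iterable[OverlapResult]) -> tuple[float, float]:
    """Unweighted mean of the platform percentages and its SD (pct points)."""
    pcts = [r.proportion_pct for r in results]
    if len(pcts) < 2:
        raise ValueError("need at least 2 results")
    mean = sum(pcts) / len(pcts)
    var = sum((x - mean) ** 2 for x in pcts) / (len(pcts) - 1)
    return mean, math.sqrt(var)
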