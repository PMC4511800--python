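"""Bundled published summary tables.

Three small reference tables ship with the package, transcribed from the
published study of negative selection on GWAS risk alleles:

* per-disease PubMed abstract co-occurrence counts for the 44 diseases
  with an environment/lifestyle index (with the reported, 1-decimal ELI
  values alongside for validation);
* SNP counts and positively-selected SNP counts for the 10 most used
  genotyping platforms (with reported percentage and SE columns, and a
  ``consistent`` flag marking the two rows whose printed percentage does
  not follow from the printed counts);
* the reported per-disease MiRA proportions with sample sizes and SEs
  (``consistent`` flags the one row whose printed SE is not reproducible
  from its printed proportion and count under any SE convention).

The counts in these tables are *inputs* to the pipeline; reported
percentages/indices are only used to validate recomputation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .tables_io import LiteratureCounts

__all__ = [
    "reference_literature_counts",
    "reference_eli_reported",
    "PlatformRow",
    "reference_platform_rows",
    "MiraRow",
    "reference_mira_rows",
]


def _rows(filename: str) -> list[dict[str, str]]:
    source = resources.files("riskspectra.data").joinpath(filename)
    with source.open(encoding="utf-8") as handle:
        return list(csv.DictReader(handle, delimiter="\t"))


def reference_literature_counts() -> list[LiteratureCounts]:
    """Published abstract counts for the 44 GWAS-studied diseases."""
    return [
        LiteratureCounts(
            disease=row["disease"],
            n_disease=int(row["n_disease"]),
            n_env=int(row["n_env"]),
            n_lifestyle=int(row["n_lifestyle"]),
        )
        for row in _rows("literature_counts.tsv")
    ]


def reference_eli_reported() -> dict[str, float]:
    """Reported ELI per disease (1-decimal presentation values)."""
    return {row["disease"]: float(row["eli"]) for row in _rows("eli_reported.tsv")}


@dataclass(frozen=True)
class PlatformRow:
    platform: str
    n_snps: int
    n_selected: int
    pct_reported: float
    se_reported: float
    consistent: bool


def reference_platform_rows() -> list[PlatformRow]:
    """Published platform SNP counts and selected-SNP counts."""
    return [
        PlatformRow(
            platform=row["platform"],
            n_snps=int(row["n_snps"]),
            n_selected=int(row["n_selected"]),
            pct_reported=float(row["pct_reported"]),
            se_reported=float(row["se_reported"]),
            consistent=row["consistent"] == "1",
        )
        for row in _rows("platform_selection.tsv")
    ]


@dataclass(frozen=True)
class MiraRow:
    disease: str
    mira: float
    n_snps: int
    se_reported: float
    consistent: bool


def reference_mira_rows() -> list[MiraRow]:
    """Published per-disease MiRA proportions (p, n, SE)."""
    return [
        MiraRow(
            disease=row["disease"],
            mira=float(row["mira"]),
            n_snps=int(row["n_snps"]),
            se_reported=float(row["se_reported"]),
            consistent=row["consistent"] == "1",
        )
        for row in _rows("mira_by_disease.tsv")
    ]
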