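"""End-to-end orchestration: inputs -> ELI/tertiles -> MiRA/spectra ->
overlap -> statistical tests -> TSV report bundle.

Every stage delegates to the library modules; this module only wires
them together, applies the record-level filters (association p-value
threshold, minimum group sizes), joins diseases between tables, and
serializes results. A run log accounts for every record dropped by every
filter, so input = kept + dropped at each stage.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import eli as eli_mod
from . import mira as mira_mod
from . import overlap as overlap_mod
from .stats import TestResult, anova_binary, spearman
from .tables_io import (
    AssociationRecord,
    normalize_disease,
    read_association_table,
    read_literature_counts,
    read_manifest,
    read_selected,
)
from .tables_io import PlatformManifest, SelectedSnpSet

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and thresholds of one pipeline run.

    ``gwas_snps`` may be None: the GWAS SNP set then defaults to the
    association table's rsIDs. ``manifests`` lists platform SNP files.
    """

    association: Path
    literature_counts: Path
    manifests: tuple[Path, ...] = ()
    selected: Path | None = None
    gwas_snps: Path | None = None
    outdir: Path | None = None
    p_threshold: float = 5e-8
    min_snps_mira: int = 20
    min_snps_spectrum: int = 50
    n_tertiles: int = 3
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.min_snps_mira <= 0 or self.min_snps_spectrum <= 0:
            raise ValueError("thresholds must be positive")
        if self.n_tertiles < 2:
            raise ValueError("n_tertiles must be >= 2")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML key-value config file into a PipelineConfig.

    Keys mirror the dataclass fields; paths are resolved relative to the
    config file's directory.
    """
    import yaml

    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    base = path.parent

    def _path(key: str) -> Path | None:
        return base / raw[key] if key in raw and raw[key] is not None else None

    kwargs: dict = {}
    for key in ("association", "literature_counts", "selected", "gwas_snps", "outdir"):
        value = _path(key)
        if value is not None:
            kwargs[key] = value
    if "manifests" in raw:
        kwargs["manifests"] = tuple(base / m for m in raw["manifests"])
    for key in ("p_threshold", "alpha"):
        if key in raw:
            kwargs[key] = float(raw[key])
    for key in ("min_snps_mira", "min_snps_spectrum", "n_tertiles", "seed"):
        if key in raw:
            kwargs[key] = int(raw[key])
    return PipelineConfig(**kwargs)


@dataclass
class PipelineReport:
    """In-memory results of a run; ``tables`` maps report name -> DataFrame."""

    config: PipelineConfig
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    tests: list[TestResult] = field(default_factory=list)
    log_lines: list[str] = field(default_factory=list)

    def log(self, message: str) -> None:
        logger.info(message)
        self.log_lines.append(message)


def _filter_by_p(records: Sequence[AssociationRecord], threshold: float, report: PipelineReport):
    kept, dropped, unknown = [], 0, 0
    for rec in records:
        if rec.p_value is None:
            unknown += 1
            kept.append(rec)
        elif rec.p_value <= threshold:
            kept.append(rec)
        else:
            dropped += 1
    report.log(
        f"p-value filter (<= {threshold:g}): input={len(records)} kept={len(kept)} "
        f"dropped={dropped} (unknown p kept: {unknown})"
    )
    return kept


def _dedup(records: Sequence[AssociationRecord], report: PipelineReport):
    """One record per (disease, SNP): the smallest reported p-value wins,
    ties (and unknown p) resolved by input order."""
    best: dict[tuple[str, str], AssociationRecord] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (normalize_disease(rec.disease), rec.snp_id)
        if key not in best:
            best[key] = rec
            order.append(key)
        else:
            old_p = best[key].p_value
            new_p = rec.p_value
            if new_p is not None and (old_p is None or new_p < old_p):
                best[key] = rec
    kept = [best[key] for key in order]
    report.log(
        f"dedup (disease, snp_id): input={len(records)} kept={len(kept)} "
        f"dropped={len(records) - len(kept)}"
    )
    return kept


def _spectrum_rows(label: str, freqs, rows: list[dict]) -> None:
    observed = mira_mod.bin_spectrum(freqs)
    null = mira_mod.neutral_null_spectrum(freqs)
    shift = mira_mod.spectrum_asymmetry(observed, null)
    for kind, spec in (("observed", observed), ("null", null)):
        rows.append(
            {
                "group": label,
                "kind": kind,
                **{f"bin{i + 1}": p for i, p in enumerate(spec.proportions)},
                "n_snps": spec.n_snps,
                "left_shift": shift if kind == "observed" else 0.0,
            }
        )


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every stage and (when ``config.outdir`` is set) write the TSV
    report bundle plus ``run_log.txt``."""
    report = PipelineReport(config=config)
    records = read_association_table(config.association)
    report.log(f"association table: {len(records)} records")
    counts = read_literature_counts(config.literature_counts)
    report.log(f"literature counts: {len(counts)} diseases")

    records = _filter_by_p(records, config.p_threshold, report)
    records = _dedup(records, report)

    # --- ELI and tertiles -------------------------------------------------
    eli_records = eli_mod.eli_table(counts)
    eli_records = eli_mod.assign_tertiles(eli_records, config.n_tertiles)
    eli_by_disease = {normalize_disease(r.disease): r for r in eli_records}
    eli_df = pd.DataFrame(
        {
            "disease": [r.disease for r in eli_records],
            "eli": [round(r.eli, 1) for r in eli_records],
            "eeli": [None if r.eeli is None else round(r.eeli, 1) for r in eli_records],
            "tertile": [r.tertile for r in eli_records],
        }
    ).sort_values("eli", ascending=False, kind="mergesort", ignore_index=True)
    report.tables["eli"] = eli_df

    # --- MiRA by disease --------------------------------------------------
    by_disease: dict[str, list[AssociationRecord]] = {}
    for rec in records:
        by_disease.setdefault(normalize_disease(rec.disease), []).append(rec)
    mira_rows = []
    for key, group in by_disease.items():
        if len(group) < config.min_snps_mira:
            continue
        summary = mira_mod.mira_summary(group, label=group[0].disease)
        mira_rows.append(
            {
                "disease": summary.label,
                "mira": round(summary.mira_proportion, 2),
                "n_snps": summary.n_snps,
                "se": round(summary.se, 2),
            }
        )
    report.log(
        f"MiRA table: {len(mira_rows)} diseases with >= {config.min_snps_mira} SNPs "
        f"(of {len(by_disease)})"
    )
    mira_df = pd.DataFrame(
        mira_rows, columns=["disease", "mira", "n_snps", "se"]
    ).sort_values(
        ["n_snps", "disease"], ascending=[False, True], kind="mergesort", ignore_index=True
    )
    report.tables["mira_by_disease"] = mira_df

    eligible = {normalize_disease(d) for d in mira_df["disease"]} if len(mira_df) else set()
    if len(eligible) >= 2:
        indicator, labels = [], []
        for key in sorted(eligible):
            for rec in by_disease[key]:
                indicator.append(int(mira_mod.is_minor(rec.risk_allele_freq)))
                labels.append(key)
        report.tests.append(
            dataclasses.replace(anova_binary(indicator, labels), name="anova_mira_by_disease")
        )

    # --- MiRA by tertile and ELI correlations -----------------------------
    joined = [
        (rec, eli_by_disease[normalize_disease(rec.disease)])
        for rec in records
        if normalize_disease(rec.disease) in eli_by_disease
    ]
    report.log(
        f"disease join: {len(joined)} of {len(records)} association records have an ELI"
    )
    tertile_rows = []
    for tertile in range(1, config.n_tertiles + 1):
        group = [rec for rec, er in joined if er.tertile == tertile]
        if not group:
            continue
        summary = mira_mod.mira_summary(group, label=f"tertile_{tertile}")
        tertile_rows.append(
            {
                "tertile": tertile,
                "mira": round(summary.mira_proportion, 2),
                "n_snps": summary.n_snps,
                "se": round(summary.se, 2),
            }
        )
    report.tables["mira_by_tertile"] = pd.DataFrame(
        tertile_rows, columns=["tertile", "mira", "n_snps", "se"]
    )
    if len(tertile_rows) >= 2:
        indicator = [int(mira_mod.is_minor(rec.risk_allele_freq)) for rec, er in joined]
        labels = [er.tertile for _, er in joined]
        report.tests.append(
            dataclasses.replace(anova_binary(indicator, labels), name="anova_mira_by_tertile")
        )
    if len(joined) >= 3:
        freqs = [rec.risk_allele_freq for rec, _ in joined]
        elis = [er.eli for _, er in joined]
        report.tests.append(
            dataclasses.replace(spearman(elis, freqs), name="spearman_eli_vs_risk_freq")
        )

    with_n = [rec for rec in records if rec.sample_size is not None]
    if len(with_n) >= 3:
        rho_rare, rho_minor = mira_mod.mira_vs_sample_size(records)
        report.tests.append(dataclasses.replace(rho_rare, name="spearman_sample_size_vs_rare"))
        report.tests.append(dataclasses.replace(rho_minor, name="spearman_sample_size_vs_minor"))

    # --- spectra ----------------------------------------------------------
    spectrum_rows: list[dict] = []
    for tertile in range(1, config.n_tertiles + 1):
        freqs = [rec.risk_allele_freq for rec, er in joined if er.tertile == tertile]
        if len(freqs) >= config.min_snps_spectrum:
            _spectrum_rows(f"tertile_{tertile}", freqs, spectrum_rows)
    for key in sorted(by_disease):
        group = by_disease[key]
        if len(group) >= config.min_snps_spectrum:
            _spectrum_rows(group[0].disease, [r.risk_allele_freq for r in group], spectrum_rows)
    report.tables["spectra"] = pd.DataFrame(
        spectrum_rows,
        columns=["group", "kind", "bin1", "bin2", "bin3", "bin4", "bin5", "n_snps", "left_shift"],
    )

    # --- selection overlap ------------------------------------------------
    if config.manifests and config.selected is not None:
        selected = read_selected(config.selected)
        manifests = [read_manifest(p) for p in config.manifests]
        platform_results = [overlap_mod.overlap(m, selected) for m in manifests]
        if config.gwas_snps is not None:
            gwas_manifest = read_manifest(config.gwas_snps, name="GWAS")
        else:
            gwas_manifest = PlatformManifest(
                name="GWAS", snp_ids=frozenset(rec.snp_id for rec in records)
            )
        gwas_result = overlap_mod.overlap(gwas_manifest, selected)
        all_results = platform_results + [gwas_result]
        report.tables["overlap"] = pd.DataFrame(
            {
                "label": [r.label for r in all_results],
                "n_snps": [r.n_snps for r in all_results],
                "n_selected": [r.n_selected for r in all_results],
                "pct": [round(r.proportion_pct, 2) for r in all_results],
                "se_pct": [round(r.se_pct, 2) for r in all_results],
            }
        )
        if len(platform_results) >= 2:
            comparisons = overlap_mod.compare_all_platforms(
                platform_results, gwas_result, alpha=config.alpha
            )
            report.tables["overlap_comparisons"] = pd.DataFrame(
                {
                    "platform": [c.platform for c in comparisons],
                    "chi2": [c.statistic for c in comparisons],
                    "p_raw": [c.p_raw for c in comparisons],
                    "p_adjusted": [c.p_adjusted for c in comparisons],
                    "significant_raw": [c.significant_raw for c in comparisons],
                    "significant_adjusted": [c.significant_adjusted for c in comparisons],
                }
            )
            mean, sd = overlap_mod.mean_proportion(platform_results)
            report.log(
                f"platform mean selected pct: {mean:.2f}% +/- {sd:.2f}% "
                f"(GWAS set: {gwas_result.proportion_pct:.2f}%)"
            )

    # --- test results table ----------------------------------------------
    report.tables["tests"] = pd.DataFrame(
        {
            "test": [t.name for t in report.tests],
            "statistic": [t.statistic for t in report.tests],
            "df": [str(t.df) for t in report.tests],
            "p_value": [t.p_value for t in report.tests],
            "n": [t.n for t in report.tests],
            "computable": [t.computable for t in report.tests],
            "note": [t.note for t in report.tests],
        }
    )

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, frame in report.tables.items():
            frame.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        (outdir / "run_log.txt").write_text("\n".join(report.log_lines) + "\n", encoding="utf-8")
    return report
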