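"""Synthetic input generator with controlled statistical structure.

Every pipeline input — association table, literature counts, platform
manifests, selected-SNP list, GWAS SNP list — can be generated from a
:class:`GeneratorSpec` whose parameters are the quantities the pipeline
later estimates, enabling parameter-recovery tests:

* per-disease left-shift strength delta in [0,1]: the risk allele is the
  minor allele with probability 1/2 + delta/2, so the expected MiRA
  proportion is 0.5 + delta/2 (delta = 0 is the frequency-independence
  null);
* per-disease true ELI: co-occurrence counts are Poisson with mean
  true_eli * n_pubs / 1000, split binomially between "environment" and
  "lifestyle", so the estimated ELI is unbiased for the true rate;
* a SNP universe with a true selected fraction q and an optional
  enrichment e of selected SNPs among GWAS-reported ones (expected
  overlap proportion q under the null, q*e under enrichment).

MAFs follow a bell-shaped Beta(2,2) rescaled to (0.05, 0.5), mimicking
the ascertainment of GWAS-detected SNPs toward common variants. A
``rare_coupling`` knob makes larger studies likelier to report rare
(MAF <= 0.05) SNPs without touching risk-direction assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .tables_io import (
    AssociationRecord,
    LiteratureCounts,
    PlatformManifest,
    SelectedSnpSet,
    write_association_table,
    write_literature_counts,
    write_snp_list,
)

__all__ = [
    "GeneratorSpec",
    "delta_from_eli",
    "gen_association_table",
    "gen_literature_counts",
    "gen_platform_and_selected",
    "write_bundle",
]

_STREAM_ASSOC, _STREAM_COUNTS, _STREAM_SNPSETS = 1, 2, 3


@dataclass(frozen=True)
class GeneratorSpec:
    """All knobs of the synthetic-data model (see module docstring).

    ``true_eli`` and ``delta`` may be scalars (shared by all diseases),
    sequences of length ``n_diseases``, or None: ELIs then span 10..110
    per 1,000 abstracts evenly, and delta follows the decreasing linear
    map :func:`delta_from_eli`, reproducing the qualitative gradient of
    stronger left-shift for environment/lifestyle-independent diseases.
    """

    n_diseases: int = 10
    snps_per_disease: tuple[int, int] = (30, 150)
    true_eli: float | Sequence[float] | None = None
    delta: float | Sequence[float] | None = None
    n_disease_pubs: int = 100_000
    with_exposure: bool = False
    exposure_ratio: float = 0.5  # exposure co-occurrence rate relative to ELI
    universe_size: int = 50_000
    platform_sizes: tuple[int, ...] = (20_000, 30_000, 25_000)
    selected_fraction: float = 0.0075
    gwas_enrichment: float = 1.0
    n_gwas_snps: int = 1_000
    maf_beta: tuple[float, float] = (2.0, 2.0)
    maf_range: tuple[float, float] = (0.05, 0.5)
    rare_coupling: float = 0.0
    rare_maf_range: tuple[float, float] = (0.005, 0.05)
    sample_size_range: tuple[int, int] = (2_000, 200_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diseases < 1:
            raise ValueError("n_diseases >= 1 required")
        lo, hi = self.snps_per_disease
        if not 1 <= lo <= hi:
            raise ValueError("snps_per_disease must be an increasing positive range")
        if not 0.0 <= self.selected_fraction <= 1.0:
            raise ValueError("selected_fraction must lie in [0,1]")
        if self.selected_fraction * self.gwas_enrichment > 1.0:
            raise ValueError("enrichment * selected_fraction exceeds 1")
        for d in self.deltas():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"delta must lie in [0,1], got {d}")

    def elis(self) -> np.ndarray:
        if self.true_eli is None:
            return np.linspace(10.0, 110.0, self.n_diseases)
        arr = np.atleast_1d(np.asarray(self.true_eli, dtype=float))
        if arr.size == 1:
            return np.full(self.n_diseases, arr[0])
        if arr.size != self.n_diseases:
            raise ValueError("true_eli length must equal n_diseases")
        return arr

    def deltas(self) -> np.ndarray:
        if self.delta is None:
            return delta_from_eli(self.elis())
        arr = np.atleast_1d(np.asarray(self.delta, dtype=float))
        if arr.size == 1:
            return np.full(self.n_diseases, arr[0])
        if arr.size != self.n_diseases:
            raise ValueError("delta length must equal n_diseases")
        return arr

    def disease_names(self) -> list[str]:
        width = len(str(self.n_diseases))
        return [f"disease_{i + 1:0{width}d}" for i in range(self.n_diseases)]


def delta_from_eli(eli: np.ndarray, delta_max: float = 0.4) -> np.ndarray:
    """Decreasing linear map from ELI to left-shift strength.

    The highest-ELI (most environment/lifestyle-dependent) disease gets
    delta = 0 (selectively neutral spectrum), the lowest-ELI disease gets
    ``delta_max``; ELIs in between interpolate linearly.
    """
    eli = np.asarray(eli, dtype=float)
    lo, hi = eli.min(), eli.max()
    if hi == lo:
        return np.full(eli.shape, delta_max / 2.0)
    return delta_max * (hi - eli) / (hi - lo)


def _rng(spec: GeneratorSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def gen_association_table(
    spec: GeneratorSpec, snp_ids: Sequence[str] | None = None
) -> list[AssociationRecord]:
    """Generate the association table (see module docstring for the model).

    ``snp_ids`` optionally supplies rsIDs (e.g. the GWAS subset of a
    generated SNP universe); by default sequential fresh ids are used.
    """
    rng = _rng(spec, _STREAM_ASSOC)
    deltas = spec.deltas()
    a, b = spec.maf_beta
    maf_lo, maf_hi = spec.maf_range
    n_lo, n_hi = spec.sample_size_range
    records: list[AssociationRecord] = []
    counter = 0
    for disease, delta in zip(spec.disease_names(), deltas):
        n_snps = int(rng.integers(spec.snps_per_disease[0], spec.snps_per_disease[1] + 1))
        maf = maf_lo + (maf_hi - maf_lo) * rng.beta(a, b, size=n_snps)
        sample_size = np.exp(rng.uniform(math.log(n_lo), math.log(n_hi), size=n_snps))
        if spec.rare_coupling > 0:
            # larger studies can see rare SNPs: swap-in rare MAFs with a
            # probability that grows with log sample size
            size_frac = (np.log(sample_size) - math.log(n_lo)) / (math.log(n_hi) - math.log(n_lo))
            make_rare = rng.uniform(size=n_snps) < spec.rare_coupling * size_frac
            maf = np.where(
                make_rare, rng.uniform(*spec.rare_maf_range, size=n_snps), maf
            )
        risk_is_minor = rng.uniform(size=n_snps) < 0.5 + delta / 2.0
        freq = np.where(risk_is_minor, maf, 1.0 - maf)
        p_values = 10.0 ** rng.uniform(-30.0, math.log10(5e-8), size=n_snps)
        for i in range(n_snps):
            counter += 1
            if snp_ids is None:
                snp_id = f"rs{1000000 + counter}"
            elif counter <= len(snp_ids):
                snp_id = snp_ids[counter - 1]
            else:
                raise ValueError("snp_ids shorter than the number of generated records")
            records.append(
                AssociationRecord(
                    disease=disease,
                    snp_id=snp_id,
                    risk_allele_freq=float(freq[i]),
                    sample_size=int(round(sample_size[i])),
                    p_value=float(p_values[i]),
                )
            )
    return records


def gen_literature_counts(spec: GeneratorSpec) -> list[LiteratureCounts]:
    """Poisson co-occurrence counts with per-disease mean
    true_eli * n_pubs / 1000, split Binomial(1/2) between terms."""
    rng = _rng(spec, _STREAM_COUNTS)
    records = []
    for disease, eli in zip(spec.disease_names(), spec.elis()):
        mean = eli * spec.n_disease_pubs / 1000.0
        total = int(min(rng.poisson(mean), spec.n_disease_pubs))
        n_env = int(rng.binomial(total, 0.5)) if total else 0
        n_exposure = None
        if spec.with_exposure:
            mean_exp = spec.exposure_ratio * mean
            n_exposure = int(min(rng.poisson(mean_exp), spec.n_disease_pubs))
        records.append(
            LiteratureCounts(
                disease=disease,
                n_disease=spec.n_disease_pubs,
                n_env=n_env,
                n_lifestyle=total - n_env,
                n_exposure=n_exposure,
            )
        )
    return records


def gen_platform_and_selected(
    spec: GeneratorSpec,
) -> tuple[list[PlatformManifest], SelectedSnpSet, frozenset[str]]:
    """SNP universe with a true selected fraction q, platform manifests
    sampled uniformly, and a GWAS-reported subset.

    In null mode (``gwas_enrichment`` = 1) the GWAS subset is uniform, so
    its expected selected proportion equals q, same as the platforms.
    With enrichment e > 1 selected SNPs are e times as likely to be
    GWAS-reported per draw; because sampling is without replacement the
    realized proportion approaches q*e only when q and the sampling
    fraction n_gwas_snps/universe_size are both small, and is diluted
    otherwise.
    """
    rng = _rng(spec, _STREAM_SNPSETS)
    universe = np.array([f"rs{i + 1}" for i in range(spec.universe_size)])
    n_selected = int(round(spec.selected_fraction * spec.universe_size))
    selected_idx = rng.choice(spec.universe_size, size=n_selected, replace=False)
    selected = SelectedSnpSet(snp_ids=frozenset(universe[selected_idx]))
    manifests = []
    for j, size in enumerate(spec.platform_sizes, start=1):
        if size > spec.universe_size:
            raise ValueError("platform size exceeds universe")
        idx = rng.choice(spec.universe_size, size=size, replace=False)
        manifests.append(PlatformManifest(name=f"platform_{j}", snp_ids=frozenset(universe[idx])))
    if spec.n_gwas_snps > spec.universe_size:
        raise ValueError("n_gwas_snps exceeds universe")
    weights = np.ones(spec.universe_size)
    if spec.gwas_enrichment != 1.0:
        weights[selected_idx] = spec.gwas_enrichment
    weights /= weights.sum()
    gwas_idx = rng.choice(spec.universe_size, size=spec.n_gwas_snps, replace=False, p=weights)
    return manifests, selected, frozenset(universe[gwas_idx])


def write_bundle(spec: GeneratorSpec, outdir: str | Path) -> dict[str, Path]:
    """Write a complete, mutually consistent input bundle.

    The association table's rsIDs are drawn from the generated GWAS
    subset of the SNP universe (sorted for byte-stable output), so the
    overlap stage of the pipeline can score the same SNPs the association
    stage analyses. Returns a name -> path map of everything written.
    """
    import dataclasses

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = gen_association_table(spec)
    # size the GWAS subset to the table so every record gets a universe rsID
    snp_spec = dataclasses.replace(spec, n_gwas_snps=max(spec.n_gwas_snps, len(records)))
    manifests, selected, gwas_ids = gen_platform_and_selected(snp_spec)
    gwas_sorted = sorted(gwas_ids)
    records = [
        dataclasses.replace(rec, snp_id=gwas_sorted[i]) for i, rec in enumerate(records)
    ]
    counts = gen_literature_counts(spec)
    paths: dict[str, Path] = {}
    paths["association"] = outdir / "association.tsv"
    write_association_table(records, paths["association"])
    paths["literature_counts"] = outdir / "literature_counts.tsv"
    write_literature_counts(counts, paths["literature_counts"])
    manifest_dir = outdir / "manifests"
    manifest_dir.mkdir(exist_ok=True)
    for manifest in manifests:
        path = manifest_dir / f"{manifest.name}.txt"
        write_snp_list(manifest.snp_ids, path)
        paths[manifest.name] = path
    paths["selected"] = outdir / "selected.txt"
    write_snp_list(selected.snp_ids, paths["selected"])
    paths["gwas_snps"] = outdir / "gwas_snps.txt"
    write_snp_list(gwas_ids, paths["gwas_snps"])
    return paths
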