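"""Minor-risk-allele (MiRA) statistics and binned risk-allele frequency spectra.

Negative selection against risk alleles pushes their frequencies down.
Two estimators of that left-shift are implemented: the MiRA proportion
(fraction of risk alleles that are minor, i.e. frequency < 0.5; expected
0.5 when the chance of being risk-associated is frequency-independent),
and the 5-bin risk-allele frequency spectrum compared against an
empirical frequency-independence null built by mirroring each SNP's
allele frequency with weight one half.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .stats import TestResult, spearman
from .tables_io import AssociationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "BIN_EDGES",
    "RARE_MAF_THRESHOLD",
    "MiraSummary",
    "SpectrumBins",
    "is_minor",
    "minor_allele_freq",
    "binomial_se",
    "mira_summary",
    "bin_spectrum",
    "neutral_null_spectrum",
    "spectrum_asymmetry",
    "mira_vs_sample_size",
]

#: Fixed partition of (0,1): 0<F<0.2, 0.2<=F<0.4, 0.4<=F<0.6, 0.6<=F<0.8, 0.8<F<1.
BIN_EDGES: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

#: A SNP is "rare" when its minor allele frequency is at or below this.
RARE_MAF_THRESHOLD = 0.05


def _check_freq(freq: float) -> None:
    if not 0.0 < freq < 1.0:
        raise ValueError(f"allele frequency must lie strictly in (0,1), got {freq}")


def is_minor(freq: float) -> bool:
    """True iff the allele is minor, i.e. its frequency is below 50%.

    Exactly 0.5 counts as non-minor: minority is defined by "< 50%", so an
    allele at one half is neither minor nor major and is scored 0 here
    (logged, because it is a boundary case the data rarely hits).
    """
    _check_freq(freq)
    if freq == 0.5:
        logger.info("allele frequency exactly 0.5 scored as non-minor")
        return False
    return freq < 0.5


def minor_allele_freq(freq: float) -> float:
    """MAF = min(F, 1-F)."""
    _check_freq(freq)
    return min(freq, 1.0 - freq)


def binomial_se(p: float, n: int, *, ddof: int = 0) -> float:
    """Standard error of a proportion, sqrt(p(1-p)/(n-ddof)).

    ``ddof=0`` is the plain binomial SE. ``ddof=1`` is the sample-variance
    convention some statistical packages report when averaging a 0/1
    indicator; it is the convention that reproduces the per-disease SEs in
    the published MiRA table.
    """
    if n - ddof <= 0:
        raise ValueError("need n - ddof > 0")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0,1], got {p}")
    return math.sqrt(p * (1.0 - p) / (n - ddof))


@dataclass(frozen=True)
class MiraSummary:
    """MiRA proportion for one disease (or disease group)."""

    label: str
    n_snps: int
    mira_proportion: float
    se: float


@dataclass(frozen=True)
class SpectrumBins:
    """Normalized 5-bin risk-allele frequency spectrum.

    ``proportions`` sum to 1 when ``n_snps`` > 0; ``n_snps`` is the number
    of SNPs behind the spectrum (a mirrored null keeps the original count,
    each SNP contributing half a unit of weight to each of its alleles).
    """

    edges: tuple[float, ...]
    proportions: tuple[float, ...]
    n_snps: int

    def __post_init__(self) -> None:
        if len(self.proportions) != len(self.edges) - 1:
            raise ValueError("proportions must have one entry per bin")
        if self.n_snps > 0 and not math.isclose(
            sum(self.proportions), 1.0, rel_tol=0, abs_tol=1e-9
        ):
            raise ValueError("proportions must sum to 1")

    def low_frequency_mass(self) -> float:
        """Total mass in the two lowest-frequency bins (F < 0.4)."""
        return self.proportions[0] + self.proportions[1]


def mira_summary(records: Sequence[AssociationRecord], label: str = "") -> MiraSummary:
    """MiRA proportion p = (# risk alleles with F < 0.5) / n with its
    binomial SE, for one group of association records."""
    if not records:
        raise ValueError("mira_summary needs at least one record")
    n = len(records)
    minors = sum(is_minor(rec.risk_allele_freq) for rec in records)
    p = minors / n
    return MiraSummary(
        label=label or records[0].disease,
        n_snps=n,
        mira_proportion=p,
        se=binomial_se(p, n),
    )


def _bin_index(freq: float) -> int:
    # first bin is open at 0; from the second bin on the lower edge is closed
    _check_freq(freq)
    idx = int(freq / 0.2)
    return min(idx, 4)


def bin_spectrum(freqs: Sequence[float], weights: Sequence[float] | None = None) -> SpectrumBins:
    """Bin frequencies into the fixed 5-bin partition of (0,1).

    Bins are half-open with the lower edge closed from the second bin on
    (so F = 0.2 lands in the second bin). ``weights`` default to 1 per
    frequency; proportions are normalized weights per bin.
    """
    freqs = np.asarray(list(freqs), dtype=float)
    if freqs.size == 0:
        raise ValueError("cannot bin an empty frequency list")
    if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
        bad = freqs[(freqs <= 0.0) | (freqs >= 1.0)][0]
        raise ValueError(f"frequency {bad} outside (0,1)")
    w = np.ones_like(freqs) if weights is None else np.asarray(list(weights), dtype=float)
    if w.shape != freqs.shape:
        raise ValueError("weights must match frequencies in length")
    idx = np.minimum((freqs / 0.2).astype(int), 4)
    counts = np.bincount(idx, weights=w, minlength=5)
    proportions = counts / w.sum()
    n_eff = int(round(w.sum()))
    return SpectrumBins(edges=BIN_EDGES, proportions=tuple(proportions), n_snps=n_eff)


def neutral_null_spectrum(freqs: Sequence[float]) -> SpectrumBins:
    """Frequency-independence null spectrum for the observed SNP set.

    Under the null the probability that an allele is risk-associated does
    not depend on its frequency, so each SNP's two alleles are equally
    likely to be the risk allele: each observed frequency f contributes
    weight 1/2 at f and 1/2 at 1-f. The result is symmetric under
    f -> 1-f and has MiRA proportion 0.5 whenever no f equals 0.5.
    """
    freqs = np.asarray(list(freqs), dtype=float)
    mirrored = np.concatenate([freqs, 1.0 - freqs])
    weights = np.full(mirrored.shape, 0.5)
    spectrum = bin_spectrum(mirrored, weights)
    return SpectrumBins(edges=spectrum.edges, proportions=spectrum.proportions, n_snps=len(freqs))


def spectrum_asymmetry(observed: SpectrumBins, null: SpectrumBins) -> float:
    """Left-shift score: observed minus null mass in the two lowest bins.

    Positive values mean the observed spectrum is shifted toward low
    frequencies relative to the frequency-independence null — the
    signature of negative selection against risk alleles.
    """
    if observed.edges != null.edges:
        raise ValueError("spectra built on different bin edges")
    return observed.low_frequency_mass() - null.low_frequency_mass()


def mira_vs_sample_size(records: Sequence[AssociationRecord]) -> tuple[TestResult, TestResult]:
    """Spearman correlations of GWAS sample size with SNP rarity and risk
    direction.

    Returns ``(rho_rare, rho_minor)``: sample size against the indicator
    MAF <= 0.05 (larger studies detect rarer SNPs) and against the
    minor-risk indicator (direction of effect should not depend on study
    size). Records without a sample size are dropped, with a logged count.
    """
    usable = [rec for rec in records if rec.sample_size is not None]
    dropped = len(records) - len(usable)
    if dropped:
        logger.info("mira_vs_sample_size: dropped %d records without sample_size", dropped)
    if len(usable) < 3:
        raise ValueError("need at least 3 records with sample_size")
    n = np.array([rec.sample_size for rec in usable], dtype=float)
    rare = np.array(
        [minor_allele_freq(rec.risk_allele_freq) <= RARE_MAF_THRESHOLD for rec in usable],
        dtype=float,
    )
    minor = np.array([is_minor(rec.risk_allele_freq) for rec in usable], dtype=float)
    return spearman(n, rare), spearman(n, minor)
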