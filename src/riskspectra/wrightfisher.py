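"""Forward Wright-Fisher simulator of recently neutral, currently
deleterious risk alleles.

The model: standing variation accumulates under neutrality; at t = 0 the
environment changes and every locus's risk allele acquires a selection
coefficient s (s > 0 = deleterious, s < 0 = advantageous). Each
generation applies the deterministic genic-selection update

    f* = f (1 - s) / (1 - s f)

followed by binomial drift in a diploid population of size N:
f' = Binomial(2N, f*) / 2N. Loci evolve independently (no linkage, no
recombination, constant N). The simulator records the MiRA proportion of
segregating loci every generation and the 5-bin risk-allele spectrum at
t = 0 and t = T, which is where the left-shift of the spectrum under
negative selection becomes visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .mira import SpectrumBins, bin_spectrum

__all__ = [
    "SimConfig",
    "SimResult",
    "constant_s",
    "gamma_s",
    "init_frequencies",
    "selection_update",
    "step",
    "run",
]

SDist = Callable[[np.random.Generator, int], np.ndarray]


def constant_s(s: float) -> SDist:
    """Selection-coefficient sampler: every locus gets the same s."""
    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, float(s))
    return sample


def gamma_s(shape: float, scale: float, sign: float = 1.0) -> SDist:
    """Gamma-distributed |s| with a common sign (default deleterious)."""
    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return sign * rng.gamma(shape, scale, size=n)
    return sample


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one forward run.

    ``s_dist`` draws one coefficient per locus at the environment change;
    sampled values must satisfy s < 1 (s >= 0 deleterious for the risk
    allele, negative values allowed for advantageous variants).
    ``init_mode`` is "uniform" (f ~ U(1/2N, 1-1/2N)) or "folded_neutral"
    (MAF with density proportional to 1/f on (1/2N, 0.5], risk allele
    assigned to the minor or major allele with probability 1/2 each).
    """

    n_loci: int = 5000
    pop_size: int = 10_000
    generations: int = 500
    s_dist: SDist = field(default_factory=lambda: constant_s(0.01))
    init_mode: str = "folded_neutral"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.pop_size < 1 or self.generations < 0:
            raise ValueError("n_loci >= 1, pop_size >= 1, generations >= 0 required")
        if self.init_mode not in ("uniform", "folded_neutral"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


@dataclass(frozen=True)
class SimResult:
    """Trajectories and endpoint spectra of one run."""

    config: SimConfig
    s_values: np.ndarray
    freq_t0: np.ndarray
    freq_tT: np.ndarray
    mira_trajectory: np.ndarray  # MiRA proportion of segregating loci, per generation
    spectrum_t0: SpectrumBins
    spectrum_tT: SpectrumBins


def init_frequencies(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw per-locus risk-allele frequencies at the environment change.

    folded_neutral inverts the CDF of the 1/f folded neutral density on
    (1/2N, 0.5]: MAF = a * (0.5/a)**u with a = 1/(2N), u ~ U(0,1). The
    risk label then lands on the minor or the major allele with equal
    probability, so the expected MiRA proportion at t = 0 is 0.5.
    """
    a = 1.0 / (2 * config.pop_size)
    if config.init_mode == "uniform":
        return rng.uniform(a, 1.0 - a, size=config.n_loci)
    maf = a * (0.5 / a) ** rng.uniform(size=config.n_loci)
    risk_is_minor = rng.uniform(size=config.n_loci) < 0.5
    return np.where(risk_is_minor, maf, 1.0 - maf)


def selection_update(freqs: np.ndarray, s_values: np.ndarray) -> np.ndarray:
    """Deterministic genic-selection step f* = f(1-s)/(1-sf)."""
    freqs = np.asarray(freqs, dtype=float)
    s = np.asarray(s_values, dtype=float)
    if np.any(s >= 1.0):
        raise ValueError("selection coefficient must satisfy s < 1")
    return freqs * (1.0 - s) / (1.0 - s * freqs)


def step(
    freqs: np.ndarray, s_values: np.ndarray, pop_size: int, rng: np.random.Generator
) -> np.ndarray:
    """One Wright-Fisher generation: selection then binomial drift.

    Fixed loci (f = 0 or 1) are absorbing under both parts of the update.
    """
    expected = selection_update(freqs, s_values)
    return rng.binomial(2 * pop_size, expected) / (2.0 * pop_size)


def _mira_of(freqs: np.ndarray) -> float:
    """MiRA proportion among segregating loci (f strictly in (0,1));
    NaN when everything is fixed."""
    seg = (freqs > 0.0) & (freqs < 1.0)
    if not seg.any():
        return float("nan")
    return float((freqs[seg] < 0.5).mean())


def run(config: SimConfig) -> SimResult:
    """Run the forward simulation; bit-reproducible from config.seed."""
    rng = np.random.default_rng(config.seed)
    freqs = init_frequencies(config, rng)
    s_values = config.s_dist(rng, config.n_loci)
    if np.any(s_values >= 1.0):
        raise ValueError("s_dist produced s >= 1")
    freq_t0 = freqs.copy()
    mira = np.empty(config.generations + 1)
    mira[0] = _mira_of(freqs)
    for t in range(1, config.generations + 1):
        freqs = step(freqs, s_values, config.pop_size, rng)
        mira[t] = _mira_of(freqs)
    seg0 = (freq_t0 > 0) & (freq_t0 < 1)
    segT = (freqs > 0) & (freqs < 1)
    empty = SpectrumBins(edges=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0), proportions=(0.0,) * 5, n_snps=0)
    return SimResult(
        config=config,
        s_values=s_values,
        freq_t0=freq_t0,
        freq_tT=freqs,
        mira_trajectory=mira,
        spectrum_t0=bin_spectrum(freq_t0[seg0]),
        spectrum_tT=bin_spectrum(freqs[segT]) if segT.any() else empty,
    )
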