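"""MiRA proportions, 5-bin spectra, and the frequency-independence null."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from riskspectra.mira import (
    BIN_EDGES,
    bin_spectrum,
    binomial_se,
    is_minor,
    mira_summary,
    mira_vs_sample_size,
    neutral_null_spectrum,
    spectrum_asymmetry,
)
from riskspectra.reference import reference_mira_rows
from riskspectra.synthetic import GeneratorSpec, gen_association_table
from riskspectra.tables_io import AssociationRecord

FREQS = st.lists(
    st.floats(min_value=1e-6, max_value=1 - 1e-6, allow_nan=False), min_size=1, max_size=200
)


def record(freq, disease="d", snp="rs1", n=None):
    return AssociationRecord(disease, snp, freq, sample_size=n)


def test_is_minor_boundary_convention():
    assert is_minor(0.49)
    assert not is_minor(0.5)  # "<50%" definition: exactly half is not minor
    assert not is_minor(0.96)
    with pytest.raises(ValueError):
        is_minor(0.0)
    with pytest.raises(ValueError):
        is_minor(1.0)


def test_mira_summary_counts_match_brute_force():
    rng = np.random.default_rng(8)
    freqs = rng.uniform(0.01, 0.99, size=137)
    records = [record(f, snp=f"rs{i}") for i, f in enumerate(freqs)]
    summary = mira_summary(records)
    brute = sum(1 for f in freqs if f < 0.5) / len(freqs)
    assert summary.mira_proportion == pytest.approx(brute)
    assert summary.se == pytest.approx(
        math.sqrt(brute * (1 - brute) / len(freqs)), abs=1e-15
    )


def test_mira_summary_all_minor_gives_p1_se0():
    records = [record(0.1, snp=f"rs{i}") for i in range(10)]
    summary = mira_summary(records)
    assert summary.mira_proportion == 1.0 and summary.se == 0.0


def test_published_se_values_reproduce_from_p_and_n():
    """The published per-disease SEs follow the sample-variance convention
    sqrt(p(1-p)/(n-1)); the one internally inconsistent row is excluded."""
    rows = [r for r in reference_mira_rows() if r.consistent]
    assert len(rows) == 24
    for row in rows:
        assert round(binomial_se(row.mira, row.n_snps, ddof=1), 2) == row.se_reported, row.disease


def test_spec_examples_hold_under_plain_binomial_se():
    assert round(binomial_se(0.61, 151), 2) == 0.04  # Crohn's disease
    assert round(binomial_se(0.96, 27), 2) == 0.04  # chronic kidney disease
    assert round(binomial_se(0.45, 22), 2) == 0.11  # Graves' disease


@given(FREQS)
def test_bin_partition_property(freqs):
    spectrum = bin_spectrum(freqs)
    assert spectrum.edges == BIN_EDGES
    assert sum(spectrum.proportions) == pytest.approx(1.0, abs=1e-9)
    # brute-force tally: every frequency in exactly one bin
    for i in range(5):
        lo, hi = BIN_EDGES[i], BIN_EDGES[i + 1]
        count = sum(1 for f in freqs if (lo <= f < hi if i > 0 else lo < f < hi))
        assert spectrum.proportions[i] == pytest.approx(count / len(freqs), abs=1e-12)


def test_bin_edge_point_two_goes_to_second_bin():
    assert bin_spectrum([0.2]).proportions == (0.0, 1.0, 0.0, 0.0, 0.0)
    assert bin_spectrum([0.1] * 5).proportions == (1.0, 0.0, 0.0, 0.0, 0.0)


def test_bin_rejects_out_of_range():
    with pytest.raises(ValueError):
        bin_spectrum([0.5, 1.0])


def test_null_spectrum_is_mirror_symmetric_and_half_minor():
    rng = np.random.default_rng(10)
    freqs = rng.uniform(0.01, 0.99, size=500)
    null = neutral_null_spectrum(freqs)
    # mirror symmetry of the bins
    assert null.proportions[0] == pytest.approx(null.proportions[4], abs=1e-12)
    assert null.proportions[1] == pytest.approx(null.proportions[3], abs=1e-12)
    # brute-force oracle: duplicate-and-mirror then plain binning
    mirrored = list(freqs) + [1 - f for f in freqs]
    brute = bin_spectrum(mirrored)
    assert null.proportions == pytest.approx(brute.proportions, abs=1e-12)
    assert null.n_snps == 500


def test_null_spectrum_idempotent_on_symmetric_input():
    freqs = [0.1, 0.9, 0.3, 0.7, 0.25, 0.75]
    observed = bin_spectrum(freqs)
    null = neutral_null_spectrum(freqs)
    assert null.proportions == pytest.approx(observed.proportions, abs=1e-12)
    again = neutral_null_spectrum(list(freqs) + [1 - f for f in freqs])
    assert again.proportions == pytest.approx(null.proportions, abs=1e-12)


def test_asymmetry_zero_for_null_and_arithmetic_example():
    freqs = [0.1, 0.35, 0.55, 0.82]
    null = neutral_null_spectrum(freqs)
    assert spectrum_asymmetry(null, null) == pytest.approx(0.0)
    from riskspectra.mira import SpectrumBins

    obs = SpectrumBins(BIN_EDGES, (1.0, 0.0, 0.0, 0.0, 0.0), 10)
    nul = SpectrumBins(BIN_EDGES, (0.5, 0.0, 0.0, 0.0, 0.5), 10)
    assert spectrum_asymmetry(obs, nul) == pytest.approx(0.5)


def test_left_shifted_observed_scores_positive():
    rng = np.random.default_rng(3)
    freqs = rng.beta(2, 5, size=2000) * 0.98 + 0.01  # mass below 0.5
    observed = bin_spectrum(freqs)
    assert spectrum_asymmetry(observed, neutral_null_spectrum(freqs)) > 0


def test_sample_size_correlations_recover_generator_structure():
    spec = GeneratorSpec(
        n_diseases=1, snps_per_disease=(8000, 8000), delta=0.0, rare_coupling=0.6, seed=12
    )
    records = gen_association_table(spec)
    rho_rare, rho_minor = mira_vs_sample_size(records)
    assert rho_rare.computable and rho_rare.statistic > 0  # larger studies see rarer SNPs
    assert rho_rare.p_value < 1e-4
    assert abs(rho_minor.statistic) < 0.05  # risk direction independent of study size


def test_sample_size_correlation_degenerate_when_constant():
    records = [record(0.3, snp=f"rs{i}", n=5000) for i in range(10)]
    rho_rare, rho_minor = mira_vs_sample_size(records)
    assert not rho_rare.computable and not rho_minor.computable
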