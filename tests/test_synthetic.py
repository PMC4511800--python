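"""Synthetic-data generator: parameter recovery, generator-reader
contract, byte-stable output."""

import math

import numpy as np
import pytest

from riskspectra.mira import is_minor
from riskspectra.overlap import compare_overlap, overlap
from riskspectra.synthetic import (
    GeneratorSpec,
    delta_from_eli,
    gen_association_table,
    gen_literature_counts,
    gen_platform_and_selected,
    write_bundle,
)
from riskspectra.tables_io import (
    PlatformManifest,
    read_association_table,
    read_literature_counts,
    read_manifest,
    read_selected,
)


def mira_of(records):
    return np.mean([is_minor(r.risk_allele_freq) for r in records])


def test_null_mode_gives_half_minor():
    spec = GeneratorSpec(n_diseases=1, snps_per_disease=(10_000, 10_000), delta=0.0, seed=1)
    records = gen_association_table(spec)
    assert abs(mira_of(records) - 0.5) < 3 * math.sqrt(0.25 / len(records))


def test_delta_recovery_by_construction():
    spec = GeneratorSpec(n_diseases=1, snps_per_disease=(10_000, 10_000), delta=0.2, seed=2)
    records = gen_association_table(spec)
    assert abs(mira_of(records) - 0.6) < 3 * math.sqrt(0.25 / len(records))


def test_delta_one_makes_every_risk_allele_minor():
    spec = GeneratorSpec(n_diseases=2, snps_per_disease=(50, 80), delta=1.0, seed=3)
    assert mira_of(gen_association_table(spec)) == 1.0


def test_delta_from_eli_is_decreasing():
    eli = np.array([10.0, 60.0, 110.0])
    delta = delta_from_eli(eli)
    assert delta[0] > delta[1] > delta[2] == 0.0
    assert delta[0] == pytest.approx(0.4)


def test_true_eli_recovered_over_replicates():
    true_eli, n_pubs, n_reps = 16.4, 120_346, 200
    estimates = []
    for seed in range(n_reps):
        spec = GeneratorSpec(
            n_diseases=1, true_eli=true_eli, n_disease_pubs=n_pubs, seed=seed
        )
        c = gen_literature_counts(spec)[0]
        estimates.append((c.n_env + c.n_lifestyle) / c.n_disease * 1000)
    lam = true_eli * n_pubs / 1000
    se_mean = math.sqrt(lam) * (1000 / n_pubs) / math.sqrt(n_reps)
    assert abs(np.mean(estimates) - true_eli) < 2 * se_mean


def test_zero_eli_gives_zero_counts_and_rate_invariance():
    spec = GeneratorSpec(n_diseases=1, true_eli=0.0, seed=4)
    c = gen_literature_counts(spec)[0]
    assert c.n_env == 0 and c.n_lifestyle == 0
    # expected ELI independent of publication volume
    means = []
    for n_pubs in (50_000, 500_000):
        ests = []
        for seed in range(60):
            s = GeneratorSpec(n_diseases=1, true_eli=30.0, n_disease_pubs=n_pubs, seed=seed)
            cc = gen_literature_counts(s)[0]
            ests.append((cc.n_env + cc.n_lifestyle) / cc.n_disease * 1000)
        means.append(np.mean(ests))
    assert means[0] == pytest.approx(means[1], abs=1.0)


def test_selected_fraction_recovered_in_null_mode():
    spec = GeneratorSpec(selected_fraction=0.0075, universe_size=100_000,
                         platform_sizes=(40_000,), n_gwas_snps=5_000, seed=5)
    manifests, selected, gwas_ids = gen_platform_and_selected(spec)
    res = overlap(manifests[0], selected)
    assert res.proportion == pytest.approx(0.0075, abs=3 * math.sqrt(0.0075 / 40_000))
    gwas_res = overlap(PlatformManifest("gwas", frozenset(gwas_ids)), selected)
    assert gwas_res.proportion == pytest.approx(0.0075, abs=3 * math.sqrt(0.0075 / 5_000))


def test_zero_selected_fraction_gives_zero_overlap():
    spec = GeneratorSpec(selected_fraction=0.0, universe_size=10_000,
                         platform_sizes=(4_000,), seed=6)
    manifests, selected, gwas_ids = gen_platform_and_selected(spec)
    assert len(selected) == 0
    assert overlap(manifests[0], selected).n_selected == 0


def test_enrichment_detected_with_power():
    """With e = 2 the GWAS set carries twice the selected fraction; the
    chi-square comparison should reject the null in most seeds."""
    rejections = 0
    for seed in range(20):
        spec = GeneratorSpec(
            selected_fraction=0.0075, gwas_enrichment=2.0, universe_size=50_000,
            platform_sizes=(20_000,), n_gwas_snps=4_000, seed=seed,
        )
        manifests, selected, gwas_ids = gen_platform_and_selected(spec)
        platform_res = overlap(manifests[0], selected)
        gwas_res = overlap(PlatformManifest("gwas", frozenset(gwas_ids)), selected)
        if compare_overlap(gwas_res, platform_res).p_value < 0.05:
            rejections += 1
    assert rejections >= 16  # >= 80% power


def test_enrichment_times_fraction_must_stay_below_one():
    with pytest.raises(ValueError):
        GeneratorSpec(selected_fraction=0.3, gwas_enrichment=4.0)


def test_generated_bundle_passes_readers(tmp_path):
    spec = GeneratorSpec(n_diseases=4, seed=7, with_exposure=True)
    paths = write_bundle(spec, tmp_path)
    records = read_association_table(paths["association"])
    counts = read_literature_counts(paths["literature_counts"])
    assert len(counts) == 4
    assert all(c.n_exposure is not None for c in counts)
    assert {r.disease for r in records} == {c.disease for c in counts}
    selected = read_selected(paths["selected"])
    manifest = read_manifest(paths["platform_1"])
    assert len(manifest) == spec.platform_sizes[0]
    assert len(selected) == round(spec.selected_fraction * spec.universe_size)
    # association rsIDs come from the generated GWAS subset
    gwas = read_manifest(paths["gwas_snps"], name="gwas")
    assert {r.snp_id for r in records} <= gwas.snp_ids


def test_same_seed_byte_identical_bundles(tmp_path):
    spec = GeneratorSpec(n_diseases=3, seed=9)
    paths_a = write_bundle(spec, tmp_path / "a")
    paths_b = write_bundle(spec, tmp_path / "b")
    for name in paths_a:
        assert paths_a[name].read_bytes() == paths_b[name].read_bytes(), name
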