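"""Generator contracts: determinism, mixture composition, degenerate configs."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from pearldecon import (
    SimulationConfig,
    VariantCallSet,
    donor_snv_rates,
    filter_by_genotype_quality,
    read_vcf,
    simulate_allograft_experiment,
    simulate_dataset,
    simulate_genotypes,
    write_dataset,
)
from pearldecon.design import PURE_DONOR_TIME_POINTS
from pearldecon.errors import ConfigurationError
from pearldecon.synthetic_data import MixtureTruth, gene_panel_table

from conftest import small_config


def _file_hashes(directory):
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(Path(directory).iterdir())
    }


def test_same_seed_gives_byte_identical_dataset(tmp_path):
    config = small_config(seed=21)
    for sub in ("a", "b"):
        outs = simulate_dataset(small_config(seed=21))
        write_dataset(outs, tmp_path / sub, gene_panel_table(config))
    assert _file_hashes(tmp_path / "a") == _file_hashes(tmp_path / "b")


def test_different_seed_changes_read_counts():
    _, _, d1, _, _ = simulate_dataset(small_config(seed=1))
    _, _, d2, _, _ = simulate_dataset(small_config(seed=2))
    assert not d1["alt_reads"].equals(d2["alt_reads"])


def test_zero_alt_frequency_yields_no_private_alleles():
    config = small_config(alt_allele_frequency=0.0, n_private_sites_per_donor=0)
    panel = simulate_genotypes(config)
    for ind in panel.individuals:
        assert all(not panel.carries_alt(ind, s) for s in panel.sites)
        assert panel.private_sites(ind) == []


def test_sole_donor_owns_every_alt_site():
    config = SimulationConfig(
        n_donors=1,
        n_hosts=0,
        n_sites=30,
        n_private_sites_per_donor=0,
        alt_allele_frequency=1.0,
        seed=3,
    )
    panel = simulate_genotypes(config)
    assert set(panel.private_sites("donorA")) == set(panel.sites)


def test_planted_private_sites_are_private(small_dataset):
    config, _ = small_dataset
    panel = simulate_genotypes(config)
    for donor in panel.donors:
        private = set(panel.private_sites(donor))
        assert len(private) >= config.n_private_sites_per_donor


@pytest.mark.parametrize(
    "field,value",
    [
        ("n_sites", 0),
        ("n_donors", 0),
        ("mean_depth", 0),
        ("alt_allele_frequency", 1.5),
        ("sequencing_error_rate", -0.1),
        ("n_private_sites_per_donor", -1),
    ],
)
def test_invalid_config_raises_naming_field(field, value):
    with pytest.raises(ConfigurationError, match=field):
        small_config(**{field: value})


def test_mixing_schedule_must_cover_design():
    config = small_config()
    schedule = dict(config.mixing_schedule)
    del schedule["3m"]
    with pytest.raises(ConfigurationError, match="3m"):
        bad = small_config(mixing_schedule=schedule)
        simulate_allograft_experiment(simulate_genotypes(bad), bad)


def test_nonzero_mixing_at_pure_time_point_rejected():
    schedule = dict(small_config().mixing_schedule)
    schedule["before"] = 0.2
    with pytest.raises(ConfigurationError, match="before"):
        small_config(mixing_schedule=schedule)


def test_pure_donor_samples_have_zero_host_reads_noiseless(
    small_noiseless_dataset,
):
    config, (meta, calls, depths, _tpm, truth) = small_noiseless_dataset
    genotypes = simulate_genotypes(config)
    pure = meta[meta["time_point"].isin(PURE_DONOR_TIME_POINTS)]
    for row in pure.itertuples(index=False):
        sub = depths[depths["sample_id"] == row.sample_id]
        for site_row in sub.itertuples(index=False):
            site = next(
                s for s in genotypes.sites
                if (s.contig, s.position) == (site_row.contig, site_row.position)
            )
            expected = config.mean_depth * genotypes.alt_fraction(row.donor_id, site)
            assert site_row.alt_reads == expected


def test_noiseless_het_donor_hom_ref_host_half_mixture():
    """At h=0.5, a donor-het / host-hom-ref site carries donor-allele
    fraction 0.25 = 0.5 (mixture) x 0.5 (dosage), exactly in noiseless
    mode and within binomial error at high depth."""
    schedule = {tp: 0.0 for tp in PURE_DONOR_TIME_POINTS}
    schedule.update({"24h": 0.5, "48h": 0.5, "1w": 0.5, "2w": 0.5, "1m": 0.5, "3m": 0.5})
    config = small_config(
        mixing_schedule=schedule, noiseless=True, sequencing_error_rate=0.0
    )
    panel = simulate_genotypes(config)
    meta, calls, depths, _, _ = simulate_allograft_experiment(panel, config)
    mixed = meta[~meta["time_point"].isin(PURE_DONOR_TIME_POINTS)]
    checked = 0
    for row in mixed.itertuples(index=False):
        for site in panel.sites:
            if (
                panel.alt_fraction(row.donor_id, site) == 0.5
                and panel.alt_fraction(row.host_id, site) == 0.0
            ):
                call = calls.get(row.sample_id, site)
                assert call.allele_depths[1] == 0.25 * config.mean_depth
                checked += 1
    assert checked > 0


def test_empirical_mixture_fraction_converges_at_high_depth():
    """Stochastic counterpart of the closed form: pooled donor-allele read
    fraction at planted donor-private sites approaches (1-h) x mean dosage
    at depth 10^4 within 0.01."""
    h = 0.6
    schedule = {tp: 0.0 for tp in PURE_DONOR_TIME_POINTS}
    schedule.update({tp: h for tp in ("24h", "48h", "1w", "2w", "1m", "3m")})
    config = small_config(
        seed=7,
        mean_depth=10_000,
        sequencing_error_rate=0.0,
        mixing_schedule=schedule,
        n_replicates=1,
    )
    panel = simulate_genotypes(config)
    meta, calls, _, _, _ = simulate_allograft_experiment(panel, config)
    donor = "donorA"
    private = panel.private_sites(donor)
    sample = meta[
        (meta["donor_id"] == donor) & (meta["time_point"] == "1w")
    ]["sample_id"].iloc[0]
    alt = sum(calls.get(sample, s).allele_depths[1] for s in private)
    total = sum(calls.get(sample, s).total_depth for s in private)
    dosage = np.mean([panel.alt_fraction(donor, s) for s in private])
    assert alt / total == pytest.approx((1 - h) * dosage, abs=0.01)


def test_truth_reports_design_host_fractions(small_dataset):
    config, (meta, _, _, _, truth) = small_dataset
    merged = meta.merge(truth.samples[["sample_id", "host_fraction"]], on="sample_id")
    for row in merged.itertuples(index=False):
        assert row.host_fraction == config.mixing_schedule[row.time_point]
    pure = merged[merged["time_point"].isin(PURE_DONOR_TIME_POINTS)]
    assert (pure["host_fraction"] == 0.0).all()


def test_written_dataset_round_trips_through_ingest(tmp_path, small_dataset):
    config, outs = small_dataset
    meta, calls, _, tpm, _ = outs
    paths = write_dataset(outs, tmp_path, gene_panel_table(config))
    calls_back = read_vcf(paths["vcf"], meta)
    assert len(calls_back) == len(calls)
    for call in calls:
        back = calls_back.get(call.sample_id, call.site)
        assert back is not None
        assert back.genotype == call.genotype
        assert back.genotype_quality == call.genotype_quality
        assert back.allele_depths == call.allele_depths
    tpm_back = pd.read_csv(paths["expression"], sep="\t", index_col="gene_id")
    assert np.allclose(tpm_back.to_numpy(), tpm.to_numpy(), rtol=1e-5)


def test_low_gq_calls_are_present_in_vcf_for_downstream_removal(
    tmp_path, small_dataset
):
    config, outs = small_dataset
    paths = write_dataset(outs, tmp_path, gene_panel_table(config))
    calls = read_vcf(paths["vcf"])
    gqs = [c.genotype_quality for c in calls]
    assert any(g < 10 for g in gqs), "fixture should exercise the GQ filter"
    filtered = filter_by_genotype_quality(calls, 10)
    assert len(filtered) < len(calls)


def test_empty_site_list_writes_valid_header_only_vcf(tmp_path):
    config = small_config()
    meta, _, depths, tpm, truth = simulate_dataset(config)
    outs = (meta, VariantCallSet(), depths.iloc[0:0], tpm, truth)
    paths = write_dataset(outs, tmp_path, gene_panel_table(config))
    calls = read_vcf(paths["vcf"], meta)
    assert len(calls) == 0
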