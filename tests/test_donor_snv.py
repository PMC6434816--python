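"""Donor-specific SNV extraction and rate computation.

The extraction is checked against an exhaustive set-difference oracle:
enumerate every (site, alt allele) pair, keep those called with the alt in
the donor's reference and not called with the alt in any other-donor
sample. The oracle never touches the implementation's indexing.
"""

import numpy as np
import pandas as pd
import pytest

from pearldecon import (
    VariantCall,
    VariantCallSet,
    VariantSite,
    compute_snv_rates,
    count_allele_reads,
    donor_snv_rates,
    extract_donor_specific_snvs,
    filter_by_genotype_quality,
    simulate_dataset,
)
from pearldecon.donor_snv import DonorSNVSet
from pearldecon.errors import EstimationError, MetadataError

from conftest import small_config


def _meta(samples):
    """samples: list of (sample_id, donor_id, time_point, is_reference)."""
    return pd.DataFrame(
        [
            dict(
                sample_id=s,
                donor_id=d,
                time_point=tp,
                replicate=1,
                is_reference=ref,
            )
            for s, d, tp, ref in samples
        ]
    )


def _site(i):
    return VariantSite("tig", 100 + i, "A", "G")


def _add(calls, sample, site, n_alt_alleles, gq=50, ad=(5.0, 5.0)):
    gt = {
        0: (site.ref_allele, site.ref_allele),
        1: tuple(sorted((site.ref_allele, site.alt_allele))),
        2: (site.alt_allele, site.alt_allele),
    }[n_alt_alleles]
    calls.add(VariantCall(sample, site, gt, gq, ad))


def _oracle(calls, metadata, donor_id):
    """Exhaustive set difference over all (site, allele) pairs."""
    ref_id = metadata.loc[
        (metadata["donor_id"] == donor_id) & metadata["is_reference"],
        "sample_id",
    ].iloc[0]
    others = set(metadata.loc[metadata["donor_id"] != donor_id, "sample_id"])
    result = set()
    for site in {c.site for c in calls}:
        ref_call = calls.get(ref_id, site)
        if ref_call is None or not ref_call.has_alt:
            continue
        if any(
            c.has_alt
            for c in calls
            if c.site == site and c.sample_id in others
        ):
            continue
        result.add(site)
    return result


def test_het_in_reference_hom_ref_elsewhere_is_member():
    meta = _meta(
        [("A0", "A", "0h", True), ("B0", "B", "0h", True)]
    )
    calls = VariantCallSet()
    s = _site(0)
    _add(calls, "A0", s, 1)
    _add(calls, "B0", s, 0)
    snvs = extract_donor_specific_snvs(calls, meta, "A")
    assert snvs.sites == frozenset([s])


def test_allele_shared_with_other_donor_excluded():
    meta = _meta(
        [("A0", "A", "0h", True), ("B1w", "B", "1w", False), ("B0", "B", "0h", True)]
    )
    calls = VariantCallSet()
    s = _site(0)
    _add(calls, "A0", s, 2)
    _add(calls, "B1w", s, 1)  # other-donor sample carries the allele
    _add(calls, "B0", s, 0)
    assert extract_donor_specific_snvs(calls, meta, "A").sites == frozenset()


def test_same_donor_later_sample_does_not_veto():
    meta = _meta(
        [("A0", "A", "0h", True), ("A1w", "A", "1w", False), ("B0", "B", "0h", True)]
    )
    calls = VariantCallSet()
    s = _site(0)
    _add(calls, "A0", s, 1)
    _add(calls, "A1w", s, 1)  # legitimately carries the donor allele
    _add(calls, "B0", s, 0)
    assert extract_donor_specific_snvs(calls, meta, "A").sites == frozenset([s])


def test_read_level_mode_vetoes_on_alt_supporting_reads():
    meta = _meta([("A0", "A", "0h", True), ("B0", "B", "0h", True)])
    calls = VariantCallSet()
    s = _site(0)
    _add(calls, "A0", s, 1)
    _add(calls, "B0", s, 0, ad=(9.0, 1.0))  # hom-ref call, one stray alt read
    assert extract_donor_specific_snvs(calls, meta, "A").sites == frozenset([s])
    assert (
        extract_donor_specific_snvs(calls, meta, "A", read_level=True).sites
        == frozenset()
    )


def test_single_sample_call_set_yields_all_alt_sites():
    meta = _meta([("A0", "A", "0h", True)])
    calls = VariantCallSet()
    expected = set()
    for i in range(20):
        n_alt = i % 3
        _add(calls, "A0", _site(i), n_alt)
        if n_alt:
            expected.add(_site(i))
    snvs = extract_donor_specific_snvs(calls, meta, "A")
    assert snvs.sites == frozenset(expected)
    assert snvs.sites == frozenset(_oracle(calls, meta, "A"))


def test_ambiguous_reference_designation_raises():
    meta = _meta([("A0", "A", "0h", True), ("A0b", "A", "0h", True)])
    with pytest.raises(MetadataError, match="exactly one"):
        extract_donor_specific_snvs(VariantCallSet(), meta, "A")


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_extraction_matches_exhaustive_oracle(seed):
    """Random call sets up to 50 sites x 10 samples, het/hom/shared mix."""
    rng = np.random.default_rng(seed)
    n_sites = int(rng.integers(5, 51))
    donors = ["A", "B", "C"]
    samples = []
    for d in donors:
        samples.append((f"{d}0", d, "0h", True))
        for k in range(int(rng.integers(0, 3))):
            samples.append((f"{d}x{k}", d, "1w", False))
    samples = samples[:10]
    meta = _meta(samples)
    calls = VariantCallSet()
    for i in range(n_sites):
        site = _site(i)
        for s, _, _, _ in samples:
            if rng.random() < 0.2:
                continue  # uncovered in this sample
            _add(calls, s, site, int(rng.integers(0, 3)), gq=int(rng.integers(0, 99)))
    calls = filter_by_genotype_quality(calls, 10)
    for d in donors:
        got = extract_donor_specific_snvs(calls, meta, d).sites
        assert got == frozenset(_oracle(calls, meta, d))


def test_count_allele_reads_direct_arithmetic():
    meta = _meta([("A0", "A", "0h", True)])
    calls = VariantCallSet()
    s0, s1, s2 = _site(0), _site(1), _site(2)
    _add(calls, "A0", s0, 1, ad=(6.0, 4.0))
    _add(calls, "A0", s1, 1, ad=(0.0, 0.0))  # zero coverage -> no row
    snv_set = DonorSNVSet("A", "A0", frozenset([s0, s1, s2]))
    table = count_allele_reads(calls, snv_set, "A0")
    assert len(table) == 1
    row = table.iloc[0]
    assert row["donor_specific_reads"] == 4.0
    assert row["other_reads"] == 6.0


def test_count_allele_reads_empty_set_raises():
    with pytest.raises(EstimationError, match="empty"):
        count_allele_reads(
            VariantCallSet(), DonorSNVSet("A", "A0", frozenset()), "A0"
        )


def _depths(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "contig", "position", "ref_allele", "alt_allele",
            "donor_specific_reads", "other_reads",
        ],
    )


def test_rates_normalize_to_reference():
    meta = _meta([("A0", "A", "0h", True), ("S", "A", "1w", False)])
    depths = _depths(
        [
            ("A0", "tig", 100, "A", "G", 50.0, 50.0),  # raw 0.50
            ("S", "tig", 100, "A", "G", 25.0, 75.0),   # raw 0.25
        ]
    )
    rates = compute_snv_rates(depths, meta, "A").set_index("sample_id")
    assert rates.loc["A0", "normalized_rate_percent"] == 100.0
    assert rates.loc["S", "normalized_rate_percent"] == pytest.approx(50.0)


def test_rate_equal_to_reference_is_exactly_100():
    meta = _meta([("A0", "A", "0h", True), ("S", "A", "cell", False)])
    depths = _depths(
        [
            ("A0", "tig", 100, "A", "G", 37.0, 63.0),
            ("S", "tig", 100, "A", "G", 37.0, 63.0),
        ]
    )
    rates = compute_snv_rates(depths, meta, "A").set_index("sample_id")
    assert rates.loc["S", "normalized_rate_percent"] == 100.0


def test_rate_above_reference_clamped_to_100():
    meta = _meta([("A0", "A", "0h", True), ("S", "A", "cell", False)])
    depths = _depths(
        [
            ("A0", "tig", 100, "A", "G", 40.0, 60.0),
            ("S", "tig", 100, "A", "G", 55.0, 45.0),
        ]
    )
    rates = compute_snv_rates(depths, meta, "A").set_index("sample_id")
    assert rates.loc["S", "normalized_rate_percent"] == 100.0


def test_uncovered_sample_gets_missing_rate_not_zero():
    meta = _meta([("A0", "A", "0h", True), ("S", "A", "3m", False)])
    depths = _depths([("A0", "tig", 100, "A", "G", 40.0, 60.0)])
    rates = compute_snv_rates(depths, meta, "A").set_index("sample_id")
    assert np.isnan(rates.loc["S", "normalized_rate_percent"])
    assert rates.loc["S", "n_sites_used"] == 0


def test_zero_reference_depth_raises():
    meta = _meta([("A0", "A", "0h", True)])
    depths = _depths([])
    with pytest.raises(EstimationError, match="reference"):
        compute_snv_rates(depths, meta, "A")


def test_noiseless_rate_is_100_times_donor_fraction(small_noiseless_dataset):
    """Closed form: with equal per-site coverage and host-free marker
    sites, the normalized rate equals 100(1-h) regardless of the het/hom
    mix (the reference denominator absorbs allele dosage)."""
    config, (meta, calls, _, _, truth) = small_noiseless_dataset
    rates = donor_snv_rates(filter_by_genotype_quality(calls), meta)
    merged = rates.merge(
        truth.samples[["sample_id", "host_fraction"]], on="sample_id"
    )
    expect = 100.0 * (1.0 - merged["host_fraction"])
    assert np.allclose(merged["normalized_rate_percent"], expect, atol=1e-9)


def test_noiseless_rate_strictly_decreasing_in_host_fraction(
    small_noiseless_dataset,
):
    config, (meta, calls, _, _, truth) = small_noiseless_dataset
    rates = donor_snv_rates(filter_by_genotype_quality(calls), meta)
    merged = rates.merge(
        truth.samples[["sample_id", "host_fraction"]], on="sample_id"
    )
    by_h = merged.groupby("host_fraction")["normalized_rate_percent"].mean()
    hs = sorted(by_h.index)
    assert all(by_h[a] > by_h[b] for a, b in zip(hs, hs[1:]))


def test_reference_rate_is_100_on_stochastic_data(small_dataset):
    _, (meta, calls, _, _, _) = small_dataset
    rates = donor_snv_rates(filter_by_genotype_quality(calls), meta)
    refs = rates[rates["sample_id"] == rates["reference_sample_id"]]
    assert len(refs) == meta["donor_id"].nunique()
    assert (refs["normalized_rate_percent"] == 100.0).all()
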