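"""Donor-specific SNV extraction and per-sample SNV read rates.

The central quantity of the pipeline: for each donor, the set of SNV
alleles that appear in that donor's 0 h reference sample and in no sample
derived from any other donor. Reads carrying those alleles are donor
transcripts by construction; pooling them across the marker sites and
normalizing to the 0 h reference (defined as 100%) yields the per-sample
donor-specific SNV read rate, whose complement is the host-contamination
rate.

Rates are micro-averaged: donor-specific and other read counts are summed
over all marker sites before the ratio is taken, so deep sites weigh more
than shallow ones. Normalized rates above 100 (sampling noise) are clamped
to 100. A sample with no covered marker site gets a missing rate — never
an imputed 0 or 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import reference_sample
from .errors import EstimationError, MetadataError
from .variant_ingest import VariantCallSet, VariantSite

logger = logging.getLogger(__name__)

#: Columns of the allele-depth table produced by :func:`count_allele_reads`.
ALLELE_DEPTH_COLUMNS = (
    "sample_id", "contig", "position", "ref_allele", "alt_allele",
    "donor_specific_reads", "other_reads",
)

#: Columns of the per-sample rate table from :func:`compute_snv_rates`.
RATE_COLUMNS = (
    "sample_id", "donor_id", "time_point", "n_sites_used",
    "raw_rate", "normalized_rate_percent", "reference_sample_id",
)


@dataclass(frozen=True)
class DonorSNVSet:
    """The (site, alt allele) pairs private to one donor."""

    donor_id: str
    reference_sample_id: str
    sites: frozenset[VariantSite]

    def __len__(self) -> int:
        return len(self.sites)


def extract_donor_specific_snvs(
    calls: VariantCallSet,
    metadata: pd.DataFrame,
    donor_id: str,
    read_level: bool = False,
) -> DonorSNVSet:
    """Extract the donor-specific SNV set for ``donor_id``.

    A site's alt allele is donor-specific when (a) the donor's 0 h
    reference genotype contains it and (b) no call from a sample belonging
    to a *different* donor contains it. Samples of the same donor at other
    time points legitimately carry the allele and never veto it.

    With ``read_level=True`` the exclusion is stricter: any alt-supporting
    read (nonzero alt allele depth) in an other-donor sample vetoes the
    site, not just a called genotype.

    ``calls`` should already be genotype-quality filtered. An empty result
    is returned with a warning; downstream rates are then undefined.
    """
    ref_id = reference_sample(metadata, donor_id)
    other_samples = set(
        metadata.loc[metadata["donor_id"] != donor_id, "sample_id"]
    )

    candidates = [
        call.site
        for call in calls.calls_for_sample(ref_id)
        if call.has_alt
    ]
    if not candidates and not calls.calls_for_sample(ref_id):
        raise MetadataError(
            f"reference sample {ref_id!r} of donor {donor_id!r} has no calls"
        )

    candidate_set = set(candidates)
    by_site: dict[VariantSite, list] = {}
    for call in calls:
        if call.site in candidate_set and call.sample_id in other_samples:
            by_site.setdefault(call.site, []).append(call)

    members = []
    for site in candidates:
        vetoed = any(
            call.has_alt or (read_level and call.allele_depths[1] > 0)
            for call in by_site.get(site, [])
        )
        if not vetoed:
            members.append(site)

    if not members:
        logger.warning(
            "no donor-specific SNVs found for donor %s; downstream rates "
            "will be undefined", donor_id,
        )
    logger.info(
        "donor %s: %d candidate alt sites in reference, %d donor-specific",
        donor_id, len(candidates), len(members),
    )
    return DonorSNVSet(
        donor_id=donor_id,
        reference_sample_id=ref_id,
        sites=frozenset(members),
    )


def count_allele_reads(
    calls: VariantCallSet, snv_set: DonorSNVSet, sample_id: str
) -> pd.DataFrame:
    """Count donor-specific and other reads for one sample.

    For each marker site with a call and nonzero total depth in the sample:
    donor_specific_reads is the alt-allele depth, other_reads the rest.
    Uncovered or zero-depth sites produce no row (they are reflected in the
    ``n_sites_used`` bookkeeping of :func:`compute_snv_rates`).
    """
    if len(snv_set) == 0:
        raise EstimationError(
            f"donor-specific SNV set for {snv_set.donor_id!r} is empty"
        )
    rows = []
    for site in sorted(snv_set.sites):
        call = calls.get(sample_id, site)
        if call is None or call.total_depth <= 0:
            continue
        ref_d, alt_d = call.allele_depths
        rows.append(
            dict(
                sample_id=sample_id,
                contig=site.contig,
                position=site.position,
                ref_allele=site.ref_allele,
                alt_allele=site.alt_allele,
                donor_specific_reads=alt_d,
                other_reads=ref_d,
            )
        )
    return pd.DataFrame(rows, columns=list(ALLELE_DEPTH_COLUMNS))


def compute_snv_rates(
    depths: pd.DataFrame,
    metadata: pd.DataFrame,
    donor_id: str,
) -> pd.DataFrame:
    """Pooled donor-specific SNV read rates for every sample of a donor.

    raw_rate = Σ donor_specific_reads / Σ (donor_specific_reads +
    other_reads) over the donor's marker sites; normalized_rate_percent =
    100 × raw_rate / raw_rate(0 h reference), clamped to at most 100, with
    the reference itself exactly 100. Samples with zero pooled depth get a
    missing (NaN) rate.
    """
    ref_id = reference_sample(metadata, donor_id)
    donor_meta = metadata[metadata["donor_id"] == donor_id]

    pooled = {}
    for sample_id, group in depths.groupby("sample_id"):
        num = float(group["donor_specific_reads"].sum())
        den = num + float(group["other_reads"].sum())
        pooled[sample_id] = (num, den, len(group))

    if ref_id not in pooled or pooled[ref_id][1] <= 0:
        raise EstimationError(
            f"reference sample {ref_id!r} has zero pooled depth over the "
            f"donor-specific SNV set"
        )
    ref_rate = pooled[ref_id][0] / pooled[ref_id][1]
    if ref_rate <= 0:
        raise EstimationError(
            f"reference sample {ref_id!r} has zero donor-specific reads"
        )

    rows = []
    n_clamped = 0
    for row in donor_meta.itertuples(index=False):
        sample_id = row.sample_id
        if sample_id not in pooled or pooled[sample_id][1] <= 0:
            raw = np.nan
            normalized = np.nan
            n_sites = 0
        else:
            num, den, n_sites = pooled[sample_id]
            raw = num / den
            if sample_id == ref_id:
                normalized = 100.0
            else:
                # ratio first: raw == ref_rate must give exactly 100.0
                normalized = 100.0 * (raw / ref_rate)
                if normalized > 100.0:
                    n_clamped += 1
                    normalized = 100.0
        rows.append(
            dict(
                sample_id=sample_id,
                donor_id=donor_id,
                time_point=row.time_point,
                n_sites_used=n_sites,
                raw_rate=raw,
                normalized_rate_percent=normalized,
                reference_sample_id=ref_id,
            )
        )
    if n_clamped:
        logger.info(
            "donor %s: clamped %d normalized rates above 100%%",
            donor_id, n_clamped,
        )
    return pd.DataFrame(rows, columns=list(RATE_COLUMNS))


def donor_snv_rates(
    calls: VariantCallSet,
    metadata: pd.DataFrame,
    donor_id: str | None = None,
    read_level: bool = False,
) -> pd.DataFrame:
    """Convenience composition: extract → count → rate, for one donor or all.

    Returns the concatenated per-sample rate table (one row per sample,
    the tabular form of the donor-specific SNV rate profile).
    """
    donors = (
        [donor_id]
        if donor_id is not None
        else sorted(metadata["donor_id"].unique())
    )
    tables = []
    for donor in donors:
        snv_set = extract_donor_specific_snvs(
            calls, metadata, donor, read_level=read_level
        )
        sample_ids = metadata.loc[metadata["donor_id"] == donor, "sample_id"]
        depths = pd.concat(
            [count_allele_reads(calls, snv_set, s) for s in sample_ids],
            ignore_index=True,
        )
        tables.append(compute_snv_rates(depths, metadata, donor))
    return pd.concat(tables, ignore_index=True)
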