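"""Variant-call ingestion: read VCF, apply the genotype-quality filter.

The pipeline consumes variant calls produced upstream (e.g. by GATK
HaplotypeCaller on STAR-mapped RNA-seq reads) as VCF v4.x with per-sample
``GT``, ``GQ`` and ``AD`` FORMAT fields. Only biallelic SNVs are kept:
indels and multi-allelic records are skipped and counted. Calls with
genotype quality below 10 are removed before donor-specific SNV extraction,
mirroring standard practice of discarding low-confidence genotypes.

Coordinates are 1-based throughout (VCF convention); no conversion happens
anywhere in the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import MetadataError, VCFParseError

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class VariantSite:
    """A biallelic SNV site; (contig, position, alt_allele) keys it uniquely."""

    contig: str
    position: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles are identical: {self.ref_allele}")


@dataclass(frozen=True)
class VariantCall:
    """One sample's genotype call at one site.

    ``genotype`` is an unordered diploid allele pair over the site's
    {ref, alt}; ``allele_depths`` is (ref reads, alt reads). Depths are kept
    as floats so that an expected-count (noiseless) simulation can carry
    exact non-integer expectations through the same container.
    ``genotype_quality`` is ``None`` when the caller emitted no GQ; such
    calls fail the quality filter.
    """

    sample_id: str
    site: VariantSite
    genotype: tuple[str, str]
    genotype_quality: Optional[int]
    allele_depths: tuple[float, float]

    def __post_init__(self) -> None:
        valid = {self.site.ref_allele, self.site.alt_allele}
        if not set(self.genotype) <= valid:
            raise ValueError(
                f"genotype {self.genotype} not over site alleles {sorted(valid)}"
            )
        if min(self.allele_depths) < 0:
            raise ValueError(f"negative allele depth: {self.allele_depths}")

    @property
    def has_alt(self) -> bool:
        return self.site.alt_allele in self.genotype

    @property
    def total_depth(self) -> float:
        return self.allele_depths[0] + self.allele_depths[1]


@dataclass
class VariantCallSet:
    """Calls indexed by (sample_id, site); at most one call per key."""

    _calls: dict[tuple[str, VariantSite], VariantCall] = field(default_factory=dict)

    def add(self, call: VariantCall) -> None:
        key = (call.sample_id, call.site)
        if key in self._calls:
            raise ValueError(f"duplicate call for {key[0]} at {key[1]}")
        self._calls[key] = call

    def get(self, sample_id: str, site: VariantSite) -> Optional[VariantCall]:
        return self._calls.get((sample_id, site))

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self._calls.values())

    def __len__(self) -> int:
        return len(self._calls)

    @property
    def samples(self) -> frozenset[str]:
        return frozenset(sample for sample, _ in self._calls)

    @property
    def sites(self) -> frozenset[VariantSite]:
        return frozenset(site for _, site in self._calls)

    def calls_for_sample(self, sample_id: str) -> list[VariantCall]:
        return [c for c in self._calls.values() if c.sample_id == sample_id]


def read_vcf(
    paths: Sequence[str] | str,
    metadata: Optional[pd.DataFrame] = None,
) -> VariantCallSet:
    """Read biallelic SNV calls from one or more VCF files.

    Multi-allelic and indel records are skipped (counted at info level);
    records lacking an AD FORMAT field are skipped with a warning; missing
    (``./.``) and half-called genotypes are omitted. When ``metadata`` is
    given, every VCF sample column must appear in it.
    """
    from cyvcf2 import VCF  # heavy import deferred

    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]

    calls = VariantCallSet()
    n_skipped_nonsnv = 0
    n_skipped_no_ad = 0
    for path in paths:
        try:
            vcf = VCF(str(path))
        except Exception as exc:  # cyvcf2 raises bare OSError on bad input
            raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc
        vcf_samples = list(vcf.samples)
        if metadata is not None:
            unknown = set(vcf_samples) - set(metadata["sample_id"])
            if unknown:
                raise MetadataError(
                    f"VCF {path} contains samples absent from metadata: "
                    f"{sorted(unknown)}"
                )
        for variant in vcf:
            if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
                n_skipped_nonsnv += 1
                continue
            ad = variant.format("AD")
            if ad is None:
                n_skipped_no_ad += 1
                logger.warning(
                    "record %s:%d lacks AD; skipped", variant.CHROM, variant.POS
                )
                continue
            site = VariantSite(
                contig=variant.CHROM,
                position=variant.POS,
                ref_allele=variant.REF,
                alt_allele=variant.ALT[0],
            )
            gq = variant.format("GQ")
            genotypes = variant.genotypes  # [[allele0, allele1, phased], ...]
            for i, sample in enumerate(vcf_samples):
                gt = genotypes[i][:-1]
                if len(gt) != 2 or any(a < 0 for a in gt):
                    continue  # missing or half-called genotype
                alleles = tuple(
                    sorted(site.ref_allele if a == 0 else site.alt_allele for a in gt)
                )
                sample_gq: Optional[int] = None
                if gq is not None:
                    raw = float(np.asarray(gq[i]).ravel()[0])
                    if raw >= 0:
                        sample_gq = int(raw)
                ref_d, alt_d = float(ad[i][0]), float(ad[i][1])
                if ref_d < 0 or alt_d < 0:
                    continue  # AD missing for this sample
                calls.add(
                    VariantCall(
                        sample_id=sample,
                        site=site,
                        genotype=alleles,
                        genotype_quality=sample_gq,
                        allele_depths=(ref_d, alt_d),
                    )
                )
    if n_skipped_nonsnv:
        logger.info("skipped %d non-SNV (indel/multi-allelic) records", n_skipped_nonsnv)
    if n_skipped_no_ad:
        logger.info("skipped %d records lacking AD", n_skipped_no_ad)
    return calls


def filter_by_genotype_quality(
    calls: VariantCallSet, threshold: int = 10
) -> VariantCallSet:
    """Retain calls with genotype quality >= ``threshold``.

    Calls strictly below the threshold are removed; calls lacking a GQ value
    are treated as failing any positive threshold (conservative). At
    threshold 0 the filter is the identity. The input set is not modified.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    kept = VariantCallSet()
    n_removed = 0
    for call in calls:
        if threshold == 0 or (
            call.genotype_quality is not None and call.genotype_quality >= threshold
        ):
            kept.add(call)
        else:
            n_removed += 1
    logger.info(
        "GQ filter (threshold %d): kept %d calls, removed %d",
        threshold, len(kept), n_removed,
    )
    return kept
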