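"""End-to-end pipeline composition: ingest → donor SNVs → contamination →
adjustment → profiling, with TSV outputs and a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import sys
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import __version__
from .contamination import DEFAULT_CAP, adjust_matrix, contamination_from_rates
from .design import load_metadata, validate_metadata
from .donor_snv import donor_snv_rates
from .errors import PearldeconError
from .profiling import (
    cluster_genes,
    export_trajectories,
    load_gene_panel,
    pca_profiles,
    select_panel,
)
from .variant_ingest import filter_by_genotype_quality, read_vcf

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; round-trips through YAML unchanged."""

    vcf: Optional[str] = None
    metadata: Optional[str] = None
    expression: Optional[str] = None
    gene_panel: Optional[str] = None
    output_dir: str = "pearldecon_results"
    gq_threshold: int = 10
    contamination_cap: float = DEFAULT_CAP
    n_groups: int = 4
    cluster_metric: str = "correlation"
    cluster_method: str = "average"
    read_level_exclusion: bool = False
    seed: int = 0
    simulation: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PearldeconError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every stage on the configured inputs; returns output paths.

    Writes: ``snv_rates.tsv``, ``contamination.tsv``,
    ``adjusted_expression.tsv``, ``pca_scores.tsv``,
    ``gene_clusters.tsv``, ``trajectories.tsv`` and ``manifest.json``.
    """
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    counters: dict[str, int] = {}

    stage = "variant_ingest"
    try:
        metadata = load_metadata(config.metadata)
        calls = read_vcf(config.vcf, metadata)
        counters["calls_read"] = len(calls)
        calls = filter_by_genotype_quality(calls, config.gq_threshold)
        counters["calls_after_gq_filter"] = len(calls)

        stage = "donor_snv"
        rates = donor_snv_rates(
            calls, metadata, read_level=config.read_level_exclusion
        )
        counters["samples_rated"] = int(rates["normalized_rate_percent"].notna().sum())

        stage = "contamination"
        estimates = contamination_from_rates(rates, cap=config.contamination_cap)
        counters["samples_capped"] = int(estimates["capped"].sum())
        tpm = pd.read_csv(config.expression, sep="\t", index_col="gene_id")
        adjusted = adjust_matrix(tpm, estimates, metadata)

        stage = "profiling"
        panel = load_gene_panel(config.gene_panel)
        sub = select_panel(adjusted, panel)
        scores, explained = pca_profiles(sub)
        assignment = cluster_genes(
            sub,
            n_groups=config.n_groups,
            metric=config.cluster_metric,
            method=config.cluster_method,
        )
        trajectories = export_trajectories(adjusted, panel, metadata)
    except PearldeconError as exc:
        raise PearldeconError(f"[stage {stage}] {exc}") from exc

    paths = {
        "snv_rates": os.path.join(outdir, "snv_rates.tsv"),
        "contamination": os.path.join(outdir, "contamination.tsv"),
        "adjusted_expression": os.path.join(outdir, "adjusted_expression.tsv"),
        "pca_scores": os.path.join(outdir, "pca_scores.tsv"),
        "gene_clusters": os.path.join(outdir, "gene_clusters.tsv"),
        "trajectories": os.path.join(outdir, "trajectories.tsv"),
        "manifest": os.path.join(outdir, "manifest.json"),
    }
    rates.to_csv(paths["snv_rates"], sep="\t", index=False, float_format="%.10g")
    estimates.to_csv(
        paths["contamination"], sep="\t", index=False, float_format="%.10g"
    )
    adjusted.to_csv(paths["adjusted_expression"], sep="\t", float_format="%.10g")
    scores_out = scores.copy()
    scores_out.index.name = "sample_id"
    scores_out.to_csv(paths["pca_scores"], sep="\t", float_format="%.10g")
    clusters_out = assignment.labels.rename("group").to_frame()
    clusters_out.index.name = "gene_id"
    clusters_out.to_csv(paths["gene_clusters"], sep="\t")
    trajectories.to_csv(
        paths["trajectories"], sep="\t", index=False, float_format="%.10g"
    )

    manifest = dict(
        config=config.to_dict(),
        pearldecon_version=__version__,
        python_version=sys.version.split()[0],
        counters=counters,
        pca_explained_variance=[float(v) for v in explained],
        transformations=dict(
            pca="log10(TPM+1), gene-centered",
            clustering=(
                f"log10(TPM+1), gene z-score, {config.cluster_metric} "
                f"distance, {config.cluster_method} linkage"
            ),
        ),
    )
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", outdir)
    return paths
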