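"""Synthetic allograft mixture datasets with known host-contamination fractions.

Emulates the mantle-grafting study design: three donor oysters, nine
sampling points (``cell``, ``before``, ``0h``, ``24h``, ``48h``, ``1w``,
``2w``, ``1m``, ``3m``) and two replicate host oysters per post-graft
sampling, each replicate carrying a graft from the same donor. Donor-pure
samples (cell, before, 0 h) contain no host reads; pearl-sac samples mix
donor and host transcripts at a configurable host fraction *h* per time
point, rising from zero at grafting to a high plateau at 1 w–3 m.

The generator produces, per sample:

* a diploid genotype per biallelic SNV site (Hardy–Weinberg draws at a
  configurable alt-allele frequency — the simplest model that yields
  donor-private alleles),
* allele read depths at each site: the alt-read count is binomial with the
  site's mixture allele fraction ``(1-h)·f_donor + h·f_host``, optionally
  perturbed by a symmetric per-read allele flip (sequencing error),
* a phred-like genotype quality drawn independently of correctness,
* a TPM row per panel gene following one of three trajectory archetypes
  (early-high "prismatic", late-high "nacreous", V-shaped "both"), scaled
  by the donor fraction ``1-h`` (panel genes are pearl-sac specific, so
  host tissue dilutes them) with multiplicative log-normal noise.

A noiseless mode (``noiseless=True`` with ``sequencing_error_rate=0``)
emits exact expected counts instead of random draws, so closed-form
identities — e.g. a normalized donor-specific SNV read rate of
``100·(1-h)`` — hold exactly on its output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .design import (
    GRAFTED_TIME_POINTS,
    PURE_DONOR_TIME_POINTS,
    REFERENCE_TIME_POINT,
    TIME_POINTS,
)
from .errors import ConfigurationError
from .variant_ingest import VariantCall, VariantCallSet, VariantSite

_BASES = ("A", "C", "G", "T")

#: Default host fraction per time point. Donor-pure points are exactly 0;
#: post-graft contamination rises to a high plateau in weeks 1-12, matching
#: the qualitative course of the grafting experiment (mostly-donor reads up
#: to 48 h, mostly-host reads from 1 w on). Values are multiples of 0.05 so
#: expected read counts at the default depth are exact integers.
DEFAULT_MIXING_SCHEDULE: dict[str, float] = {
    "cell": 0.0,
    "before": 0.0,
    "0h": 0.0,
    "24h": 0.05,
    "48h": 0.10,
    "1w": 0.55,
    "2w": 0.65,
    "1m": 0.70,
    "3m": 0.75,
}

#: Mean pearl-sac TPM per time point for the three trajectory archetypes
#: (order: cell, before, 0h, 24h, 48h, 1w, 2w, 1m, 3m). "prismatic":
#: up-regulated early, collapsing once the pearl sac matures; "nacreous":
#: up-regulated from 1-2 w after pearl-sac maturation; "both": high early,
#: dipping around 1 w, recovering late. The drastic change sits at the 1 w
#: transition, when pearl-sac formation completes and nearly all panel
#: genes switch regime. Magnitudes are arbitrary but well separated.
DEFAULT_EXPRESSION_PROGRAMS: dict[str, tuple[float, ...]] = {
    "prismatic": (100.0, 110.0, 120.0, 150.0, 140.0, 30.0, 20.0, 15.0, 10.0),
    "nacreous": (10.0, 10.0, 12.0, 10.0, 15.0, 60.0, 120.0, 140.0, 150.0),
    "both": (120.0, 110.0, 100.0, 90.0, 70.0, 10.0, 60.0, 100.0, 130.0),
}

#: Genotype-quality sampling parameters: a small fraction of calls fall in
#: the low band (below the GQ 10 filter), the rest in a confident band.
DEFAULT_GQ_DISTRIBUTION: dict[str, float] = {
    "low_fraction": 0.05,
    "low_min": 0,
    "low_max": 9,
    "high_min": 30,
    "high_max": 99,
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic allograft experiment."""

    n_donors: int = 3
    n_hosts: int = 36  # one host oyster per (donor, grafted time point, replicate)
    n_replicates: int = 2
    n_sites: int = 500
    n_private_sites_per_donor: int = 100
    alt_allele_frequency: float = 0.3
    mixing_schedule: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXING_SCHEDULE)
    )
    mean_depth: int = 200
    sequencing_error_rate: float = 0.005
    gq_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GQ_DISTRIBUTION)
    )
    n_genes: int = 192
    expression_programs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_EXPRESSION_PROGRAMS)
    )
    expression_noise_sd: float = 0.2  # sd of log10 multiplicative noise
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_donors", "n_sites"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_hosts < 0:
            raise ConfigurationError(f"n_hosts must be >= 0, got {self.n_hosts}")
        if self.n_replicates < 1:
            raise ConfigurationError(
                f"n_replicates must be >= 1, got {self.n_replicates}"
            )
        if self.mean_depth < 1:
            raise ConfigurationError(f"mean_depth must be >= 1, got {self.mean_depth}")
        for name in ("alt_allele_frequency", "sequencing_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for tp, h in self.mixing_schedule.items():
            if not 0.0 <= h <= 1.0:
                raise ConfigurationError(
                    f"mixing_schedule[{tp!r}] must be in [0, 1], got {h}"
                )
        for tp in PURE_DONOR_TIME_POINTS:
            if self.mixing_schedule.get(tp, 0.0) != 0.0:
                raise ConfigurationError(
                    f"mixing_schedule[{tp!r}] must be exactly 0 (donor-pure sample)"
                )
        if self.noiseless and self.sequencing_error_rate != 0.0:
            raise ConfigurationError(
                "noiseless mode requires sequencing_error_rate = 0"
            )
        for group, prog in self.expression_programs.items():
            if len(prog) != len(TIME_POINTS):
                raise ConfigurationError(
                    f"expression_programs[{group!r}] must give one mean per "
                    f"time point ({len(TIME_POINTS)}), got {len(prog)}"
                )
        if self.n_genes < len(self.expression_programs):
            raise ConfigurationError(
                "n_genes must be >= number of expression programs"
            )
        if self.n_private_sites_per_donor < 0:
            raise ConfigurationError(
                f"n_private_sites_per_donor must be >= 0, got "
                f"{self.n_private_sites_per_donor}"
            )
        if self.n_private_sites_per_donor * self.n_donors > self.n_sites:
            raise ConfigurationError(
                "n_private_sites_per_donor × n_donors exceeds n_sites"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GenotypePanel:
    """Diploid genotypes of all simulated individuals at all SNV sites."""

    individuals: list[str]
    sites: list[VariantSite]
    genotypes: dict[tuple[str, VariantSite], tuple[str, str]]
    donors: list[str] = field(default_factory=list)
    hosts: list[str] = field(default_factory=list)

    def alt_fraction(self, individual: str, site: VariantSite) -> float:
        """Alt-allele dosage fraction: 0, 0.5 or 1."""
        gt = self.genotypes[(individual, site)]
        return sum(a == site.alt_allele for a in gt) / 2.0

    def carries_alt(self, individual: str, site: VariantSite) -> bool:
        return self.alt_fraction(individual, site) > 0

    def private_sites(self, individual: str) -> list[VariantSite]:
        """Sites where ``individual`` carries the alt allele and no other
        panel member does — the ground-truth donor-specific SNVs."""
        others = [ind for ind in self.individuals if ind != individual]
        return [
            s
            for s in self.sites
            if self.carries_alt(individual, s)
            and not any(self.carries_alt(o, s) for o in others)
        ]


@dataclass
class MixtureTruth:
    """Simulation ground truth.

    ``samples`` has one row per sample: sample_id, donor_id, host_id,
    time_point, host_fraction, expected_donor_reads_per_site and
    expected_host_reads_per_site (site coverage is uniform at
    ``mean_depth``, so per-site expectations are constant per sample).
    """

    samples: pd.DataFrame

    def host_fraction(self, sample_id: str) -> float:
        row = self.samples.loc[self.samples["sample_id"] == sample_id]
        return float(row["host_fraction"].iloc[0])


def donor_name(i: int) -> str:
    return f"donor{chr(ord('A') + i)}" if i < 26 else f"donor{i}"


def simulate_genotypes(config: SimulationConfig) -> GenotypePanel:
    """Draw a genotype panel for all donors and hosts.

    Sites are biallelic SNVs on synthetic transcript contigs. The panel has
    two kinds of sites:

    * *planted private markers* — ``n_private_sites_per_donor`` sites per
      donor at which that donor carries the alt allele (heterozygous with
      probability 2/3, mirroring the predominance of heterozygotes among
      rare variants) and every other individual is homozygous reference.
      These model the rare, individual-private polymorphisms that make a
      donor's transcripts identifiable; under a neutral per-site draw a
      private allele would have to be absent from every other oyster in the
      cohort, which at any appreciable allele frequency almost never
      happens, so the markers are planted explicitly with their privacy
      guaranteed.
    * *background sites* — the remainder, with each individual's genotype
      drawn as two independent Bernoulli(``alt_allele_frequency``) alleles
      (Hardy–Weinberg). These carry shared variation that the
      donor-specific SNV extraction must reject.
    """
    rng = np.random.default_rng(config.seed)
    donors = [donor_name(i) for i in range(config.n_donors)]
    hosts = [f"host{i + 1:03d}" for i in range(config.n_hosts)]
    individuals = donors + hosts

    sites: list[VariantSite] = []
    for k in range(config.n_sites):
        ref, alt = rng.choice(len(_BASES), size=2, replace=False)
        sites.append(
            VariantSite(
                contig=f"transcript{k:05d}",
                position=101 + int(rng.integers(0, 400)),
                ref_allele=_BASES[ref],
                alt_allele=_BASES[alt],
            )
        )

    n_planted = config.n_private_sites_per_donor * config.n_donors
    genotypes: dict[tuple[str, VariantSite], tuple[str, str]] = {}

    # planted private markers: blocks of consecutive sites, one block per donor
    for k in range(n_planted):
        site = sites[k]
        owner = donors[k // config.n_private_sites_per_donor]
        het = rng.random() < 2.0 / 3.0
        for ind in individuals:
            if ind == owner:
                gt = (
                    tuple(sorted((site.ref_allele, site.alt_allele)))
                    if het
                    else (site.alt_allele, site.alt_allele)
                )
            else:
                gt = (site.ref_allele, site.ref_allele)
            genotypes[(ind, site)] = gt

    # background sites: Hardy-Weinberg draws at the configured alt frequency
    background = sites[n_planted:]
    p = config.alt_allele_frequency
    for ind in individuals:
        draws = rng.random((len(background), 2)) < p
        for site, (a, b) in zip(background, draws):
            genotypes[(ind, site)] = tuple(
                sorted(site.alt_allele if x else site.ref_allele for x in (a, b))
            )
    return GenotypePanel(
        individuals=individuals,
        sites=sites,
        genotypes=genotypes,
        donors=donors,
        hosts=hosts,
    )


def _sample_plan(config: SimulationConfig) -> pd.DataFrame:
    """Lay out the sample sheet: donor-pure points get one sample, grafted
    points ``n_replicates`` samples each in a distinct host oyster."""
    rows = []
    host_cursor = 0
    for d in range(config.n_donors):
        donor = donor_name(d)
        for tp in TIME_POINTS:
            if tp not in config.mixing_schedule:
                raise ConfigurationError(
                    f"mixing_schedule lacks time point {tp!r}"
                )
            if tp in PURE_DONOR_TIME_POINTS:
                rows.append(
                    dict(
                        sample_id=f"{donor}_{tp}",
                        donor_id=donor,
                        host_id="",
                        time_point=tp,
                        replicate=1,
                        is_reference=(tp == REFERENCE_TIME_POINT),
                    )
                )
            else:
                for r in range(1, config.n_replicates + 1):
                    if config.n_hosts == 0:
                        raise ConfigurationError(
                            "n_hosts must be >= 1 when grafted time points "
                            "are simulated"
                        )
                    host = f"host{host_cursor % config.n_hosts + 1:03d}"
                    host_cursor += 1
                    rows.append(
                        dict(
                            sample_id=f"{donor}_{tp}_r{r}",
                            donor_id=donor,
                            host_id=host,
                            time_point=tp,
                            replicate=r,
                            is_reference=False,
                        )
                    )
    return pd.DataFrame(rows)


def _draw_gq(rng: np.random.Generator, params: dict[str, float], n: int) -> np.ndarray:
    low = rng.random(n) < params["low_fraction"]
    gq = rng.integers(int(params["high_min"]), int(params["high_max"]) + 1, size=n)
    n_low = int(low.sum())
    if n_low:
        gq[low] = rng.integers(
            int(params["low_min"]), int(params["low_max"]) + 1, size=n_low
        )
    return gq


def _call_genotype(site: VariantSite, alt_fraction: float) -> tuple[str, str]:
    """Naive genotype call from the observed alt-read fraction."""
    if alt_fraction < 0.1:
        return (site.ref_allele, site.ref_allele)
    if alt_fraction > 0.9:
        return (site.alt_allele, site.alt_allele)
    return tuple(sorted((site.ref_allele, site.alt_allele)))


def simulate_allograft_experiment(
    panel: GenotypePanel, config: SimulationConfig
) -> tuple[pd.DataFrame, VariantCallSet, pd.DataFrame, pd.DataFrame, MixtureTruth]:
    """Simulate the full grafting time course over a genotype panel.

    Returns ``(metadata, calls, allele_depths, tpm, truth)`` where
    ``allele_depths`` is a long table (sample_id, contig, position,
    ref_allele, alt_allele, alt_reads, ref_reads) of the per-site read
    depths also carried in ``calls``, ``tpm`` is a gene × sample TPM frame
    and ``truth`` records each sample's true host fraction.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x5EA]).generate_state(1)[0]
    )
    meta = _sample_plan(config)
    e = config.sequencing_error_rate
    depth = config.mean_depth
    sites = panel.sites

    # per-individual alt-dosage vectors over sites, computed once
    alt_frac: dict[str, np.ndarray] = {
        ind: np.array([panel.alt_fraction(ind, s) for s in sites])
        for ind in panel.individuals
    }
    zero = np.zeros(len(sites))

    calls = VariantCallSet()
    depth_rows = []
    truth_rows = []
    for row in meta.itertuples(index=False):
        h = float(config.mixing_schedule[row.time_point])
        truth_rows.append(
            dict(
                sample_id=row.sample_id,
                donor_id=row.donor_id,
                host_id=row.host_id,
                time_point=row.time_point,
                host_fraction=h,
                expected_donor_reads_per_site=depth * (1.0 - h),
                expected_host_reads_per_site=depth * h,
            )
        )
        # noiseless mode suppresses the low-GQ band too: expected-count
        # emission with no call randomly lost to the quality filter, so the
        # closed-form rate identities hold exactly over the full marker set
        gq_params = (
            {**config.gq_distribution, "low_fraction": 0.0}
            if config.noiseless
            else config.gq_distribution
        )
        gq_values = _draw_gq(rng, gq_params, len(sites))
        fd = alt_frac[row.donor_id]
        fh = alt_frac[row.host_id] if row.host_id else zero
        f = (1.0 - h) * fd + h * fh
        f_obs = f * (1.0 - e) + (1.0 - f) * e
        if config.noiseless:
            alt_vec = depth * f_obs
        else:
            alt_vec = rng.binomial(depth, f_obs).astype(float)
        ref_vec = depth - alt_vec
        for site, gq, alt_reads, ref_reads in zip(sites, gq_values, alt_vec, ref_vec):
            alt_reads = float(alt_reads)
            ref_reads = float(ref_reads)
            genotype = _call_genotype(site, alt_reads / depth)
            calls.add(
                VariantCall(
                    sample_id=row.sample_id,
                    site=site,
                    genotype=genotype,
                    genotype_quality=int(gq),
                    allele_depths=(ref_reads, alt_reads),
                )
            )
            depth_rows.append(
                (
                    row.sample_id, site.contig, site.position,
                    site.ref_allele, site.alt_allele, ref_reads, alt_reads,
                )
            )

    allele_depths = pd.DataFrame(
        depth_rows,
        columns=[
            "sample_id", "contig", "position", "ref_allele", "alt_allele",
            "ref_reads", "alt_reads",
        ],
    )
    truth = MixtureTruth(samples=pd.DataFrame(truth_rows))
    tpm = _simulate_expression(meta, config, rng)
    return meta, calls, allele_depths, tpm, truth


def _simulate_expression(
    meta: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Gene × sample TPM frame following the archetype programs.

    Panel genes are pearl-sac (donor-tissue) specific, so the measured TPM
    of a sample with host fraction *h* is the program mean times ``1-h``,
    with multiplicative log-normal noise unless in noiseless mode. Genes are
    split evenly over the archetypes in program order.
    """
    groups = list(config.expression_programs)
    gene_rows = []
    for g in range(config.n_genes):
        group = groups[g % len(groups)]
        gene_rows.append((f"gene{g + 1:04d}", group))
    tp_index = {tp: i for i, tp in enumerate(TIME_POINTS)}

    values = np.empty((config.n_genes, len(meta)))
    for j, row in enumerate(meta.itertuples(index=False)):
        h = float(config.mixing_schedule[row.time_point])
        t = tp_index[row.time_point]
        means = np.array(
            [config.expression_programs[grp][t] for _, grp in gene_rows]
        )
        measured = means * (1.0 - h)
        if not config.noiseless and config.expression_noise_sd > 0:
            noise = rng.normal(0.0, config.expression_noise_sd, size=config.n_genes)
            measured = measured * np.power(10.0, noise)
        values[:, j] = measured
    return pd.DataFrame(
        values,
        index=pd.Index([g for g, _ in gene_rows], name="gene_id"),
        columns=list(meta["sample_id"]),
    )


def gene_panel_table(config: SimulationConfig) -> pd.DataFrame:
    """Gene-panel table (gene_id, layer_class) matching the simulated genes.

    Archetype names that are shell-layer classes map through directly; any
    other program name is classed ``other``.
    """
    groups = list(config.expression_programs)
    known = {"prismatic", "nacreous", "both"}
    rows = []
    for g in range(config.n_genes):
        group = groups[g % len(groups)]
        rows.append(
            dict(
                gene_id=f"gene{g + 1:04d}",
                layer_class=group if group in known else "other",
            )
        )
    return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: genotypes + experiment in one call."""
    panel = simulate_genotypes(config)
    return simulate_allograft_experiment(panel, config)


# ---------------------------------------------------------------------------
# on-disk dataset


def _write_vcf(
    path, meta: pd.DataFrame, calls: VariantCallSet
) -> None:
    """Emit a minimal multi-sample VCF v4.2 with FORMAT GT:GQ:AD.

    Allele depths are rounded to integers as the format requires; missing
    calls are written as ``./.``.
    """
    samples = list(meta["sample_id"])
    sites = sorted(calls.sites)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pearldecon-synthetic\n")
        for contig in sorted({s.contig for s in sites}):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n'
        )
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for site in sites:
            fields = [
                site.contig,
                str(site.position),
                ".",
                site.ref_allele,
                site.alt_allele,
                ".",
                "PASS",
                ".",
                "GT:GQ:AD",
            ]
            for sample in samples:
                call = calls.get(sample, site)
                if call is None:
                    fields.append("./.:.:.,.")
                    continue
                n_alt = sum(a == site.alt_allele for a in call.genotype)
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[n_alt]
                gq = "." if call.genotype_quality is None else str(call.genotype_quality)
                ref_d = int(round(call.allele_depths[0]))
                alt_d = int(round(call.allele_depths[1]))
                fields.append(f"{gt}:{gq}:{ref_d},{alt_d}")
            fh.write("\t".join(fields) + "\n")


def write_dataset(
    outputs: tuple[pd.DataFrame, VariantCallSet, pd.DataFrame, pd.DataFrame, MixtureTruth],
    directory,
    panel_table: Optional[pd.DataFrame] = None,
) -> dict[str, str]:
    """Write a simulated dataset to ``directory``; returns the file paths.

    Files: ``variants.vcf`` (multi-sample, FORMAT GT:GQ:AD),
    ``metadata.tsv``, ``expression_tpm.tsv``, ``gene_panel.tsv`` and
    ``truth.tsv``. The VCF round-trips through :func:`pearldecon.
    variant_ingest.read_vcf` losslessly for integer depths.
    """
    import os

    meta, calls, _depths, tpm, truth = outputs
    os.makedirs(directory, exist_ok=True)
    paths = {
        "vcf": os.path.join(directory, "variants.vcf"),
        "metadata": os.path.join(directory, "metadata.tsv"),
        "expression": os.path.join(directory, "expression_tpm.tsv"),
        "gene_panel": os.path.join(directory, "gene_panel.tsv"),
        "truth": os.path.join(directory, "truth.tsv"),
    }
    _write_vcf(paths["vcf"], meta, calls)
    meta.drop(columns=["host_id"], errors="ignore").to_csv(
        paths["metadata"], sep="\t", index=False
    )
    tpm.to_csv(paths["expression"], sep="\t", float_format="%.6g")
    if panel_table is None:
        panel_table = pd.DataFrame(
            dict(gene_id=tpm.index, layer_class="other")
        )
    panel_table.to_csv(paths["gene_panel"], sep="\t", index=False)
    truth.samples[["sample_id", "host_fraction"]].to_csv(
        paths["truth"], sep="\t", index=False
    )
    return paths
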