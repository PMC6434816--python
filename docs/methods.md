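# Methods

## Estimator

The pipeline estimates, per RNA-seq sample, the fraction of transcripts
contributed by host tissue in a same-species (allograft) mixture, using
only a VCF with per-sample genotypes (GT), genotype qualities (GQ) and
allele depths (AD), plus a sample sheet mapping samples to donors and
time points.

**Donor-specific SNVs.** For donor *d* with 0 h reference sample *r(d)*,
the marker set is every biallelic SNV site whose alt allele is (a) present
in *r(d)*'s called genotype and (b) absent from the called genotype of
every sample belonging to a different donor. Samples of the same donor at
other time points never veto a site — they legitimately carry the allele.
A stricter read-level mode (`read_level=True`) additionally vetoes sites
with any alt-supporting read in an other-donor sample; the genotype-level
rule is the default because the marker definition is a statement about
called variants, and stray single reads are dominated by sequencing error.
Calls with GQ < 10 are removed first (missing GQ fails any positive
threshold; a threshold of 0 disables the filter entirely).

**Rates.** Reads are pooled across marker sites (micro-average), not
averaged per site, so site coverage acts as a natural weight:

    raw(s)  = Σ_sites alt reads / Σ_sites total reads
    rate(s) = 100 · raw(s) / raw(r(d))   [clamped to ≤ 100]

The reference's own normalized rate is exactly 100 by construction. The
normalization cancels allele dosage: a mix of heterozygous and homozygous
marker sites gives the same expected rate 100·(1−h) for host fraction h,
because numerator and denominator scale by the same mean dosage. Samples
with zero pooled depth get a missing rate — never an imputed 0 or 100.

**Contamination and adjustment.**

    contamination(%) = 100 − rate(%)
    adjusted TPM     = TPM · 100 / (100 − contamination(%))

The adjustment is a single scalar per sample, applied uniformly to all
panel genes; it is exact for transcripts expressed only in donor tissue
and is an upper correction for genes the host also expresses. Estimates
reaching 100% contamination are capped (default 99.9%) with a warning so
the divisor never hits zero; capped samples are flagged in the output.
Adjusted columns are not renormalized to sum to 10⁶ — adjusted values are
comparable abundances, not a re-closed composition. Applying the
adjustment to donor-pure pre-graft samples reproduces the estimator's
known small underestimation there (their rates fall slightly below 100
from sampling noise and are clamped); the pipeline surfaces this in its
recovery reports rather than correcting for it.

Floating-point care: ratios are computed before scaling (`100·(raw/ref)`,
`TPM·(100/(100−c))`) so the identity cases — sample equal to reference,
contamination zero — are bit-exact, not merely close.

## Simulator

The generator emulates the grafting study design: `n_donors` = 3 donor
oysters; nine sampling points (cell, before, 0 h — donor-pure; 24 h …
3 m — pearl sacs in host oysters); `n_replicates` = 2 replicate hosts per
post-graft sampling, each host a distinct individual (36 hosts by
default). The default mixing schedule rises from h = 0 at the donor-pure
points through 0.05/0.10 at 24/48 h to 0.55–0.75 at 1 w–3 m, matching the
qualitative course of the experiment (mostly donor reads before 1 week,
mostly host after).

**Genotypes.** Two site classes:

* *Planted donor-private markers* (`n_private_sites_per_donor`, default
  100 per donor): the owning donor carries the alt allele (heterozygous
  with probability 2/3, as rare variants mostly are), every other
  individual is homozygous reference. Donor-private alleles are planted
  rather than drawn because privacy is a joint condition over all ~39
  simulated individuals: under a neutral per-site allele-frequency draw
  the expected yield of private sites is essentially zero, and any
  frequency high enough to yield them also puts the allele in the donor's
  own hosts, which biases the estimator by construction rather than by
  behavior.
* *Hardy–Weinberg background* (the remaining sites, alt-allele frequency
  0.3): shared variation that the extraction step must reject, exercising
  the other-donor veto logic.

**Reads.** Per sample and site, total depth is fixed at `mean_depth`
(default 200) and the alt-read count is binomial with success probability
`f' = f(1−e) + (1−f)e`, where `f = (1−h)·f_donor + h·f_host` is the
mixture allele-dosage fraction and `e` the symmetric per-read error rate
(default 0.005). Genotypes are re-called from the observed alt fraction
(<0.1 hom-ref, >0.9 hom-alt, else het), and GQ is drawn independently of
correctness: 5% of calls fall below the GQ 10 filter, the rest in 30–99.
The estimation pipeline consumes these calls exactly as it would GATK
output.

**Noiseless mode** (`noiseless=True`, error rate 0) emits exact expected
counts (`depth·f`, possibly non-integer in memory; rounded in the VCF)
and suppresses the low-GQ band, so the closed-form identities — pure
samples at exactly 100%, mixed samples at exactly 100·(1−h) — hold to
machine precision. Exactness tests therefore run in memory; round-trip
tests use the stochastic integer path.

**Expression.** Panel genes (default 192) follow three trajectory
archetypes over the nine time points — early-high "prismatic"
(peaking 24–48 h then collapsing), late-high "nacreous" (rising from
1–2 w), and V-shaped "both" (high early, dipping at 1 w, recovering) —
with the regime switch at 1 w, when pearl-sac formation completes.
Measured TPM is the archetype mean times the donor fraction (1−h) —
panel genes are pearl-sac specific, so host tissue dilutes them — with
multiplicative log-normal noise (σ = 0.2 in log10). Magnitudes are
arbitrary; only the trajectory shapes and the dilution matter to the
pipeline. Real data differ in ways the simulator does not attempt:
gene-length and library-composition effects in TPM, overdispersed
coverage, allele-specific expression, mapping bias at variant sites, and
host expression of panel genes. Passing tests therefore demonstrate the
estimator's correctness under its stated model, not the biological
fidelity of any particular contamination value.

## Profiling

PCA treats samples as observations over log10(TPM+1), mean-centered per
gene; component signs are fixed (largest-magnitude loading positive) for
reproducibility. Gene clustering z-scores the log-trajectories and uses
correlation distance with average linkage (both configurable — trajectory
shape, not magnitude, defines the groups); the dendrogram is cut to
`n_groups` (default 4) and groups are lettered A, B, … by leaf order,
left to right, as heatmap group labels read. Constant gene rows get a
zero profile plus a tiny deterministic tilt so correlation distance stays
defined. Trajectory export averages adjusted TPM over replicates per time
point and reports the replicate count actually used.

## Problem sizes and numerical choices

The validation experiments are sized for quick, reproducible runs: the
default simulated dataset is 45 samples × 500 sites at depth 200
(≈100 marker sites per donor, pooled depth ≈2×10⁴ reads, giving
sub-point standard error on the rate), and the recovery benchmark uses
500 marker sites per donor at depth 200 over true host fractions
0.1–0.9, where the estimate lands within 1 percentage point of truth.
The mixture-convergence property is checked at depth 10⁴ (tolerance
0.01). All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical config and seed reproduce every
output byte-identically.

## Known limitations

* Point estimates only — no uncertainty intervals on contamination.
* The genotype-level veto cannot exclude a marker shared with a host of
  the *same* donor (such hosts appear in no other-donor sample); in the
  simulator planted markers are host-free by design, and in real designs
  this is an irreducible limitation of the 0 h-reference comparison.
* The adjustment assumes panel genes are silent in host tissue; for genes
  the host expresses it overcorrects.
* Indels and multi-allelic sites are excluded at ingest, not used.
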