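# pearldecon

Donor/host deconvolution of pearl-sac allograft transcriptomes from
donor-specific SNV read rates.

## The problem

Cultured pearls form inside a *pearl sac*: mantle tissue from a donor
pearl oyster (*Pinctada fucata*) is grafted into a host oyster's gonad,
where the donor's epithelial cells proliferate around the nucleus and
secrete the pearl's shell layers. Pearl-sac RNA-seq samples taken weeks to
months after grafting are unavoidably contaminated with the surrounding
host gonad tissue, and because donor and host are the same species the
contaminating transcripts cannot be separated by sequence homology.

They can, however, be separated by genotype. A donor's private SNVs —
alleles called in the donor's graft tissue at grafting time (the 0 h
reference) and in no sample derived from any other donor — act as genetic
barcodes for donor-origin reads. pearldecon implements this estimator and
the downstream expression correction:

1. **Donor-specific SNV rate.** Pool reads over the donor's private SNV
   sites: `raw rate = Σ donor-allele reads / Σ total reads`. Normalize to
   the 0 h reference, defined as 100%:
   `rate(%) = 100 · raw(sample) / raw(0 h)`.
2. **Contamination.** `contamination (%) = 100 − rate (%)`.
3. **Adjusted expression.** For genes expressed only in donor (pearl-sac)
   tissue, `adjusted TPM = TPM × 100 / (100 − contamination (%))`
   rescales measured abundance to the pure-donor scale.
4. **Profiling.** PCA of samples and hierarchical clustering of gene
   trajectories over a biomineralization gene panel (192 genes classed as
   prismatic-layer, nacreous-layer or both-layer forming) across the nine
   sampling points: cell, before, 0 h, 24 h, 48 h, 1 w, 2 w, 1 m, 3 m.

Because no deposited dataset exists at a size usable for validation, the
package ships a first-class simulator of the grafting design (3 donors,
9 time points, 2 replicate hosts per post-graft sampling) with known
mixing fractions, used throughout the tests.

## Worked example

```sh
pearldecon simulate --seed 5 --out ds
pearldecon run --vcf ds/variants.vcf --metadata ds/metadata.tsv \
    --expression ds/expression_tpm.tsv --panel ds/gene_panel.tsv --out res
head -4 res/snv_rates.tsv
```

prints

```
sample_id	donor_id	time_point	n_sites_used	raw_rate	normalized_rate_percent	reference_sample_id
donorA_cell	donorA	cell	88	0.6759659091	100	donorA_0h
donorA_before	donorA	before	86	0.6737790698	100	donorA_0h
donorA_0h	donorA	0h	92	0.6725	100	donorA_0h
```

Each row is one sample's pooled donor-specific SNV read rate: `raw_rate`
is the fraction of reads at the donor's private SNV sites that carry the
donor allele (≈0.67 here because most planted markers are heterozygous),
and `normalized_rate_percent` expresses it relative to the 0 h reference.
Donor-pure samples (cell, before, 0 h) sit at 100%; post-graft pearl-sac
samples drop towards 25–45% as host tissue takes over.
`res/contamination.tsv` holds the complementary contamination
percentages, `res/adjusted_expression.tsv` the corrected TPM matrix, and
`res/pca_scores.tsv` / `res/gene_clusters.tsv` / `res/trajectories.tsv`
the panel profiling.

The same steps are available as a narrative analysis under `analysis/`
(`01_simulate_dataset.py` … `05_recovery_experiment.py`), each printing
what it found and writing its tables under `results/`. On the default
design (seed 1), the estimator recovers the true contamination within
1.8 percentage points at every sample, and within 0.8 points in the
dedicated benchmark with 500 marker sites per donor.

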