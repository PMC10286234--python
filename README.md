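# hmkpop

Pool-seq population structure and local-adaptation analysis for marine
metapopulations.

`hmkpop` is a Python toolkit for analysing pooled whole-genome sequencing
(pool-seq) of population samples — the design used in marine fisheries
genomics, where one barcoded library is sequenced per pool of 30–96 fish and
the data deliver population allele frequencies but no individual genotypes.
It implements the full analysis chain from per-SNP read-count tables to
candidate adaptive loci:

- **Allele frequencies with effective-coverage correction.** Pool-seq counts
  arise from two nested sampling steps (chromosomes into the pool, reads from
  chromosomes). The effective coverage
  `n_eff = (nC − 1)/(n + C)` (haploid pool size `n`, depth `C`) bounds the
  information per site by both depth and pool size.
- **Pairwise pool-F<sub>ST</sub> with block-jackknife CIs.** A
  method-of-moments ANOVA estimator built from identity-in-state
  probabilities: within-pool identity `Q1` is deconvolved from read pairs via
  the probability `1/n` that two reads hit the same chromosome, and
  `F_ST = (Q1 − Q2)/(1 − Q2)` is aggregated as a ratio of sums over SNPs. It
  reduces to Weir & Cockerham's θ as depth → ∞. Standard errors come from a
  delete-one block jackknife over blocks of 1000 consecutive SNPs.
- **Isolation-by-distance**: Rousset-linearized `F_ST/(1 − F_ST)` regressed
  on great-circle km, Mantel permutation test.
- **dAF genome scans**: per-SNP `dAF = |mean AF(group1) − mean AF(group2)|`
  between contrasts of grouped pools, 100-SNP rolling means, Bonferroni
  Z-score outlier flagging, region calling and top-2% SNP extraction.
- **Marker classification and PCA**: undifferentiated vs highly
  differentiated SNP sets by across-pool frequency SD, positional thinning,
  centered allele-frequency PCA.
- **Windowed nucleotide diversity** (π) per pool, 10 kb windows / 2 kb step.
- **Redundancy analysis (RDA)** linking outlier-SNP frequencies to
  standardized environmental predictors, with permutation pseudo-F tests and
  candidate-SNP extraction by axis loadings (> 1 SD).
- **Inversion genotyping** from diagnostic SNPs: PCA + k-means into three
  clusters (two homozygous arrangements and heterozygotes, validated by the
  heterozygote cluster's elevated observed heterozygosity), plus per-site
  arrangement frequencies.
- **SNP-panel design**: call-rate QC, exact Hardy–Weinberg tests, LD
  grouping, per-locus Weir–Cockerham F<sub>ST</sub>, panel reduction,
  individual PCA and sNMF-style NMF admixture with masked cross-entropy
  model selection.
- **A synthetic-data generator** that emulates the full sampling design —
  Balding–Nichols background divergence, planted outlier loci, a 9.9 Mb
  inversion segregating along a latitudinal cline, temperature covariates —
  with complete ground truth for validation.

## Worked example

Simulate an 11-pool study along the eastern Atlantic cline, estimate
pairwise pool-F<sub>ST</sub>, scan a North Sea contrast, and genotype the
planted inversion:

```python
import numpy as np
import hmkpop as hp

cfg = hp.default_config(seed=42, n_neutral_snps=4000)
truth = hp.simulate_metapopulation(cfg)
counts = hp.pool_and_sequence(truth)
freqs = hp.estimate_frequencies(counts)

fst = hp.pairwise_fst_matrix(counts)
iu = np.triu_indices(len(fst), k=1)
print(f"mean pairwise pool-FST: {fst.to_numpy()[iu].mean():.4f}")

contrast = hp.Contrast(
    name="north_sea", group1=["NOS1", "NOS2"],
    group2=[p for p in cfg.site_ids if not p.startswith("NOS")],
)
scan = hp.scan_contrast(freqs, contrast)
for r in scan.regions:
    print(f"region {r.chrom}:{r.start}-{r.end} ({r.n_snps} SNPs)")

diag = np.where(truth.diagnostic_mask)[0]
geno = hp.genotype_panel_sample(truth, n_per_site=20, snp_list=diag)
lat = dict(zip(cfg.site_ids, cfg.latitudes))
calls = hp.InversionGenotyper(geno, site_latitudes=lat).fit(seed=0)
print(calls.summary())
```

Output:

```
mean pairwise pool-FST: 0.0111
region chr1:17408130-17598310 (20 SNPs)
Inversion genotyping
  cluster 1: 138 individuals, Ho = 0.000
  cluster 2: 47 individuals, Ho = 1.000
  cluster 3: 35 individuals, Ho = 0.000
  southern-haplotype frequency per site:
    MED: 0.050
    NAF: 0.850
    ...
```

The mean pairwise pool-F<sub>ST</sub> of ~0.01 reflects the configured
low-divergence background plus the planted adaptive loci; the scan recovers
the planted North Sea locus on chr1 around 17.5 Mb as a single region; the
inversion genotyper separates the three arrangement classes perfectly (the
middle cluster is 100% heterozygous) and re-estimates the planted
latitudinal cline of arrangement frequencies.

The same analyses are available from the shell:

```sh
hmkpop simulate --out sim/ --seed 42
hmkpop fst --counts sim/counts.tsv --meta sim/meta.tsv --out fst.tsv
hmkpop run --config run.yaml --out results/
```

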