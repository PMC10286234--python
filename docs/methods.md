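# Methods

This note documents the statistical models behind `hmkpop`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducibility.

## Pool-seq sampling model

All pool-seq estimators treat an observed read count as the outcome of two
nested binomial samples: `2N` chromosomes drawn from the population into the
pool (diploid pool size `N`), then `C` reads drawn with replacement from
those chromosomes. Two consequences run through the package:

1. **Effective coverage.** The information at a site is bounded by both the
   depth and the pool, captured by `n_eff = (2N·C − 1)/(2N + C)`. `n_eff` is
   monotone in both arguments and converges to `2N` as `C → ∞` and to `C` as
   `N → ∞`. A `floor` variant truncates to an integer chromosome count;
   the real-valued form is the default. Corrected counts are
   `round(freq · n_eff)`. Frequencies themselves are always the raw alt-read
   proportion — the correction rescales the *weight* of a site, not its
   estimate.
2. **Pool-F<sub>ST</sub>.** For a pool with `n = 2N` chromosomes and alt/ref
   read counts `(a, r)`, the fraction of identical read pairs
   `P = [a(a−1) + r(r−1)]/[c(c−1)]` mixes same-chromosome pairs (probability
   `1/n`, always identical) with distinct-chromosome pairs, so
   `Q1 = (nP − 1)/(n − 1)` estimates within-pool identity-in-state without
   read-depth bias. Between pools, reads always come from distinct
   chromosomes and `Q2 = p₁p₂ + q₁q₂` needs no correction. The estimator
   `F_ST = (ΣQ1 − ΣQ2)/(Σ1 − ΣQ2)` (ratio of sums over SNPs, the standard
   aggregation for low-information SNPs) reduces to Weir & Cockerham's
   two-population θ in the infinite-depth limit, and is unbiased for the
   Balding–Nichols divergence parameter in simulation (verified at F = 0.01
   with 5000 SNPs, depth 40, pools of 50). SNPs with fewer than two reads in
   either pool carry no pair information and are excluded.

Uncertainty comes from a delete-one block jackknife over blocks of 1000
consecutive SNPs (configurable): `SE² = ((B−1)/B)·Σ(θ₍ᵢ₎ − θ̄₍·₎)²`, CI =
estimate ± 1.96·SE. Blocks are contiguous in genome order, so the jackknife
is robust to local LD between SNPs.

## Isolation by distance

Pairwise estimates are linearized as `F_ST/(1 − F_ST)` and regressed on
great-circle ("as the crow flies") distance on a 6371-km sphere. The Mantel
test permutes site labels and is one-sided for a positive association, the
standard direction for isolation-by-distance; `p = (1 + #{r* ≥ r})/(B + 1)`.
An estimate of exactly 1 cannot be linearized and raises an error naming the
pair. Group-level mean-F<sub>ST</sub> comparisons use the exact two-sided
Wilcoxon rank-sum test with Holm ("sequential Bonferroni") adjustment across
the declared family of comparisons.

## dAF genome scan

Differentiation per SNP is `dAF = |mean AF(group1) − mean AF(group2)|` with
unweighted means over the informative pools of each group (matching the
statistic as defined, rather than a depth-weighted variant). Smoothing is a
centered rolling mean over exactly `window` consecutive SNPs (default 100)
computed within chromosomes; positions without a full window are missing.
Note the centered label of an even window is asymmetric by half a position —
properties that rely on reversal symmetry hold exactly for odd windows.

Outliers are flagged against a genome-wide empirical Gaussian null: `z =
(dAF − mean)/SD` over all non-missing SNPs, flagging where the upper-tail
normal p-value is below `alpha / n_tests` (Bonferroni). The choice of the
genome-wide empirical mean/SD as the null is deliberate and configurable (a
symmetric trimming fraction is exposed for heavy-tailed scans). Both the
per-SNP and rolling-mean surfaces are emitted; flags are computed on the
per-SNP surface, where the Bonferroni count is well defined.

Regions are maximal runs of flagged SNPs with consecutive flagged SNPs at
most `merge_gap_bp` apart (default 100 kb) and at least `min_snps` members
(default 5); the span runs from the first to the last flagged SNP. These
defaults keep a contiguous multi-megabase signal (e.g. the simulated 9.9 Mb
inversion cline scanned in a north-vs-south contrast) as one region while
rejecting isolated false flags. Per region, the top `ceil(q·n)` SNPs by dAF
(default q = 0.02, ties resolved to the leftmost position for determinism)
feed downstream analyses; a per-region cap of 10 supplies the RDA input set.

## Marker classification and PCA

SNPs are partitioned by the sample SD of their frequencies across pools:
SD ≤ low → presumed neutral, SD ≥ high → presumed selected, middle band
discarded. The cutoffs (defaults 0.02 / 0.2) are configuration, not
estimates. Thinning is greedy left-to-right (keep a SNP iff ≥ spacing from
the last kept SNP on that chromosome; spacings default to 1 kb for the
neutral set, 10 kb for the selected set, where linkage is stronger); a
`max-sd` mode keeps the most differentiated SNP per window instead.
Frequency PCA centers each SNP column and does **not** scale to unit
variance — standard for allele frequencies, where the variance itself is the
signal. Missing cells are mean-imputed per SNP. Components with zero
variance are dropped rather than reported as 0%.

## Nucleotide diversity

Site heterozygosity is `2p(1−p)·C/(C−1)` — the `C/(C−1)` factor corrects
the small-sample bias of estimating `2pq` from `C` reads. This depth-based
correction replaces the full combinatorial min-count correction used by
pooled-diversity tools; it is pluggable, and exact parity with those tools
is a non-goal. Sites below `min_coverage` (default 4) are excluded and
reduce the covered fraction. Window π (default 10 kb window, 2 kb step) is
the sum of site values over the covered window length, as a percentage. With
SNP-only input the per-base depth of invariant sites is unknown; they are
assumed covered, which makes the reported π a lower-bound approximation —
windows are comparable between pools but the absolute level depends on that
assumption.

## Redundancy analysis

Environmental predictors are standardized to zero mean and unit variance
(constant columns are rejected) and pruned greedily for collinearity: walk
the variables in a priority order (temperature mean and range first by
default) and keep one iff its squared correlation with every kept variable
is below 0.7. The RDA itself is ordinary least squares of the column-
centered frequency matrix on the centered predictors followed by an SVD of
the fitted values; constrained axes are the left singular vectors scaled by
their singular values, SNP loadings the right singular vectors, and
`proportion constrained = tr(Ŷ'Ŷ)/tr(Y'Y)`. The implementation agrees with
`vegan::rda` to 6 significant figures on test fixtures (eigenvalues after
dividing by n−1, vegan's variance scaling).

Significance uses permutation pseudo-F tests (default 1000 permutations):
rows of the predictor matrix are permuted for the model test; axes are
tested sequentially against the residual variance and testing stops at the
first non-significant axis; marginal predictor tests permute one predictor's
residuals given the others. p = (1 + #{F* ≥ F})/(B + 1) throughout.

Candidate SNPs are those whose loading on a significant axis lies more than
`sd_multiplier` (default 1) SDs from the loading distribution's center. The
center is the mean loading by default (a zero-centered variant is a flag) —
with hundreds of near-symmetric loadings the two differ negligibly, but
mean-centering is robust to a dominant axis polarity. Each candidate is
attributed to the predictor with the highest squared correlation to its
frequency column. A degenerate loading distribution (SD 0) yields no
candidates, and no significant axis yields an empty list, not an error.

## Inversion genotyping

Individuals are projected by centered PCA of their dosages at the diagnostic
SNPs (missing calls mean-imputed per SNP) and clustered by k-means (k = 3,
25 seeded k-means++ restarts, best inertia) on the first two components,
relabelling clusters 1..3 by ascending PC1 centroid. Because dosage polarity
is arbitrary, the "southern" arrangement is defined as the pole enriched in
a declared reference site — by default the southernmost site by latitude.
Validation: the middle cluster must show the highest observed
heterozygosity (fraction of calls equal to 1 across diagnostic SNPs).
Per-site arrangement frequency is `(2·hom + het)/(2n)`. The diagnostic SNP
list is an input; its length is not fixed by the package.

At 20 individuals per site the binomial sampling SD of a site frequency near
0.5 is ~0.08, so re-estimation of a planted cline is accurate to ±0.1 in
expectation but individual seeds can exceed that purely through individual
sampling; the recovery tests therefore check the estimate against the
sampled individuals' true genotypes per seed and against the planted cline
on the across-seed mean.

## SNP panel

QC retains markers, then individuals, with call rate strictly above 0.8
(markers first so that a failed assay does not drag individuals down), then
drops monomorphic markers and markers with opposite-homozygote conflicts
between declared replicate pairs. The Hardy–Weinberg test is the exact
conditional test: enumerate all heterozygote counts compatible with the
observed allele counts, with weights `2^h·n!/(n_AA!·h!·n_aa!)`, and sum the
probabilities of configurations no more likely than the observed one. The
test is conservative (super-uniform p-values) by construction, as every
exact conditional test is. Holm adjustment is applied within each test
family (HWE; LD).

LD between markers is the squared Pearson correlation of dosage vectors over
individuals called at both (≥ 10 required), with a permutation p-value.
Linkage groups are connected components of the union of Holm-significant
pairs and same-chromosome pairs within 1 Mb — physical proximity links a
pair regardless of significance, since a non-significant test at n = 160 is
weak evidence of independence. Panel reduction keeps the marker with the
highest mean per-locus Weir–Cockerham F<sub>ST</sub> (mean over population
pairs) per group, ties to the lowest position.

Per-locus F<sub>ST</sub> from genotypes is the 1984 Weir–Cockerham
variance-components estimator (a, b, c with the heterozygosity terms);
multi-locus and pairwise values are ratios of summed components.
Populations with fewer than two typed individuals at a locus are dropped
from that locus.

### Admixture

Ancestry is estimated by factorizing the individuals × markers dosage/2
matrix as `Q·G` with `Q` rows on the probability simplex and `G` in [0, 1]:
alternating least squares where the `G` update is a ridge-stabilized solve
clipped to the box, and each `Q` row is solved by nonnegative least squares
on a system augmented with the equation `α·Σq = α` (α = 10) that softly
enforces the simplex, followed by exact renormalization. Missing and
held-out entries are handled EM-style (filled with the current `Q·G` before
each solve). This is a methodological reimplementation of the sNMF family —
same model, same selection criterion, none of the original's spectral
details.

Model selection masks a fraction (default 5%) of observed entries per
repetition and scores the held-out prediction by binomial cross-entropy with
predictions clamped to [1e−6, 1−1e−6]. One mask is drawn per repetition and
shared across all K, so cross-entropy comparisons between K are paired
within a repetition — this removes mask noise from the comparison and is
why per-repetition rankings of K are stable. The selected K is the smallest
K whose mean cross-entropy is within one SE of the minimum (plateau rule).

## The synthetic-data generator

The generator emulates: 9–11 pools of 30–96 diploids at 25–46× depth along a
latitudinal gradient (defaults use the study's pool sizes and coordinates);
neutral background SNPs whose per-site frequencies are independent
Balding–Nichols draws (Beta with mean = ancestral frequency, variance
parameter F, default 0.007 — the observed low-differentiation regime);
localized outlier loci with exact per-site target frequencies (optionally
pinning the background SNPs in their span, which emulates the diversity loss
of a sweep); one 9.9 Mb inversion whose diagnostic SNPs are in complete
association with the arrangement; and temperature covariates linear in
latitude with Gaussian noise plus a warm anomaly for the Mediterranean-style
site. Sequencing is the two-level binomial model above with Poisson depth
(an overdispersed depth model is out of scope). A single seed fans out into
named substreams (frequencies, individuals, chromosomes, depths, reads,
dropout, environment), so each stage is independently reproducible and runs
are byte-identical under a fixed seed.

Deliberately **not** emulated: linkage decay among neutral SNPs (draws are
independent given the site frequency, so the block jackknife sees less
autocorrelation than real data), within-pool relatedness, unequal DNA
contributions of individuals to a pool, mapping or reference bias, and
demographic history. Recovery tests on this generator therefore validate the
estimators under their own sampling assumptions; they do not certify
robustness to those artefacts.

Problem sizes in the validation suite (4000–6000 SNPs, 20 seeds, 200 null
replicates, 100-marker panels) were chosen as the smallest sizes at which
the targeted effects are comfortably resolvable relative to Monte-Carlo
noise.

## Numerical conventions

- Coordinates are 1-based inclusive everywhere in memory; BED output is the
  single 0-based, half-open surface.
- Missing genotype token is `NA`; missing depth is the count pair `0,0`
  (site untyped in that pool); frequencies are NaN exactly where depth is 0.
- Frequencies are always of the alt allele; minor-allele views are derived
  at display time. Alleles are stored as given (no reverse-complement
  logic).
- Permutation p-values are always `(1 + #{extreme})/(B + 1)`, so the
  smallest attainable p is `1/(B+1)`.
- Ties in top-SNP extraction and panel reduction resolve to the leftmost
  genomic position, making every ranking deterministic.
- Degenerate inputs fail loudly: zero-SD dAF series, constant environmental
  columns, rank-deficient predictor matrices, inverted classification cuts
  and out-of-bounds planted loci all raise `ValidationError` with the
  offending name.
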