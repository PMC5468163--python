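# Methods

`hybridzone` analyses a two-lineage secondary-contact system from a panel
of biallelic SNPs: it asks which loci diverged between the parental
lineages beyond what drift can explain, which loci introgress through the
admixed zone beyond what neutral admixture can explain, and whether the
two signals touch the same genes.

## Data model

Genotypes are alternate-allele counts in {0, 1, 2} with an explicit
missing code, one SNP per RAD contig after filtering (QUAL > 30,
biallelic SNPs only, one variant per contig by a seeded uniform draw,
minor-allele-frequency floor 0.05).  Any half-called genotype is treated
as missing.  All statistics are computed from non-missing alleles only;
no missingness threshold excludes loci, but a per-locus missing fraction
is always reported.  The allele orientation in storage is the VCF
alternate allele; east/west direction is attached downstream from
parental allele frequencies, never baked into storage.

## Divergence statistics

For each locus, with `p` the allele frequency from `n` sampled alleles:

* within-population diversity `pi = 2 p (1-p) n/(n-1)` (unbiased per-site
  heterozygosity; equals the mean pairwise difference over allele pairs);
* `delta_pi = pi_east - pi_west` — positive where the east is more diverse;
* Weir–Cockerham `F_ST` in the allele-count (haploid-sample) ANOVA form,
  negative estimates clamped to zero (panmixia) before any downstream
  use.  The haploid form is the clean contract for RAD allele counts with
  missingness; it can differ from genotype-aware implementations in the
  third decimal, which is the one deliberate numerical deviation here.
* `d_xy = p_w (1-p_e) + p_e (1-p_w)` — the probability two alleles drawn
  one from each population differ.

Outliers are flagged by Mahalanobis distance over the signed vector
(`F_ST`, `d_xy`, `delta_pi`) — signed, because loci at either diversity
extreme can be genuinely aberrant — using type-7 empirical quantiles and
strict `>` at the 95th (outlier) and 99th (strong) quantiles.  A
retention floor `F_ST > 0.2` then removes high-MD loci whose pattern
(shared intermediate-frequency alleles) is better read as balancing
selection.  A near-singular covariance is ridged with
`1e-8 * trace(S)/dim`.

## Neutral posterior-predictive null

The null for divergence is a two-population isolation coalescent in
mutational units: theta = 4*N*mu per site, time in expected substitutions
per site, pairwise coalescence rate `2/theta_i` within each population
and `2/theta_anc` in the ancestral population entered at time tau.
Mutations are JC69 over a finite locus (default 190 sites), so recurrent
and back mutation occur; each simulated locus contributes one uniformly
chosen polymorphic biallelic site, mirroring SNP-panel ascertainment
(skipped loci are counted and reported).  Default parameters are the
posterior means of a SNAPP-style fit to the empirical system —
`theta_west = 0.0592, theta_east = 0.217, theta_anc = 0.0615,
tau = 0.00578` — and a full run draws one batch of loci per posterior
sample (default 100 loci per row) with per-locus allele counts resampled
from empirical-like coverage distributions.

Useful closed forms used as test oracles: the expected branch length
separating one lineage from each population is `2 tau + theta_anc`
(0.0731 at the defaults), and within-population pairwise diversity equals
`theta_i` exactly when `theta_anc = theta_i`.  The simulator is also
cross-checked against msprime (an independent coalescent implementation)
on three parameter sets.

Empirical-vs-null comparison bins both distributions on [0, 1] in width
0.1 and Fisher-exact-tests each bin (two-sided, no multiple-testing
correction — the per-interval comparisons are reported raw).  The
false-positive estimate for a range is the ratio of simulated to
empirical mass, capped at 1.

## Genomic clines

Each admixed individual carries a hybrid index `h` (eastern genome
fraction); each locus carries a cline center `alpha` and rate `beta`.
The eastern-ancestry probability is

    Phi = h + 2 h (1-h) (alpha + beta (2h - 1)),  truncated to [0, 1],

so `alpha = beta = 0` gives the neutral diagonal `Phi = h`.  Admixed
genotypes are `Binomial(2, Phi p_e + (1-Phi) p_w)`; parental allele
counts give binomial likelihoods for `p_w, p_e` with Beta(1,1) priors;
`h ~ Uniform(0,1)`.

**Hierarchical locus effects.**  `alpha_i ~ N(0, sigma_alpha^2)` and
`beta_i ~ N(0, sigma_beta^2)` with inverse-gamma(2, s^2) hyperpriors
(s = 1 for alpha, 0.5 for beta), Gibbs-updated each sweep.  This is
deliberate: with 21 admixed individuals most loci carry little ancestry
information, and under fixed weakly-informative priors their posterior
medians wander to +-1, producing sporadic false excess-ancestry calls on
null data.  The hierarchical variance shrinks weakly-informed loci
toward the genomewide distribution — the behaviour of the established
genomic-cline software this model follows — and makes the null-admixture
benchmark (below) clean.  `hierarchical=False` restores fixed
`N(0,1)` / `N(0,0.5)` priors.

Sampling is Metropolis-within-Gibbs with reflected random-walk block
updates of {h}, {alpha}, {beta}, {p_w}, {p_e}; the blocks factorise, so
acceptance is element-wise and fully vectorised.  Step sizes adapt
during burn-in only (target acceptance 20–50%).  Defaults: 25,000
iterations, 2,500 burn-in, thin 5.  Minimum effective sample size (via
arviz) below a configurable floor triggers a warning, not an error.
Fixed seed gives byte-identical summaries.

**Classification.**  A locus has excess eastern ancestry when its 95%
alpha interval excludes 0, its median alpha is positive, and the median
lies above the 97.5th percentile of the genomewide median-alpha
distribution (mirror-image for west).  Strong ("gamma-quantile")
outliers evaluate each median alpha under a normal fitted to the
genomewide medians and flag quantiles outside `[n/2, 1 - n/2]` with
`n = 0.1`; an empirical-rank reading of the same rule is available.
Swapping the east/west labels negates alpha and mirrors all calls.

**Null-admixture benchmark.**  A null admixed population redraws each
gene copy from a uniformly chosen parental population's observed alleles
(21 individuals, 5 replicates by default).  Fitting clines to it must
yield no excess-ancestry loci; this is the package's calibration
benchmark and an acceptance test.

## Comparative layer

Pearson correlations relate `|alpha|` to `F_ST`, `d_xy`, `|delta_pi|`
and MD (absolute values: sign encodes direction, not strength), with
optional `F_ST`-thresholded subsets.  Gene overlap between outlier sets
is tested against 1,000 uniform resamples from the background of all
genes linked to analysed loci (p with the +1 correction, so never 0;
significance also reported as exceeding the null's 95th quantile).
Candidate-set enrichment is Fisher's exact test, one-sided (enrichment)
by default since every use is an enrichment claim, with a 0.5 continuity
correction on the sample odds ratio when a cell is empty.  East-vs-west
outlier counts are compared by the exact two-sided binomial at 0.5.

## Synthetic world

The generator's defaults state one world and keep it: parental
populations of 24 + 24 diploids simulated from the isolation coalescent
at the posterior-mean theta/tau above, with "true" allele frequencies
taken from a 60-allele coalescent frequency panel per population (so
truth frequencies are themselves isolation-model draws); an admixed
population of 21 individuals with hybrid indices on a uniform [0.2, 0.8]
grid (the empirical zone is broadly admixed with mean h near 0.46);
null-admixture defaults of 21 individuals and 5 replicates; a pseudo
posterior of 375 log-normal rows with CV 0.1 around the parameter means.

Planted divergence moves the two parental frequencies toward opposite
fixation by a fraction `boost` of their remaining distance to the
boundary (boost 1 = reciprocal fixation).  Scaling by distance-to-
boundary rather than by `min(p, 1-p)` keeps planted loci detectable even
at shared-rare-allele sites, which dominate the isolation-model spectrum;
a `min`-scaled shift leaves most planted loci statistically invisible
and would defeat the purpose of planting.

Synthetic gene annotations link each locus to one up- and one downstream
gene from a shared pool; designated candidate sets over-sample genes
linked to divergent loci by a configurable factor (1 = no planting).

What the generator does **not** emulate: linkage/recombination within or
between loci, post-contact migration during the parental divergence
phase (the null is isolation-only), spatial structure, genotyping error,
and realistic missingness patterns (tests inject missingness uniformly).
A green test therefore establishes correctness of the estimators and
samplers under the stated model, not robustness to those features.

## Identifiability and test design

Cline parameters are only identifiable where parental allele frequencies
differ: at the stated theta/tau roughly 95% of coalescent SNPs have
`|p_e - p_w| < 0.3`, and for those loci the alpha posterior is close to
its (shrunk) prior.  Parameter-recovery tests therefore plant signal at
ancestry-informative loci and use informative parental panels for the
hybrid-index check; calibration and the null benchmark keep the full
stated world.

## Runtime scaling

The default MCMC (25,000 iterations) and full posterior-predictive run
(375 rows x 100 loci) are the production settings.  The test suite and
the acceptance script run shortened chains (8,000 iterations, burn-in
2,000) and smaller simulation batches so the whole suite completes in a
few minutes on one CPU; recovery and calibration results quoted in tests
were verified stable under these settings.

## Known limitations

* The haploid-form `F_ST` differs slightly from genotype-aware
  estimators under Hardy–Weinberg departures.
* `d_xy` is per-SNP, not per-locus-sequence; fixed differences give
  `d_xy = 1` by construction.
* The cline sampler estimates parental frequencies jointly but ignores
  genotype uncertainty and linkage; its beta estimates are weakly
  identified at 21 admixed individuals and shrink strongly.
* The gamma-quantile classification assumes the genomewide median-alpha
  distribution is adequately normal; with heavy planted signal the
  fitted normal widens and the flags become conservative.
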