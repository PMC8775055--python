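# Methods

`hapssgwas` implements a haplotype-based single-step GWAS for an
ordered-categorical trait, together with a synthetic-data generator
that reproduces the statistical structure such an analysis assumes.
This note records the models, the defaults and why they were chosen,
and the limits of what the synthetic validation can show.

## The analysis pipeline

### Haplotype blocks and pseudo-SNPs

Pairwise LD between phased loci is measured as
r² = (p_AB − p_A p_B)² / (p_A(1−p_A) p_B(1−p_B)) on haplotype counts,
with missing calls excluded pairwise and monomorphic loci assigned
r² = 0 (such loci cannot support a block and are removed by QC anyway).
Blocks at a threshold (0.15, 0.50 or 0.80, matching assumed high,
medium and low recombination) are contiguous marker intervals whose
bounding pair reaches the threshold and in which at least
`min_pair_fraction` (default 0.5) of within-window pairs do too; a
non-overlapping subset maximizing the number of covered markers is
selected by weighted-interval dynamic programming, with ties broken
toward earliest-starting, then shortest, intervals so the output is
deterministic.  The DP optimum is verified against exhaustive
enumeration on chromosomes of ≤ 12 markers.  Markers left uncovered
are non-clustered SNPs (NCSNP).  Blocks have ≥ 2 loci by construction
and never span chromosomes; inter-marker distance never breaks a block
— only LD does.  This is a deterministic re-statement of variable-size
LD blocking; exact equivalence with any particular published block
finder is a non-goal.

Within each block, every distinct phased allele string becomes a
pseudo-SNP coded 0/1/2 by copy number.  A missing SNP call anywhere in
the block voids the individual's whole block (an allele string is
undefined with missing sites).  All unique alleles are retained as
columns even though they are linearly dependent (block dosages sum
to 2); invertibility is restored downstream by blending (see below).
A pseudo-SNP's representative position is the block's first SNP.
Pseudo-SNP columns get the same marker QC as SNPs (MAF < 0.01, call
rate < 0.90, |observed − expected heterozygosity| > 0.15, applied in
that order after the X-PAR position rule, animals filtered first); the
heterozygosity rule on pseudo-SNPs is a literal carry-over and is
approximate, since a pseudo-SNP column is not a biallelic locus.

### Single-step threshold model

The trait is analysed on the liability scale:

    l = X b + W w + Z u + e,
    w ~ N(0, I σ²_w),  u ~ N(0, H σ²_g),  e ~ N(0, I σ²_e),

with the observed score c = k iff t_{k−1} < l ≤ t_k.  H blends
pedigree and genomic information; its inverse is formed directly as

    H⁻¹ = A⁻¹ + [0 0; 0 τ(αG + βA22)⁻¹ − ωA22⁻¹]

with τ = ω = 1, α = 0.90, β = 0.10.  A is built by the tabular method
(inbreeding implicit; no unknown-parent groups), and G by VanRaden's
first method, G = (M−2p) D (M−2p)′ / 2Σp(1−p), with allele
frequencies from the genotyped set, missing dosages mean-imputed to
2p, and D the marker-weight diagonal (identity in the unweighted
analysis).  Dense linear algebra is used throughout; the intended
scale is up to a few thousand pedigree animals.

Variance components are fixed inputs, not estimated.  The Gibbs
sampler uses standard data augmentation: truncated-normal liability
draws per record, a single joint Gaussian draw of (b, w, u) via a
Cholesky factor of the (constant) full-conditional precision — chosen
over scalar Gibbs for mixing at the default 10,000-iteration chain —
and uniform draws of the C−2 interior thresholds between flanking
liability extremes.  Identification fixes t₁ = 0 and σ²_e at its
supplied value; b has a vague N(0, 10⁸) prior.  Defaults: 10,000
iterations, 1,000 burn-in, thinning 10 (900 retained draws).
Correctness anchors: with liabilities held fixed the posterior means
reproduce the dense mixed-model-equations solution; with C = 2 and
negligible random effects the fixed-effect posterior matches a probit
maximum-likelihood fit; σ²_g → 0 forces û → 0.

### Back-solving, variance shares and weighting

Marker effects are back-solved as g = D (M−2p)′ G*⁻¹ û over the
genotyped animals, where G* is the same blended matrix used inside
H⁻¹ (the raw all-allele G is singular, and using one genomic matrix
per iteration keeps prediction and association consistent).  The
normative scale is the identity (M−2p) g = 2Σp(1−p) û, asserted in
tests; the per-allele substitution effect entering the variance share
is therefore g/k with k = 2Σp(1−p), giving

    VEM%_i = 2 p_i (1−p_i) (g_i/k)² / σ²_g × 100,

which sums to ≈ 100 across markers when û explains all of σ²_g.
Block shares are VEH%_j = Σ member VEM%; NCSNPs report individually.

Weighted iterations use VanRaden's nonlinear-A rule,
d_i = 1.125^(min(|g_i|/sd(g), 5) − 2), with sd(g) taken genome-wide;
weights hence lie in [1.125⁻², 1.125³] ≈ [0.79, 1.42].  Iteration 1 is
the unweighted ssGWAS; iterations 2 and 3 rebuild G with the previous
iteration's weights (p held fixed) and re-run the chain with a fresh
deterministic seed derived from (base seed, iteration).

### Empirical top selection

Per-marker variance shares (zeros excluded from fitting, retained for
comparison) are fitted with a Beta or Gamma law.  Family choice offers
two rules.  The skewness–kurtosis rule places the observed moment pair
(bootstrap bias-corrected; the sample kurtosis of skewed data is
systematically low) relative to the Gamma locus k = 3 + 1.5 s²; points
clearly inside the Beta region below it select Beta, ties and
boundary cases select Gamma.  Because the Beta family contains Gamma
as its shape2 → ∞ boundary, moment (or any) discrimination is
impossible for near-boundary Betas; the pipeline therefore defaults to
a penalized likelihood rule in which Beta must beat Gamma by > 3 nats.
Percent values are rescaled by 1/100 for Beta fits.  The selection
threshold is the fitted quantile at CDF 1 − 10⁻⁵ ("top 0.001%",
read as the extreme upper tail), mapped back to the percent scale;
strictly larger values are selected, and an empty selection is legal.
Cross-scenario overlaps are counted on genomic intervals so a
pseudo-SNP block and an NCSNP at the same locus can match.

## The synthetic-data generator

The generator emulates a beef-cattle temperament study design: a
discrete-generation pedigree with alternating-sex founders and random
male–female pairings; phased founder haplotypes whose LD decays with
physical distance; gene dropping with Poisson recombination; an
ordered 4-category phenotype from a liability model; and masking of
genotypes (a genotyped subset, plus per-call missingness).

LD uses a latent-state copying chain: each haplotype carries a uniform
state that is retained between adjacent markers with probability
exp(−rate · distance) and refreshed otherwise, so equal-frequency
adjacent pairs have population r² = exp(−2 · rate · d);
`decay_rate_for_adjacent_r2` inverts this.  Allele frequencies are
constant within short geometric "frequency runs" (mean 5 markers),
creating complete-LD runs that are detectable as blocks at r² ≥ 0.8
while cross-run LD decays smoothly — the feature the block
constructor needs at all three thresholds.  A coalescent would be more
faithful but is unnecessary: the analysis consumes only r² structure.
The limits of this emulation: no mutation/genotyping error, no
population structure or selection, exchangeable contemporary groups,
and block boundaries much cleaner than on a real chip.  Passing tests
therefore demonstrate algorithmic correctness and statistical
behaviour under the assumed model, not robustness to real-data
artefacts.

Phenotypes: liability = covariates + contemporary-group effect +
breeding value + residual, with σ²_g = h² (default 0.38), σ²_w the CG
fraction (default 0.10) and σ²_e the remainder, on a unit
non-covariate scale.  Default category frequencies are
71.9/22.2/5.1/0.8%.  Thresholds are solved numerically so the
expected marginal frequencies equal the target exactly given the
realized systematic + genetic offsets (root-finding on
mean_i Φ((t − m_i)/σ_e)), which is the finite-sample version of
Gaussian marginal quantiles.  Covariates (age-of-dam class, conception
type, a linear age deviation) are small effects drawn once per configuration
(sd 0.1 by default), as their real magnitudes are not published.
QTL architecture is configurable (count and effect sd) rather than
asserted, the trait being known only as highly polygenic; callers may
also inject a custom genetic value to place focal QTL.

Gene dropping requires both parents known or none; pedigrees with
single known parents should be completed with dummy founders first.
Mendelian consistency, crossover-rate calibration, realized
heritability and category frequencies are all property-tested.

## Numerical choices and edge cases

- QC removals are attributed to the first failing rule in the fixed
  order PAR → call rate → MAF → heterozygosity; animals are filtered
  before markers and statistics recomputed.  "Above" the PAR boundary
  (133,300,518 bp on the X, labelled chromosome 30) is strict.
  The heterozygosity rule is two-sided by default with a config switch.
- Monomorphic or all-missing markers never crash anything: undefined
  r² is 0, undefined p is flagged and removed by call-rate/MAF rules.
- The blended matrix must have smallest eigenvalue > 1e-10, otherwise
  construction aborts naming it.  H⁻¹ is symmetrized to round-off.
- All random processes take explicit integer seeds; identical
  (config, seed) reproduce byte-identical outputs.

## Validation scale and known limitations

Simulation experiments run at a desk scale of roughly 2,000 pedigree
animals, 1,000–1,600 genotyped, and 500–1,500 markers on 2–3
chromosomes — about 1/30 of the motivating study — with the default
10,000-iteration chain.  At this scale GEBV stability across
nonlinear-A iterations (r > 0.98) and the two-SNP minimum block size
reproduce robustly.  Signal localization is information-limited: a
QTL carrying ~5% of σ²_g is recovered as the top-VEH% block only in a
minority-to-half of replicates, because a single ordered-categorical
record per animal caps GEBV accuracy near 0.77, which both attenuates
the focal block's share and creates phantom per-block shares of
comparable size; a large-effect QTL (~30% of σ²_g) localizes
essentially always.  This is a property of the study design at reduced
scale, not of the implementation (with GEBVs replaced by true breeding
values the focal block ranks first).

The upper-10⁻⁵ selection threshold on a few hundred markers is far in
the fitted tail, so selections are small or empty unless an outlier is
present — consistent with its purpose of flagging only extreme
regions.
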