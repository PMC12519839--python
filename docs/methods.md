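# Methods

This note documents the models, statistics and numerical choices behind
`mungomhc`, and what the synthetic-data generator does and does not
emulate.

## Amplicon genotype validation

Input is a per-sample variant table (sample, replicate, sequence, read
count); within-amplicon frequency is reads divided by the amplicon total.
The frequency threshold is estimated as the **median within-amplicon
frequency of putative artefacts**, where a putative artefact is any
variant within `max_distance_artefact` (default 2 nt, Hamming distance on
equal-length sequences; unequal lengths never merge) of a strictly
higher-frequency variant in the same amplicon. When no such variant
exists, a configured floor (default 0.01) is used.

Each unique sequence is then labelled by a three-rule procedure, applied
in priority order:

1. below the frequency threshold in every amplicon → artefact;
2. close to a higher-frequency variant, co-occurring with one in every
   amplicon where it appears, and never concordant across a sample's two
   replicates → artefact;
3. concordant across both replicates of at least one sample, or present
   in ≥ `min_samples` (default 3) samples at depth ≥ `min_reads`
   (default 10) → allele.

Sequences matching none of the branches lack allele-level support and are
artefacts. The branch ordering is a documented design choice: the
underlying manual decision procedure lists the criteria but not their
priority. Genotypes are the per-individual union of allele-labelled
variants over both replicates; genotype reproducibility is
2·|A∩B| / (|A|+|B|) over the two replicate allele sets (NaN when both are
empty). Negative controls are screened by total reads against a
threshold; pedigree triads are checked with multi-locus presence/absence
logic (every offspring allele must occur in at least one parent — a
necessary, not sufficient, condition).

## Allele classification and nomenclature

Alleles are translated in a configurable frame with the standard code;
any stop codon flags a pseudogene (`-Ps` suffix). Coding alleles are
anchored on a reference protein by global pairwise alignment (BLOSUM62,
gap open −11 / extend −1) and checked at conserved diagnostic columns,
numbered 1-based on the reference with reference gaps unnumbered. A
mismatch at any `classical-required` column makes the allele putatively
nonclassical; pseudogene status takes precedence (a stop codon makes
conserved-residue status moot). When the always-conserved site is the one
that mismatches, the allele is still called nonclassical (a documented
extension). Names are assigned by decreasing carrier frequency (fraction
of genotyped individuals carrying the allele) with lexicographic sequence
order breaking ties, giving a deterministic `<Prefix> <tag>*<NN>[-Ps]`.

## Polymorphism statistics

For an equal-length alignment, columns containing non-ACGT symbols are
excluded entirely (complete deletion) and the effective length L
adjusted. S counts columns with ≥ 2 observed bases; η sums (distinct
bases − 1) per column, so η ≥ S with equality iff every polymorphic
column is biallelic; k is the mean pairwise Hamming difference; π = k/L;
pairwise identity is the mean pairwise fraction of identical columns
× 100. The amino acid p-distance is the mean pairwise proportion of
differing residues; its standard error resamples residue columns with
replacement (default 1000 replicates, sample SD across replicates,
seeded). Allele accumulation curves average the cumulative unique-allele
count over random orderings of individuals.

## Selection inference

Nei–Gojobori counting with Jukes–Cantor correction. Potential synonymous
sites per codon: at each position the three single-nucleotide changes are
classified; changes creating stop codons are excluded from the
denominator, and N = 3 − S per codon, so S + N = 3 × codons always holds.
Observed differences between codons differing at d positions average the
synonymous/nonsynonymous step counts over all d! mutational pathways,
excluding pathways that pass through a stop codon (if every pathway does,
all are retained equally). Proportions pS = Sd/S and pN = Nd/N are
corrected by d = −(3/4)·ln(1 − 4p/3); p ≥ 0.75 is a saturation error and
saturated pairs are excluded with a warning. The statistic is the mean of
(dN − dS) over unordered pairs; its SE is the sample SD over
codon-resampled bootstrap replicates (codons resampled within the
analysis mask); Z = mean/SE, with a one-tailed normal p-value for the
test of positive selection (H0: dN ≤ dS). Site masks are 0-based amino
acid positions mapped to codons; positively selected sites and
peptide-binding-region lists are inputs, not inferred here.

## Supertype clustering

Functional (non-pseudogene) alleles are embedded by the five
physicochemical z-descriptors of the residues at selected sites (five
dimensions per site); Euclidean distance on these rows is the
physicochemical distance between alleles. The cluster number is chosen by
repeated k-means (each repetition with 5 random initialisations per k)
scored by BIC(k) = n·ln(WSS/n) + k·ln(n). The selected k per repetition
is the smallest k whose next BIC improvement step falls below 10%
(configurable) of the largest single-step improvement — a BIC elbow rule.
An earlier candidate rule (smallest k reaching 90% of the total
improvement to the global BIC minimum) was rejected because k-means BIC
drifts monotonically past the elbow on small samples, so the global
minimum — and with it the 90% point — sits at k_max even for cleanly
separated two-cluster data. The consensus k is the mode over repetitions
(ties toward smaller k); mean and median are reported alongside.

Assignment repeats DAPC: k-means grouping, PCA retaining the fewest
components explaining ≥ 90% variance (capped at n/3), linear discriminant
analysis with posterior memberships. Labels are aligned across runs by
Hungarian matching on confusion matrices against the first run;
repeatability is Light's Kappa (mean pairwise Cohen's kappa over runs)
and the mean assignment proportion averages the per-allele maximum
posterior. k = 1 is trivially repeatable (kappa 1).

## Linkage structure

Phi is the Pearson correlation of binary presence/absence columns, with
p-values from n·Phi² ~ χ²(1); constant columns are undefined and flagged.
Blocks come from Ward clustering on 1 − Phi. R's `ward.D` applies the
Lance–Williams update to the raw dissimilarities, while scipy's `ward`
updates squared inputs; feeding √(1 − Phi) to scipy therefore reproduces
the `ward.D` merge order on 1 − Phi (reported heights are square roots).
The tree cut maximises mean within-block Phi over blocks of size ≥ 2 —
an automated stand-in for what is usually done by visual inspection of a
correlation heat map, so marginal clusters may split or merge relative to
a manual reading. Blocks with mean Phi ≥ `min_mean_phi` (default 0.5) are
reported with their co-occurrence percentage. Locus bounds: the largest
positively correlated block size, or ceil(max per-individual allele
count / 2) as a fallback (a diploid carries ≤ 2 alleles per locus).
Significance display uses p < 0.05 without multiple-testing correction
by default, matching the conventional display rule for such plots.

## Comparative phylogenetic mixed model

The consensus tree is a rooted majority-rule consensus (clades in ≥ 50%
of input trees are retained) with each retained edge given the mean
length of that clade over the trees containing it. The species covariance
scales the tree to unit height and sets cov[i, j] to the root-to-MRCA
depth, diagonal fixed at 1; species absent from the tree are mapped to a
proxy tip, copying its row with covariance to the proxy set just below 1
(10⁻³ offset) so the matrix stays invertible.

The model is Gaussian on log10 allele count with fixed effects
intercept, conservation status (LC=1 … CR=5 entered linearly — the
reported trend in such data is linear, and the linear coding is
declared), log10 sample size, number of exons (1 or 2) and MHC class
(II vs I), plus iid species intercepts u ~ N(0, σ²ₛI) and phylogenetic
intercepts v ~ N(0, σ²ₚC). All full conditionals are conjugate, so the
sampler is pure Gibbs: multivariate-normal draws for β (vague N(0, 10⁶)
prior), u and v, and inverse-gamma draws (IG(0.001, 0.001)) for σ²ᵣ, σ²ₛ
and σ²ₚ. Defaults are 2 chains × 6000 iterations with 1000 warmup.
Phylogenetic signal is λ = σ²ₚ/(σ²ₚ + σ²ₛ + σ²ᵣ) per draw — a variance
ratio; other λ definitions exist, so λ comparisons across software are
tolerance-based. σ²ₛ and σ²ₚ are only weakly separated when C is close to
identity; λ posteriors are then prior-sensitive near 0, which is why the
null-phylogeny check asserts a small posterior mean rather than an exact
zero. With all three variances pinned (`fix_variances`), the posterior
mean of β converges to the closed-form GLS estimate — used as an
equivalence test. Predictions per status level fix other covariates at
reference values (mean log10 n, mean exons, class I) and flag
observations outside the 5–95% posterior predictive range.

## Synthetic data generator

The generator defines the conditions everything is tested under:

- **Allele pools**: codon sequences built on a shared scaffold with ~35%
  variable codon positions (real alleles are 84–95% pairwise identical),
  a conserved tyrosine at a designated diagnostic column; pseudogene
  fraction gets an in-frame stop, nonclassical fraction a non-conserved
  residue at the diagnostic column.
- **Amplicon runs**: every individual in duplicate, one near-empty
  negative control per 94-well plate; per-allele read counts negative
  binomial around `depth_mean` (default 600, dispersion 5 — matching
  observed per-sample depths of order 10²–10³); artefacts arise per
  parent allele with probability `artefact_fraction`, at 1–2 nt from the
  parent, at a uniform fraction (5–45%) of the parent's reads, always
  logged as ground truth.
- **Genotypes**: two haplotypes per individual drawn from a small set of
  allele-set haplotypes with Dirichlet frequencies; an inbreeding
  parameter F gives identical-by-descent pairs. Unions of haplotype
  allele sets produce the block LD structure the linkage stage must
  recover.
- **Codon alignments**: Jukes–Cantor nucleotide proposals along the tree
  thinned per site by ω: nonsynonymous proposals accepted with
  min(1, ω) and, for ω > 1, synonymous proposals thinned by 1/ω so that
  ω > 1 genuinely elevates dN/dS; stop codons always rejected. Adequacy
  is judged purely by recovery: ω = 1 gives mean dN−dS within 2 SE of 0,
  ω ≪ 1 negative, masked ω > 1 sites give the mask higher Z.
- **Comparative tables**: conservation status is a species-level trait;
  sample size, class and exon count vary per observation; the response
  adds species, phylogenetic (Brownian, covariance ∝ shared branch
  length) and residual Gaussian effects, then rounds 10^y to an integer
  count (≥ 1). The default intercept (≈ 1.8) keeps counts large enough
  that integer rounding does not bias the slope.

Not emulated: read-level FASTQ with quality scores, chimeras spanning
more than 2 nt, allele-specific amplification bias, copy-number
variation, genotyping error correlated across replicates, and non-Brownian
trait evolution. Passing tests therefore certify the statistical
machinery under these idealised error models, not robustness to every
artefact class of a real sequencing run.

## Problem sizes

Default test and acceptance runs use 16–24 alleles, 60–200 individuals,
8–12 tip trees with 150–300 nt alignments, 30–50 clustering repetitions,
and mixed-model recovery at 77 observations of 39 species with 20
replicate fits of 2 chains × 1500 iterations — sizes chosen so the whole
suite re-runs in well under a minute per stage while leaving every
statistic's sampling error far smaller than the effects being measured.
The library defaults (500 clustering repetitions, 1000 bootstrap
replicates, 6000 MCMC iterations) match standard practice for real
analyses.
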