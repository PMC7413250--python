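# Methods

## The analysis in brief

`divpanel` treats a diversity panel as two parallel views of the same set
of accessions — a mixed-type trait table and a biallelic SNP dosage matrix
— and asks three questions: which dissimilarity measure and agglomeration
rule best represent each view as a dendrogram (judged by cophenetic
correlation), how the accessions group under the winning representations,
and how congruent the views are (Mantel tests, membership concordance,
per-group diversity and differentiation statistics).

## Distance definitions and conventions

**Gower.** d_G(i,j) = Σ_c w_ijc d_ijc / Σ_c w_ijc.  Quantitative and
ordinal traits contribute |x_ic − x_jc| / range_c (ordinal values are level
ranks); nominal traits contribute 0/1 mismatch.  w_ijc = 0 when either
value is missing or the trait's observed range is zero.  A pair sharing no
usable trait has no defined distance and is a hard error naming the pair,
rather than a silent 0.

**Euclidean / Manhattan.** Computed on quantitative + ordinal traits only;
a nominal trait is an error directing the caller to Gower.  Traits are
standardized (zero mean, unit variance) by default because field traits
have heterogeneous units (days, kg, scores); raw-scale computation is a
flag.

**Mahalanobis.** Uses the sample covariance of the trait table; requires
more accessions than traits.  Singular or near-singular covariance
(condition number > 1e12) is an error by default; a flag switches to the
Moore–Penrose pseudo-inverse with a logged warning.

**IBS.** Per-locus shared-allele count s = 2 − |g_i − g_j| on dosages
(identical genotypes share 2 — including heterozygote pairs — opposite
homozygotes 0, heterozygote vs homozygote 1); similarity is the mean of
s/2 and the dissimilarity is its complement, so it lives in [0, 1].

**Nei (between individuals).** Each individual is read as a two-allele
population with ALT frequency g/2; D = −ln(J_xy / √(J_x J_y)) with J the
per-locus mean allele-frequency products.  Pairs with J_xy = 0 get +inf,
flagged on the matrix and excluded from clustering and fusion.  This is a
distance between individuals, not the per-locus gene-diversity summary
that sometimes travels under the same name; with tens of retained loci or
more, infinities never occur in practice.

**Jaccard.** d = 1 − ΣPQ / (ΣP² + ΣQ² − ΣPQ) directly on dosage vectors.
Two all-zero profiles (denominator 0) are defined as distance 0 with a
warning — identical null profiles.

**Modified Rogers.** (1/m) Σ_l √(½ Σ_alleles (p − q)²).  For biallelic
dosages the per-locus term collapses to |g_i − g_j| / 2, which makes the
measure numerically identical to the IBS dissimilarity on this data type;
both are kept because they are distinct formulas with distinct behaviour
on multi-allelic data, and the coincidence is regression-tested rather
than assumed.

**Combined matrix.** Fusing the phenotypic and genotypic views requires a
scale decision the underlying formulas do not make: Gower lies in [0, 1]
while a genotypic matrix's range depends on the panel.  Each input is
therefore rescaled by its own maximum off-diagonal entry before the
element-wise weighted mean w·pheno + (1−w)·geno (default w = 0.5).  Both
the weight and the implicit rescaling are exposed; w = 0 reproduces the
genotypic analysis exactly.

## Clustering and model selection

The six linkages (single, complete, average/UPGMA, McQuitty/WPGMA,
median/WPGMC, ward.D2) are Lance–Williams agglomerations computed by
`scipy.cluster.hierarchy` on the precomputed dissimilarities; `ward` and
`median` operate on squared distances and report square-rooted heights,
matching the ward.D2 convention.  Tie-breaking among equal intercluster
distances follows scipy's deterministic order; on continuous data, exact
ties have measure zero and the cophenetic correlation is unaffected.

Median linkage can produce height inversions.  Heights are reported as
computed — no monotonicity repair — and cophenetic distances use the raw
merge heights.

Trees are cut to exactly k clusters by undoing the last k−1 merges (merge
order, not height, resolves ties), so cuts are nested: the k-partition
always refines the (k−1)-partition.  k defaults to 3 in the pipeline
configuration; no automatic k selection is attempted.

Cophenetic correlation is the Pearson correlation of strict upper
triangles; a zero-variance triangle (all distances equal) is an explicit
error, which the grid machinery records as a failed cell rather than
propagating.  The selection rule is argmax over the grid, per view.

Membership concordance aligns cluster labels across partitions by
maximum-overlap assignment (Hungarian algorithm on the contingency table)
before counting agreements, so relabelled but identical partitions count
as fully concordant; adjusted Rand indices are reported alongside as the
alignment-free check.

## Diversity and differentiation

Shannon H′ (nats), inverse Simpson H_B, Simpson λ = 1 − 1/H_B and Pielou
J = H′/ln S are defined on any nonnegative abundance vector; the pipeline
applies them to cluster-size profiles, and the identity between λ and H_B
holds to machine precision by construction.  J is undefined (NaN) for a
single category.  What "abundance" should mean at panel level is genuinely
underdetermined for this kind of study; defining the operation generically
and documenting the convention used was the cleanest resolution.

Weir–Cockerham Fst uses the per-locus a / b / c variance components from
genotype counts and the ratio-of-sums multi-locus combination, which is
the standard nearly-unbiased choice.  Per locus, only populations with at
least two genotyped individuals enter; loci with fewer than two such
populations or zero total variance are skipped.  The estimator is
invariant to group relabelling and locus order (tested).

The Mantel test permutes rows and columns of the second matrix
simultaneously, uses the add-one rule p = (1 + #{r* ≥ r}) / (B + 1) so p
is never zero and never below 1/(B+1), and takes a mandatory seed.  The
default tail is upper (positive association); two-sided uses |r|.  The
default B = 9999.

## Genotype QC

MAF filtering is a strict inequality (maf > threshold, default 0.1) and
the missingness rule keeps loci with missing fraction ≤ max_missing
(default 0, i.e. complete data only).  Hardy–Weinberg goodness of fit is a
continuity-corrected 1-df chi-square of the three genotype counts against
p², 2pq, q²; monomorphic loci get p = 1 by convention.  PIC uses the
biallelic form 1 − p² − q² − 2p²q², which is bounded above by expected
heterozygosity.

LD pruning is the familiar indep-pairwise scheme with window and step
measured in SNP counts (default 50 / 5 / r² 0.5).  Within a window,
offending pairs are scanned in locus order and resolved by removing the
lower-MAF member (tie: the later locus); sweeps repeat until a full pass
over each chromosome removes nothing, which guarantees that no window of
the pruned output still contains a pair above the threshold.  r² is the
squared Pearson correlation of dosages over pairwise-complete calls.
GQ/DP call-level filters are applied at VCF read time when those FORMAT
fields exist, and skipped with a log line otherwise.

## Adjusted means and trait selection

The trial model is all-fixed-effects least squares with sum-to-zero
coding: value = μ + year + block(year) + genotype, plus genotype×year when
the design both replicates within genotype-year cells and observes every
genotype in at least two years (otherwise the adjusted mean would not be
estimable).  The adjusted mean μ̂ + ĝ equals the arithmetic per-genotype
mean for balanced complete designs and the constrained normal-equations
solution otherwise; rank-deficient designs fall back to the minimum-norm
solution.  A mixed-model (REML) treatment of years/blocks as random was
deliberately left out: at panel scale with two or three environments the
fixed-effects fit is the transparent choice.

PCA is on the trait correlation matrix (so eigenvalues sum to the number
of traits); loadings are eigenvectors scaled by √eigenvalue, i.e. trait-
component correlations, with each component's dominant loading forced
positive.  Ordinal traits enter as level ranks; nominal traits are
excluded from PCA but kept for Gower, which handles them natively.  Trait
selection retains components with eigenvalue ≥ 1 (Kaiser rule) and traits
whose best |loading| reaches 0.45; both thresholds are configuration
knobs because no universal rule exists for "contributes most", and the
defaults are documented as choices.

## The synthetic panel

**What it emulates.** A ~173-accession panel in 3 latent groups,
differentiated at a target Fst via the Balding–Nichols model: ancestral
ALT frequency p ~ U(maf_range), group frequency ~ Beta(p(1−F)/F,
(1−p)(1−F)/F) (exactly p when F = 0), dosages Binomial(2, p_group) —
Hardy–Weinberg within groups.  Default 10⁴ SNPs spread over 20
chromosomes with sorted positions; ancestral MAF in (0.05, 0.5).
Phenotypes follow the trial decomposition grand mean + group shift + year
+ block(year) + genotype + G×Y + residual with effect SDs (1, 0.5, 0.3,
0.5, 0.5 respectively) in units of the genotype SD; `trait_separation`
scales per-trait, per-group mean shifts drawn N(0, 1) and centred, so 0
means phenotypically indistinguishable groups and 3 means strong
separation (the default, mirroring a panel with clearly resolvable
clusters).  Default traits: 20 quantitative, 7 ordinal (latent Gaussians
thresholded into 3–9 levels, like field score scales), 3 nominal
(group-tilted category probabilities).  Two years × three blocks;
missingness is MCAR and defaults to zero (it exists to exercise the QC
filters).  All draws descend from one seed through named child streams,
so a config is bit-reproducible.

**What it does not emulate.** Linkage disequilibrium structure (loci are
independent given group frequencies — the LD pruner is validated on
constructed correlated fixtures instead), clonal duplicates, selection or
pedigree structure among breeding lines, genotyping error, trait
ontologies, and non-MCAR missingness.  Passing recovery tests on these
panels therefore demonstrates correctness of the machinery under the
stated model, not robustness to real-world artefacts like LD-induced
pseudo-replication or shared pedigree.

## Problem sizes in tests and the acceptance script

Module tests run on toy fixtures (≤ 15 accessions) against brute-force
oracles at 1e-10–1e-12.  Calibration and recovery checks use: 500 null
replicates × 999 permutations for Mantel type-I error (judged against the
exact binomial 99% band around 0.05); 50 replicates per F ∈ {0, 0.05,
0.15, 0.3} of 3×50-accession, 2000-SNP panels for Fst recovery (mean
within ±0.02 of F, monotone); and 100 panels at default size with 1000
SNPs for end-to-end recovery (ARI > 0.9 in ≥ 95% of panels for each of the
phenotypic, genotypic and combined routes).  1000–2000 SNPs is ample for
these purposes — pairwise IBS distances and multi-locus Fst stabilise well
below 10⁴ loci — and keeps the whole suite within a few minutes on one
CPU.

## Known limitations

* Nei distances of +inf (possible only at very small locus counts) make a
  matrix unusable for clustering and fusion; the matrix is flagged and the
  grid records the failure instead of guessing a finite surrogate.
* The LD pruner's fixed-point sweep is quadratic per window and meant for
  panel-scale data (10⁴–10⁵ SNPs), not biobank scale.
* `ls_means` fits each trait independently and assumes fixed effects
  throughout; strongly unbalanced multi-year designs with random-effect
  structure deserve a dedicated mixed-model tool.
* The Mantel permutation loop rebuilds the permuted matrix per draw;
  at panel sizes (n ≈ 200, B = 9999) this is seconds, not minutes.
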