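# Methods

## Scope and data model

All analyses operate on three objects: a `GenotypeMatrix` (accessions ×
biallelic variants, haploid-coded 0/1 with missing, because selfed
accessions carry no heterozygous sites), a phenotype table of replicated
trait values from a randomized complete block design, and gene
annotation/expression tables.  Genotypes are never imputed at the data
layer; each analysis decides its own handling of missingness (the scan
mean-imputes per variant, the candidate regression treats missing as a
third genotype state, LD and kinship use pairwise-complete observations).

Variant-level inclusion follows the standard sequence-GWAS filters:
minor allele frequency ≥ 0.02 (computed over called genotypes only;
boundary inclusive) and a minimum call count (default 100 accessions).
Filtering is idempotent and order-preserving.

## Phenotype reduction

Association runs on least-squares accession means: the additive fixed-
effects model `value = accession + block` is solved by least squares with
a sum-to-zero constraint on block effects, so each accession coefficient
is its block-adjusted mean; unbalanced data go through the same normal
equations.  No accession×block interaction is fitted — with one replicate
per accession per block it is inestimable.  Flowering-type traits are
encoded as ordinal scores 1..9 over observed scoring dates plus a 10th
category for plants that never flowered, and analysed untransformed.

Among-accession variance fractions use a one-way random-effects
method-of-moments decomposition applied after removing the estimated
block effects: `σ²_within = MS_within`,
`σ²_among = max(0, (MS_among − MS_within)/n₀)` with `n₀` the unbalanced-
design replicate coefficient.  Method of moments (rather than REML) keeps
the estimator deterministic and directly checkable against hand-computed
sums of squares; the proportion is truncated at zero and invariant to
affine trait transforms.

## Kinship and the mixed-model scan

Kinship is the allele-sharing (identity-in-state) proportion over
pairwise-complete genotypes, computed on up to 5,000 randomly sampled
SNPs per chromosome (seeded).  The estimator is bounded in [0,1] with
unit diagonal and is deliberately simple and swappable; pairwise-complete
denominators can leave the matrix very slightly indefinite, so downstream
fits clip small negative eigenvalues and reject matrices whose smallest
eigenvalue falls below −0.05 of the largest (a structural, not numerical,
failure).

The scan is the "population parameters previously determined" expedient:
variance components of the null model are fitted once by REML — profile
restricted likelihood in δ = σ²_e/σ²_g after projecting out the intercept
and rotating into the eigenbasis of the projected kinship; Brent search
on log δ ∈ [−10, 10], convergence 1e−8 — and reused for every variant's
GLS test in the whitened coordinate system.  Missing genotypes are
mean-imputed to the variant's allele frequency for the scan only (this
preserves one global rotation); `n_used` records the true call count.
The test statistic is t = β/se on n−2 df (equivalent to the 1-df F).
Monomorphic-after-imputation variants are flagged undefined and excluded
from candidate selection.  Q-Q diagnostics report observed vs uniform
−log10 p quantiles and the genomic-inflation factor λ_gc (median observed
χ²(1) over its reference median).

Ties in p are broken by (chromosome, position), making candidate lists
deterministic.  No structure covariates beyond kinship enter the model; a
descriptive kinship-PC variance utility is provided.

## Candidate architecture statistics

LD between candidates is the squared Pearson correlation of call vectors
over pairwise-complete accessions (pairs with <10 complete observations
flagged undefined).  The summary statistic is, per threshold t ∈ {0.8,
0.3}, the fraction of candidates whose maximum off-diagonal r² is < t.
MAF bins are fixed at [0.02, 0.05), [0.05, 0.10), [0.10, 0.5].  Effect
size is |β| — for a 0/1 genotype the predicted phenotypic difference
between the two variants — and the MAF–effect relation is a Pearson
correlation with its t-transform p-value (a signed-β variant is also
available).  Gene tagging assigns a SNP inside a gene interval to that
gene and an intergenic SNP to the nearest gene on the same chromosome
(boundary-gap distance, equidistant ties to the smaller start coordinate
and flagged); the annotation model has no exon structure, so "coding
region" is approximated by the gene interval.  Named-gene reports list
all genes within a 10-kb window of a candidate.  Tissue-specificity
enrichment is the exact hypergeometric upper tail for the number of
tagged genes expressed in nodule and/or root and nowhere else.

## Variance explained and the winner's curse

The top-50 candidates enter a multiple regression on accession means with
each candidate encoded as a 3-level factor {ref, alt, missing} (two
indicator columns; zero-variance and collinear columns dropped and
logged).  Backwards stepwise selection removes whole candidates — both
columns together — choosing at each step the removal that lowers the
Gaussian AIC (n·log(RSS/n) + 2·(p+1)) most, until no removal improves it.
If the initial model is not estimable the lowest-ranked candidates are
pre-pruned first.

Because candidates are selected and evaluated on the same data, the raw
r² is inflated (Beavis effect / winner's curse).  The correction re-runs
the entire pipeline — scan, candidate selection, stepwise regression — on
R = 20 (configurable) datasets in which phenotype values are randomly
reassigned to accessions after block adjustment, recording per replicate
the r², top-200 MAF-bin counts, and MAF–effect correlations (top 50 and
top 200).  The adjusted proportion of variance explained assumes the
truly explainable variance is uniformly distributed between the null mean
and one: `adjusted = (r² − r̄²_null)/(1 − r̄²_null)`; it may be negative.
These randomizations are approximate nulls: the kinship term makes the
data not fully exchangeable, so when a strong polygenic signal aligned
with kinship is present the permutation null underestimates the
selection bias.

## In silico platforms

A platform emulates a fixed-content array: panel MAF is computed on the
discovery-panel accessions only; one SNP with panel MAF strictly > 0.10
is drawn uniformly from each 1-kb window (index `floor((pos−1)/1000)` per
chromosome) containing at least one eligible SNP; fillers are drawn
uniformly without replacement from the remaining panel-eligible SNPs up
to the target size (the all-SNP filler variant is a switch; platforms
truncate with a warning when eligible SNPs run out).  The platform scan
applies the identical full-sample filters and model to the platform
subset; when the full scan is supplied its rows are extracted directly,
so shared SNPs carry bit-identical p-values.  Overlap reports count, per
replicate and per (top-n, distance) cell with inclusive boundaries, the
top-n platform candidates within the distance of the nearest top-200
sequence candidate on the same chromosome, aggregated min/mean/max over
replicates.  MAF-bias reports give the bin histograms of all assayed
SNPs, sequence candidates, platform candidates, and the sequence
candidates "tagged" (within 1 kb) by platform candidates.

## Synthetic data

The generator produces the statistical structure the analyses assume, not
sequence-level realism.  Per chromosome, variants are placed uniformly
and cut into LD blocks of `block_length_bp` (default 3 kb, the scale over
which LD decays in the motivating system).  Each block carries
`n_founder_haplotypes_per_block` (default 32) founder haplotypes; each
accession inherits one founder per block, drawn from its subpopulation's
Dirichlet founder weights (concentration 0.3 — values below 1
differentiate subpopulations and create kinship structure).  Accessions
sharing a founder are identical across the block, giving strong within-
block LD; missingness is independent Bernoulli per call.

Derived-allele frequencies follow Beta(shape, 7); founders acquire the
derived allele by weighted-prefix assignment in a random per-variant
order, so the expected population frequency equals the Beta draw up to
founder-weight granularity and sites below the resolution become
monomorphic (retained, and removed later by the MAF filter, mirroring the
real pipeline order).  The default shape 0.2 was calibrated once so the
post-filter genome-wide mean MAF is ≈ 0.09, the one constraint the
motivating dataset fixes; the spectrum is otherwise unconstrained.

Phenotypes are replicate-level
`y_ij = Σ β_v x_iv + g_i + b_j + e_ij` with causal effect magnitudes
∝ [p(1−p)]^(−α) (α = `maf_effect_alpha` couples rarity to effect size; α>0
yields the negative MAF–effect correlations seen for selection-shaped
traits), a polygenic term drawn with covariance proportional to the
realized genomic relationship matrix, shared greenhouse-block effects,
and i.i.d. residuals.  Heritabilities are defined on the accession-mean
scale: causal and polygenic components are rescaled so their realized
among-accession variances equal `h2_causal` and `h2_polygenic`, and the
block-mean of the residual has variance 1 − h2_causal − h2_polygenic
(replicate-level residual SD is √n_blocks larger).  This makes the
squared correlation between a single causal genotype and the accession
means equal h2_causal by construction — the scale on which the scan
operates.  Realized variance fractions and scaled effects are recorded in
`GroundTruth` for recovery tests.

What the generator does not emulate: sequencing reads and read-level SNP
calling, genotyping error, crossover-interrupted haplotypes within blocks
(LD is block-constant rather than decaying), selection, and linked
causal-variant clustering beyond what block LD induces.  Tests passing on
these simulations therefore validate the statistical machinery — model
fitting, selection, correction, and bias measurement — not the biology of
any particular dataset.

## Problem sizes and numerical choices

The test suite and examples run the full pipeline at desk scale — 80–200
accessions and 10³–10⁴ variants, 100-platform replicates at a few
thousand SNPs — sizes chosen so every experiment (20-seed calibrations,
randomization nulls, platform sweeps) completes in minutes while leaving
all estimators in their asymptotic regime.  Tolerances: REML convergence
1e−8 on log δ; scan-vs-explicit-GLS agreement asserted at 1e−6;
eigenvalue clipping floors at 1e−10 of the largest eigenvalue; stepwise
AIC improvements below 1e−10 are treated as ties (no removal).  All
randomness flows from explicit integer seeds; pipeline stages derive
per-stage seeds by hashing the stage name, so each stage is independently
reproducible.

## Known limitations

- λ_gc slightly above 1 can persist after kinship correction when the
  trait is strongly polygenic — expected, since polygenicity inflates the
  median test statistic even without confounding.
- The permutation null undercorrects the winner's curse for traits whose
  heritable signal is strongly aligned with kinship (see above); the
  calibration experiments therefore use exchangeable nulls.
- The IBS kinship has no MAF weighting; a GRM-style estimator would fit
  behind the same interface.
- Gene tagging ignores strandedness and exon structure.
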