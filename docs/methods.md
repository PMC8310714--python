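# Methods

This note documents the models, estimators and design choices behind
`sbgevo`, and what the synthetic-data generator does and does not emulate.

## Differential expression engine

Counts are filtered (genes with a total below 1 across all samples are
removed) and TMM-normalized. TMM follows the standard trimmed-mean-of-
M-values recipe: the reference sample is the one whose 75th percentile of
count fractions is closest to the mean; per sample, M-values (log2 ratio of
count fractions vs the reference) are double-trimmed (30% on M, 5% on A,
both tails) and combined with inverse asymptotic-variance weights; factors
are rescaled to geometric mean 1. Normalized counts are
count / (library size × factor), rescaled by the geometric-mean library
size so values stay on a count-like scale (the rescaling is a global
constant and cancels from every downstream contrast).

Sex bias per species×organ is a Wald test on
LFC = log2((mean_M + c)/(mean_F + c)) with pseudo-count c = 0.5 on the
normalized scale (configurable). The standard error comes from the delta
method under a negative-binomial model: per gene, a method-of-moments
dispersion pooled over the two sexes (floored at 1e-8, capped at 100) is
shrunk toward a binned-median mean–dispersion trend with a prior weight of
4 pseudo-replicates — small-sample stabilization in the spirit of standard
RNA-seq engines, but fully specified here. p-values are two-sided normal,
BH-adjusted within one species×organ family. The engine's operating
characteristics are measured, not assumed: on a 5 000-gene null simulation
the fraction of adjusted discoveries is far below 0.05, and planted
|LFC| ≥ 2.6 genes at 50 replicates per sex are recovered with sensitivity
> 0.95 at FDR < 0.05 (see `tests/test_acceptance.py` and
`scripts/acceptance.py` for the measured values). With the typical 3
replicates the raw Wald p is anticonservative in the tails, which is why
calling is done on adjusted p-values combined with the |LFC| > 2 effect-size
threshold.

"VST" for QC is log2(normalized + 1): QC only needs a variance-damping
monotone transform. Sample flags (low signal; sex mismatch by k = 3
nearest-neighbour majority within species×organ; organ mismatch by nearest
organ centroid) are advisory — exclusion is a user decision.

LFC sign convention: positive = male-biased. Category bins (none / low /
mid / high / extreme at 2, 2.6, 4.1, 6.5) are applied to |LFC|.

## Intersex population genetics

Males and females of one species are treated as two populations. Per site,
Hudson's moment components are

    α = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)
    β = p₁(1−p₂) + p₂(1−p₁)

with sample allele frequencies p and allele-copy counts n per sex. The
per-gene estimate is the ratio of sums Σα/Σ(α+β) over Fst-eligible sites,
which shrinks noisy per-site ratios toward the regional value; negative
values are retained (moment estimators go negative when differentiation is
below the within-group sampling noise). Genes without eligible variant
sites report a missing Fst. π per gene divides the summed per-site
diversity 2d(n−d)/(n(n−1)) by all covered sites, variant or not, so genes
with patchy coverage are comparable. Tajima's D uses the 1989 constants at
the gene-wise minimum sample size (sites with deviating n would in
principle need hypergeometric down-sampling of d, but the per-site π is
already unbiased under down-sampling, so only the constants use the
minimum n; D is undefined below n = 4 or S = 1). Inputs are hard genotype
calls with per-sample depth: genotype-likelihood machinery belongs to the
upstream variant-calling workflow, and with hard genotypes the
empirical-Bayes per-site estimators reduce to direct counting.

Site filters: ≥3 covered individuals, total depth ≥3, per-site quality ≥13
when present; Fst additionally requires ≥2 covered individuals of each sex.
A site belongs to at most one gene (first gene in sorted annotation order
on overlap). All covered individuals per sex are used (no balancing).

## Selection statistics

dN/dS is Nei–Gojobori (1986) counting: per codon, the 9 single-nucleotide
mutants are classified (mutations to stops excluded from site counts —
the classical convention), site counts averaged over the two sequences;
observed differences at multi-hit codons are averaged over all shortest
substitution paths, dropping paths through stop codons when a stop-free
path exists; Jukes–Cantor correction d = −(3/4)ln(1 − 4p/3) is applied to
both proportions, undefined at saturation (p ≥ 3/4). ω = dN/dS, set to 0
when dN = 0 with observed synonymous differences, undefined when dS is 0
or saturated. NG86 is a counting estimator: absolute values can differ
from codon-ML estimates, but the contrasts used here (ω above/below 1,
class comparisons) are preserved, and on simulated neutral pairs the
estimate is within a few percent of 1.

Δx standardizes the expression shift of a focal species from the reference
(ancestral-proxy, most basal) species: difference of mean log2(TPM+1)
divided by the pooled within-species SD of both species' replicates
(focal-only SD available as an option). |Δx| > 1 in either direction flags
putative directional selection; the joint candidate set intersects this
with ω > 1. TPM uses annotation gene lengths.

## Expression phylogenies

Distances between species are 1 − ρ (Spearman, average ranks) between mean
TMM-normalized profiles per organ and gene class. Trees are neighbour
joining (the Q-criterion): ties in Q broken toward the lowest-index pair,
negative branch lengths clamped to zero with the deficit moved to the
sister branch — on additive matrices the generating topology and branch
lengths are recovered exactly (asserted against patristic-matrix oracles
and an independent NJ implementation). Bootstrap resamples genes with
replacement; a split's support is the fraction of replicate trees
containing it. Root-to-tip sums use outgroup rooting at the most basal
species-tree taxon when present, else midpoint rooting. RF distance counts
nontrivial bipartitions present in exactly one tree; the normalized
variant divides by the total nontrivial splits of both trees. Divergence
times are patristic distances on the time tree (twice the MRCA age when
ultrametric); the per-pair rate of expression change is (1 − ρ)/t.

## Ancestral reconstruction and turnover

Sex-bias status is a 3-state character (U, FBG, MBG) under the equal-rates
Mk model; the single rate q is fitted by maximizing the pruning likelihood
summed over genes with a uniform root prior. Because the likelihood is
flat in q far above the optimum, the optimizer brackets on a log-spaced
grid before bounded refinement (relative tolerance ~1e-12 on the bracket).
Missing species×organ entries (e.g. organs lacking replicates) enter as
uninformative tips, preserving tree shape. Joint ancestral states are the
max-product (Viterbi-style) assignment over internal nodes; ties break
toward U, then FBG, then MBG — fixed and documented since likelihood ties
are real at high rates. Both the likelihood and the joint argmax are
asserted equal to exhaustive enumeration on trees of ≤6 tips at 1e-10.

Turnovers: a branch whose parent/child states differ contributes gains and
losses per direction; a direct MBG→FBG flip counts one loss_MBG plus one
gain_FBG. Net gains−losses telescope along every root-to-tip path to the
tip-minus-root state tally (the all-branch sum does not telescope on a
bifurcating tree, since internal parents serve two children — the per-path
identity is the invariant asserted in the tests). PGLS regresses terminal-
branch turnover totals on each trait under a Brownian residual covariance
C (shared root-to-MRCA path lengths); σ² is profiled out and t-tests use
df = n − 2. On a star tree with equal depths the estimates reduce exactly
to OLS.

## Genomic distribution

The per-LG screen builds, per species, the 2×2 table of MBG/FBG counts on
the LG versus the rest of the genome and runs a one-sided Fisher's exact
test in the direction of the observed on-LG MBG−FBG difference
(feminization = FBG excess, equivalently MBG deficit); a zero difference
reports p = 1 by convention, as do zero-margin tables. Mann–Whitney
contrasts (sex chromosome vs pooled autosomes per gene class and
statistic) use exact p when min(n, m) ≤ 8 without ties, else the normal
approximation with tie and continuity corrections. BH adjustment is the
plain step-up procedure throughout (one routine package-wide).

## The synthetic-data generator

The generator defines the study conditions and is first-class, tested
code. Defaults mirror the emulated design: 14 species on a Yule tree of
height 10 Myr, five organs (gonad, brain, liver, gill, jaw), 3 replicates
per sex and organ, 800 genes on 6 linkage groups, 40 genotyped sites per
gene, 5 diploid individuals per sex, mean sequencing depth 8 with 10%
per-site dropout. The gene and site counts are desk-scale choices — large
enough for every statistical pattern to be measurable, small enough that
the full pipeline runs in about a minute on one CPU; the real study had
~44× more genes, which matters only for per-LG screens (below).

Model components and what they stand in for:

- **Expression.** Per organ, gene baselines are Normal(5, 2) on log2;
  species deviations are Brownian (default rate 0.02 per Myr; planted SBGs
  drift 3× faster, giving the elevated divergence of SBG-class trees).
  Counts are negative-binomial with gene-wise lognormal dispersion (median
  0.05) and lognormal library-size factors (CV 0.3, exercising TMM
  nontrivially). A fraction of genes per organ (gonad 0.4; somatic organs
  0.01) is bias-capable, with |LFC| drawn from a mixture over the four
  bias categories (0.35/0.35/0.2/0.1) and the full LFC added to the biased
  sex's mean.
- **Bias-state evolution.** Capable genes' states evolve on the tree under
  the same equal-rates process the analysis fits (default q = 0.02 per
  Myr), giving a parameter-recovery target and realistic cross-species
  sharing. XY-region genes are male-biased at the root with probability
  0.05 instead of 0.5, emulating demasculinization of the differentiated
  region. At 800 genes this shifts the per-LG Fisher screen's direction
  consistently (every species' sex-LG table leans feminized) without
  reaching BH significance — a power limit of the desk scale, not of the
  test, whose sensitivity is demonstrated with planted strong signals in
  the unit tests.
- **Genotypes.** Autosomal sites segregate with probability θ·a_n
  (θ = 0.02); derived sample counts follow the neutral 1/i spectrum, so
  Tajima's D is centred near zero; alleles are placed on chromosomes
  independently of sex, so autosomal intersex Fst is centred at zero. In
  the XY region (the first 40% of the sex LG), half the sites are fixed
  X/Y divergent: every male heterozygous, every female homozygous X.
  All species share the same XY system by default — the analysis is
  per-species, so differing systems are a matter of configuration, not of
  code path.
- **Coding sequences.** Derived sequences accumulate Poisson-many
  single-nucleotide proposals (0.06 per site); synonymous proposals are
  accepted with probability min(1, 1/ω) and nonsynonymous with min(1, ω),
  so the realized dN/dS targets ω. Per-gene ω is lognormal (median 0.2)
  with 20 genes set to ω = 1.8; the same genes carry a +3 log2 expression
  shift in one focal species, planting recoverable joint candidates.
- **Traits.** Brownian component on the tree plus independent
  Normal(0, 0.3) noise. The default traits are independent of the
  turnover process — the PGLS stage's recovery is measured on responses
  simulated from the trait (slope-coverage target), while the default
  pipeline output shows its behaviour under the null.

What the generator does **not** emulate: read-level artefacts (mapping
bias, multi-mapping, GC effects), genotype-likelihood uncertainty,
isoform structure, correlated gene modules, organ-specific mean–variance
relationships beyond the NB family, and unequal sex ratios. Passing tests
therefore validate the estimators and the pipeline's wiring under the
stated generative assumptions, not robustness to those real-data
complications.

## Numerical and convention choices

- Coordinates are GFF3-style 1-based inclusive everywhere; VCF positions
  1-based; strand is carried but ignored by all statistics.
- All randomness flows from one integer seed through
  `numpy.random.default_rng`; reruns are byte-identical, and every output
  table carries the configuration hash in a comment header. The run
  manifest records per-file SHA-256 checksums (and deliberately no
  timestamps, so identical runs produce identical manifests).
- Spearman ties get average ranks; Mann–Whitney exact/asymptotic cutover
  at min(n, m) = 8 without ties; Fisher zero-margin convention p = 1.
- NJ negative-branch handling: clamp to zero, deficit to the sister branch.
- Δx with zero pooled SD: 0 when the means agree, undefined otherwise.
- Degenerate inputs (constant profiles, monomorphic state matrices,
  constant traits, empty LGs) raise or report explicitly rather than
  silently propagating.

## Known limitations

- The Wald DE engine's raw p-values are approximate at 2–3 replicates;
  calls rely on BH adjustment plus the effect-size threshold (as in the
  emulated workflow), and borderline |LFC| ≈ 2 genes at low replication
  are under-called.
- NG86 underestimates ω when substitutional saturation sets in and cannot
  separate branch-specific effects; it is a pairwise counting method by
  design.
- The Mk model assumes one symmetric rate for all six transitions and
  gene-independent evolution; rate heterogeneity across genes is not
  modelled.
- Per-gene Fst needs at least one variant Fst-eligible site; at the
  default θ about 5% of gene×species pairs report missing Fst.
- PGLS assumes a Brownian residual covariance with no Pagel's-λ style
  flexibility; turnover counts are treated as continuous responses.
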