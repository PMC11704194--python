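# Methods

This note documents the statistical procedures implemented in
`protegrate`, the generative model of the synthetic cohort, the
defaults that matter, and the choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Genomics

**Gene-level copy number and arm scores.** Segment tables use SEG
semantics: 1-based inclusive coordinates and a log2 copy ratio per
segment. The copy number of a gene (or arm) in a sample is the
overlap-length-weighted mean of the log2 ratios of all segments
intersecting it. The arm summary is a weighted *mean* rather than a
raw weighted sum: normalizing by the total overlapped length keeps arm
scores on the log2-ratio scale, so the same ±1 cutoff used for
segment-level amplification/deletion calls remains meaningful at arm
level. A raw-sum variant would scale with arm length and segment
coverage, making thresholds incomparable across arms. Overlaps are
computed half-open internally; all I/O remains 1-based inclusive.
Boundary values are called (≥ cutoff is amplified) so calls are
deterministic.

**TMB.** Mutations per megabase of captured coding sequence, counting
SNVs and indels, synonymous included. The coding size is a config
input (default 31.6 Mb, a typical whole-exome capture footprint).

**Trinucleotide contexts.** SNVs are tabulated into the conventional
96 classes: six pyrimidine-reference substitutions (C>A, C>G, C>T,
T>A, T>C, T>G) × 16 flanking-base combinations, ordered substitution →
5' base → 3' base. Purine-reference records are reverse-complemented;
the operation is invariant to the strand on which a variant is
reported (tested by full 192 → 96 enumeration). Contexts are carried
in the mutation table itself, so no reference FASTA is needed.

**Signature extraction.** Multiplicative-update NMF (Frobenius
objective) on the 96 × samples count matrix, best of 10 random
restarts, ≤ 2000 iterations, stopping at a relative objective change
below 1e-6. The update rules guarantee a monotone non-increasing
error trace, which is exposed and asserted. Extracted profiles are
column-normalized to probability vectors (exposures rescaled
accordingly) and each is assigned the reference signature of maximal
cosine similarity. The NMF is written in-package because the iteration
trace and restart policy are part of the contract; tests cross-check
the attained objective against scikit-learn's NMF.

**Co-occurrence.** Two-sided Fisher exact tests on 2×2 event tables;
features with degenerate margins (present in all or no samples) are
reported with p = 1 and flagged rather than tested.

## Label-free quantification

iBAQ divides a protein's summed peptide intensity by its count of
theoretically observable peptides. The digestion rule — fully tryptic,
cleavage C-terminal of K/R except before P, length 7–30, no missed
cleavages — is standard iBAQ practice; length bounds and missed
cleavages are parameters. FOT divides each protein's iBAQ by the
sample's total iBAQ and multiplies by 1e6, so each sample column sums
to 1e6 exactly before imputation (asserted at 1e-6 relative). Missing
values are then set to 1e-5 and recorded in a boolean mask; rank-based
statistics (QC Spearman, the cis/trans ledger, differential tests)
exclude masked cells by default, since a constant imputation value
would otherwise manufacture ties. The FOT denominator uses all
quantified proteins of the run. Phosphosites require localization
probability strictly greater than 0.75; reported residue percentages
are rounded half-up to one decimal.

## cis/trans correlation ledger

Gene-level CNV is correlated with mRNA, protein, and phosphoprotein
abundance by Spearman's rho (average ranks on ties, two-sided
t-approximation p, matching `scipy.stats.spearmanr`). *cis* means the
CNV feature and the target map to the same gene symbol; phosphosites
are collapsed to one row per gene by the site of highest mean measured
abundance. BH adjustment is applied within each (layer, mode) family
separately, mirroring per-layer reporting of significant cis effects.
Imputed cells are excluded pairwise and pairs with fewer than 10
complete observations are skipped. A peak/locus-based cis definition
(rather than same-gene) would be a straightforward extension but is
not implemented.

## Enrichment scoring

One ssGSEA engine serves pathway scores, TF activity, immune/stromal
scores and cell-type signatures. Per sample, features are ranked by
abundance (average ranks, statistic = ascending rank so the largest
value gets N); the enrichment score is the sum over the
descending-ordered walk of (weighted in-set ECDF − out-set ECDF), with
in-set weights |rank|^α, α = 0.25. Cohort normalization divides all
scores by the max−min range of raw scores. Defaults (α, the
normalization, min_size = 10) follow common ssGSEA practice and are
exposed. Single-target TF regulons fall back to the target's z-scored
abundance. MGPS is the mean of per-gene z-scores; zero-variance genes
contribute 0. Over-representation is a one-sided hypergeometric
upper-tail test with BH control. The Gaussian-kernel GSVA variant and
xCell's spillover compensation are deliberately not implemented.

Note a compositional caveat of rank-based scoring: strongly shifting
one program also displaces the ranks of all other genes, so "null"
sets show weak anti-correlated scores when the planted program is a
large fraction of the matrix. Tests account for this by using planted
programs that are small relative to the feature space.

## KSEA

Kinase activity per sample is
`z = (s̄ − p̄)·√m / δ`, with `s̄` the mean log2 abundance of the
kinase's m mapped substrate sites and `p̄`, `δ` the mean and SD over
all measured sites of that sample. Sites, not proteins, are the
aggregation unit; kinases with fewer than 3 measured sites (default)
are dropped. A two-sided normal p accompanies each z. A mean-only
variant (raw substrate mean z-scored per kinase across samples) is a
toggle. The z-score is invariant to per-sample rescaling of the
linear abundances. NetworKIN-style predicted relations are ingested
only above score 1; curated relations pass unfiltered.

## Consensus clustering

Per repetition, ⌈pItem·n⌉ samples are drawn without replacement and
clustered by PAM on 1 − Spearman correlation between sample profiles
over the top-50% most variable features (variance by default, MAD as
an option). PAM is a deterministic BUILD + SWAP implementation,
verified against exhaustive medoid search on small instances.
consensus(i,j) = co-cluster count / co-sample count; final labels come
from average-linkage hierarchical clustering of 1 − consensus cut at
k. Model selection reports the consensus-CDF area, its delta-area per
k, and the mean silhouette on the consensus distance; the chosen k
maximizes silhouette with delta-area as tie-break. Since Spearman
correlation between two fixed profiles does not depend on which other
samples were drawn, the full distance matrix is computed once and
subset per repetition when pFeature = 1. The default repetition count
in tests and the acceptance script is 200; production-scale runs
(thousands of repetitions) only sharpen the consensus matrix, they do
not change its expectation.

## Survival statistics

Kaplan–Meier curves and the k-sample log-rank test come from
`lifelines`; Cox proportional hazards uses the Efron tie
approximation, reporting coefficient (= ln HR), HR, 95% Wald CI and p.
Optimal dichotomizing cutpoints use maximally selected rank
statistics: per-subject log-rank scores `a_i = δ_i − Λ̂(t_i)`
(Nelson–Aalen cumulative hazard at the subject's time), with the
standardized statistic at cutpoint c being
`|S_c − m·ā| / sqrt(m(n−m)/(n(n−1))·Σ(a_i−ā)²)` for the m subjects at
or below c; admissible cutpoints leave at least minprop = 0.1 of the
cohort on each side; ties resolve toward the lower cutpoint. The
naive log-rank p at the selected cutpoint does not account for the
selection and is anti-conservative; a permutation p for the maximal
statistic (default 1000 permutations when enabled) restores the
nominal level and both are reported. Differential abundance uses
Wilcoxon rank-sum or Student t for two groups, Kruskal–Wallis or ANOVA
beyond, fold changes on the unlogged scale with imputed cells
excluded, and BH control; fold-change thresholds (2 for tumor/normal
contrasts, 1.5 for subgroup contrasts) are configuration, not code.

## Synthetic cohort generator

The generator emulates the files a proteogenomic study consumes, with
known ground truth. Genome: 4 chromosomes × (p, q) arms, genes in
contiguous equal blocks, 50 kb bodies. Per sample and arm, segments
are produced at deterministic breakpoints (split at focal-event
boundaries, then halved), each with N(0, 0.1) log2 baseline noise;
arm/focal carriers (Bernoulli per event fraction) receive the planted
mean shift. Expression layers are generated on the log2 scale —
baseline N(5, 1) per gene, plus slope × copy-ratio for cis genes, plus
the program shift for the sample's cluster, plus N(0, noise_sd)
residual — and exponentiated to positive FOT-like values for output.
Phosphosites comprise the kinase substrate sites (shifted by the
sample's true kinase activity, which is the per-cluster shift plus
N(0, 0.1)), one site per cis gene (dosage-coupled), and background
sites. The peptide table splits each protein's abundance ×
observable-count over 3–8 peptides by Dirichlet weights, so iBAQ
recovers the planted abundance exactly. Mutation counts are
Poisson(316) per sample with 5% indels; SNV contexts are multinomial
draws from the sample's signature mixture (per-sample Dirichlet around
the specified weights, concentration 8), and half the SNVs are emitted
on the purine strand to exercise strand collapsing. Two synthetic
reference signatures ship in code: a C>T-concentrated and a
C>A-concentrated profile with a uniform floor (these are constructed
stand-ins, not COSMIC profiles). Survival times are exponential with
hazard = baseline × per-cluster HR, censored by independent
Uniform(0, 120 months) administrative censoring — the simplest
mechanism satisfying the non-informative censoring assumed by log-rank
and Cox.

One global seed drives named substreams (clusters, segments,
expression, phospho, mutations, survival, peptides) via
`SeedSequence.spawn`, so adding a stream never perturbs the others and
a fixed seed reproduces the cohort bit-identically.

**Default study conditions** (`default_cohort_spec`): 200 samples,
2000 genes, one arm loss (4q, 50% carriers, −1.0), one focal gain (5
genes on 2p, 25% carriers, +1.5), 20 cis genes on 4q with slope 1.5,
three equal clusters with 40-gene programs shifted +1.0, three kinases
with 10 substrate sites each active (+1.0) in one cluster, signature
mixture (0.6, 0.4), residual noise SD 0.5 (so dosage slope/noise = 3),
baseline hazard 0.02/month with HR 2.5 in cluster C3. Effect sizes
are chosen for testability — large enough that recovery is expected at
cohort sizes of 60–100, small enough that noise matters; the magnitudes
in real cohorts are unknown. Program and substrate-set sizes shrink
proportionally on small gene universes.

**What the generator does not emulate:** tumor purity admixture,
batch effects, peptide-level missingness mechanisms
(missing-not-at-random censoring of low abundances), correlated gene
programs beyond the planted ones, and realistic LD/chromosomal
structure of mutations. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative
model, not performance on real tumors.

## Problem sizes in tests

The test suite and acceptance script use scaled cohorts — 60–100
samples, 100–200 genes, 200 consensus repetitions, 20 seeds for
recovery/calibration suites, 250 permutations for the cutpoint null —
sizes at which the planted effects are comfortably identifiable while
the full suite runs in about a minute. The statistical contracts do
not depend on these sizes.

## Known limitations

- The `all` (trans) correlation mode loops over the full CNV × target
  cross product; for genome-scale matrices this is slow and a blockwise
  rank-matrix implementation would be preferable.
- GISTIC-style peak calling, driver-gene significance, purity
  estimation and spectral search are out of scope; their outputs are
  this package's inputs.
- The optimal-cutpoint naive p is reported for compatibility but
  should not be interpreted without the permutation adjustment.
- Consensus clustering assumes profiles correlate within subtypes;
  subtypes defined only by variance structure are invisible to the
  Spearman distance.
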