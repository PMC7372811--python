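# Methods

This note documents the statistical procedures the package implements, the
assumptions behind them, the design choices that were genuinely open, and what
the synthetic cohort generator does and does not emulate.

## Conditioning of the abundance matrix

The pipeline starts from an integer species × sample count matrix. Species
with ≤ `min_reads` (default 5) total reads across all samples are removed as
likely sequencing noise. Counts are converted to relative abundances per
sample to absorb uneven library sizes; no rarefaction or compositional
log-ratio transform is applied. The prevalence filter keeps species present
(count > 0) in at least `prevalence_threshold` (default 20%, boundary
inclusive) of the analyzed samples; prevalence is evaluated on raw values
before any normalization, and per analyzed cohort (per habitat for the
per-habitat networks, over the pooled cohort for a pooled comparison). After
species filtering, a relative table keeps each species' share of the *full*
community — rows are not re-closed — so downstream fold ratios and effect
sizes stay interpretable as community shares.

For multivariate and supervised analyses each species column is mapped to van
der Waerden scores Φ⁻¹(r/(n+1)) (ranks with ties averaged, zeros included in
the ranking) and then centered and scaled to mean 0, variance 1. This
achieves a Gaussian-shaped marginal per species without empirical-quantile
boundary infinities, is monotone within each column (Spearman correlations are
preserved exactly in the absence of ties), and is tie-safe for the
zero-heavy columns typical of sparse microbiome data. Constant columns are
excluded and listed. Good's coverage, 1 − singletons/reads, is reported per
sample as a sampling-completeness diagnostic.

Compositional summaries (pie-chart-style tables) aggregate relative
abundances to a chosen rank and pool taxa whose cohort-mean share falls below
`other_cutoff` (default 0.5%) into an "Other" category; mass is conserved.

## Diversity, ordination, group tests

Alpha diversity (observed species; Shannon index, base 2, exposed as a
parameter) is computed on counts before any transformation. Beta diversity is
Bray-Curtis, which on relative-abundance rows equals half the L1 distance.
PCoA eigendecomposes the double-centered Gower matrix −½·J·D²·J; negative
eigenvalues (from non-Euclidean dissimilarities) are retained in the reported
spectrum but excluded from coordinates and from the variance denominator, and
no Lingoes/Cailliez correction is applied by default. Hierarchical clustering
is complete linkage on the same distances.

ANOSIM ranks all n(n−1)/2 distances and contrasts mean between- vs
within-group ranks, scaled by M/2 so R ∈ [−1, 1]; PERMANOVA computes the
pseudo-F from squared distances (SS_total = Σd²/n, within-group terms by
group). Both permute group labels (never the matrix) and report
p = (b+1)/(m+1) with m = 999 permutations by default — a convention that can
never return 0 and is floored at 1/(m+1). Significance is assessed at
p ≤ 0.05, boundary inclusive. On univariate Euclidean data the pseudo-F
reduces algebraically to the classical one-way ANOVA F, which the tests
exploit as an oracle.

The Mann-Whitney U test uses exact enumeration when the pooled sample has at
most 12 observations (via an exhaustive permutation path when ties are
present) and the tie- and continuity-corrected normal approximation otherwise;
the worst-case discrepancy of the approximation over all 5|5 partitions of 10
values is below 0.03. The Fisher–Freeman–Halton test enumerates every r×c
table with the observed margins recursively and sums the probabilities of
tables no more probable than the observed one (float-equality guard 1+10⁻⁷);
a partition-function identity (total probability 1 ± 10⁻⁹) is asserted on
every call. The enumeration budget is N ≤ 200 with at most 12 cells.

Multiple testing uses the two-stage Benjamini-Hochberg step-up at q = 10%:
stage 1 is the classic BH step-up at q, its rejection count r₁ estimates the
null proportion (m₀ = m − r₁), and stage 2 reruns the step-up at q·m/m₀ when
0 < r₁ < m. This variant dominates one-stage BH on every input (stage 1 *is*
BH; stage 2 can only widen it), a property the suite asserts, and matches
statsmodels' `fdr_tsbh` exactly.

## Biomarker discovery

PLS-DA is fit by NIPALS against a single centered {0, 1} class column with
successive deflation; scores are mutually orthogonal by construction.
Two components are used by default (exposed as a parameter). VIP scores
follow VIPⱼ = √(p·Σₐ SSYₐ(wₐⱼ/‖wₐ‖)²/Σₐ SSYₐ), so Σⱼ VIPⱼ² equals the feature
count on every fit — asserted in tests. Reported VIPs are the mean (with SD)
over the n leave-one-out refits; the n folds are deterministic and their
order does not affect the mean. A fold that would lose a class is skipped
with a warning; classes of size < 2 are rejected up front.

Fold ratios compare group-mean relative abundances, higher over lower
(FR ≥ 1); a zero lower mean is floored at half the smallest nonzero relative
abundance in the table and flagged.

The LEfSe-style report screens species with the Mann-Whitney U test at
α = 0.05, controls the survivors with the two-stage FDR at q = 0.10, requires
at least five nonzero observations, and scores what remains on per-million-
scaled abundances: the effect size is log₁₀ of the absolute mean of the raw
class-mean difference and the first-axis LDA-projected difference, floored at
1 so effects are non-negative. No additional LDA-score cutoff is applied
beyond the gates. Survivors are by construction a subset of the
MWU-significant species.

## Co-occurrence networks

Networks are built on prevalence-filtered, rank-normalized data. Edges
require a two-sided Pearson p ≤ 0.05 (t distribution, n−2 df) and carry r,
p, sign, |r| as weight, and a significance category: the eight categories are
p-value decades, (5·10⁻², 10⁻²] → 1 down to ≤ 10⁻⁸ → 8, so thicker edges are
more significant and the binning is reproducible and monotone. Communities
come from the Louvain (Blondel) algorithm at resolution 1 on |r| weights —
signs are kept as edge attributes but dropped for community detection, since
classic modularity assumes non-negative weights — with randomized restarts
(default 10) and the best-modularity partition returned; the reported Q is
always recomputed from the returned partition as a consistency check.
Betweenness uses unweighted shortest paths (Brandes), unnormalized; degree is
the incident edge count of the undirected graph. Keystone species are the
top-k nodes by betweenness (ties broken by degree, then species id); a graph
in which no node lies on any shortest path yields an empty keystone list.

`community_separation_test` (statistic: the maximum number of set members
sharing one community; null: random equal-size node subsets) is an explicitly
defined stand-in for assessing topological clustering of a species set — no
canonical procedure exists for this question — and is off by default in
reports.

## The synthetic cohort generator

The generator emulates the *statistical structure* of a paired
vaginal/endometrial 16S study, not its sequences. Per cohort it draws a
latent Gaussian copula Z ~ N(0, C), where C is block-structured (constant
within-block correlation ρ ≥ 0, which guarantees positive semi-definiteness);
log-abundances are profile baselines plus planted biomarker shifts
(log₂ effects for the enriched outcome group) plus σ·Z; structural zeros are
applied per sample × species; the rows are closed to compositions; and counts
are multinomial at a log-normal sequencing depth (CV 0.3, default mean 17,696
reads — a realistic filtered-library size for this assay).

Key parameters and defaults:

- `dominance_fraction` (0.92): expected share of the dominant species in the
  `lactobacillus_dominant` profile; remaining mass follows power-law ranked
  abundances (exponent 1), as does the whole `polymicrobial` profile.
- `noise_sigma` (0.30, log scale): the within-species log-normal perturbation.
  Chosen so that the dominant species' cohort-mean share fluctuates within
  the 90–95% band that characterizes Lactobacillus-dominant vaginal
  communities; compositional closure biases the realized share slightly below
  the nominal target, and larger noise widens and lowers the band.
- `dropout` (0.9): maximum structural-zero probability. A scalar decays
  log-linearly with species abundance — from 0 for the most abundant species
  to the maximum for the rarest — reflecting the abundance–occupancy
  relationship of real communities and creating the prevalence gradient that
  makes the ≥ 20% filter non-trivial. Pre-dropout baselines are inflated by
  1/(1−dropoutⱼ) so expected post-dropout composition matches the profile.
  An explicit per-species array is used verbatim.

Two things the generator deliberately exposes about compositional data are
worth knowing when interpreting recovery tests. First, a planted fold-change
on a species that carries appreciable mass leaks into every other species'
relative abundance through closure; biomarker-isolation experiments therefore
plant effects on species that are rare against a stable dominant backbone.
Second, correlated blocks planted on the most abundant ranks dominate the
closure denominator and induce spurious global correlations; community-
recovery benchmarks plant blocks at mid-abundance ranks.

What the generator does **not** emulate: read-level error, chimeras,
phylogenetic signal, taxonomy beyond a small set of plausible lineages, or
any real-data covariance beyond the planted blocks. Passing recovery tests
therefore demonstrates the pipeline's correctness on data satisfying its own
assumptions, not performance on real sequencing runs.

## Numerical conventions and degenerate inputs

- Permutation p-values: (b+1)/(m+1), seeded; seeds recorded in results.
- Distance matrices must be symmetric (±10⁻¹²) with zero diagonal.
- Zero-variance species are dropped (with warnings) before normalization and
  network construction; zero-sum samples are hard errors.
- Zero-margin rows/columns are removed before the exact r×c test; a table
  reduced to a single row or column has p = 1.
- Comparison groups with fewer than 3 samples skip the affected stages with a
  prominent warning; groups of 3–4 run but are annotated "low-power" (the
  study design this pipeline mirrors includes a 4 vs 30 contrast).
- Pipeline runs are bit-reproducible: all randomness derives from the single
  configured seed via a spawned seed sequence, and rerunning an identical
  configuration yields byte-identical artifacts.

## Problem sizes used in the checks

The automated checks run at desk scale: cohorts of 15–50 samples per group
and 10–100 species, 199–999 permutations, and 20–500 seed replicates per
property (null calibration of the ANOSIM type-I error and of co-occurrence
edge rates, FDR bounds under a global null, and recovery of planted
biomarkers, correlation blocks and habitat separation). The acceptance script
reproduces the full two-habitat design at 34 samples per habitat with 100
species and 999 permutations.

## Known limitations

- The LEfSe-style effect size follows the original tool's spirit (LDA-derived
  magnitude on scaled abundances) but is a per-feature composite, not a
  reimplementation of the original multi-class cladogram machinery.
- No compositionality-aware correlation (SparCC/SPIEC-EASI); Pearson on
  rank-normalized shares inherits closure-induced dependence, which the null
  calibration quantifies at the chosen filter settings.
- Exact Mann-Whitney enumeration stops at 12 pooled observations; the exact
  r×c test stops at N = 200 / 12 cells (a Monte-Carlo fallback is stubbed,
  not implemented).
- PCoA applies no correction for negative eigenvalues; strongly non-Euclidean
  dissimilarity structures will lose some variance from the embedding.
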