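# Methods

## Study design and data model

The pipeline operates on per-domain OTU × sample count tables from a
replicated habitat design. The default design has 21 habitats — five soil
sites (dry hill DH, conifer forest CF, flooded area FL, agricultural soil
AS, shore SH) sub-sampled by depth, plus lake water (LA) and sediments (SE)
— each with three field replicates, i.e. 63 samples per domain table.
Habitats are identified as `SITE-Layer` composites (`DH-Top`, `SH-2`,
`LA-1`, `SE-Low`, …). Counts are non-negative integers (reads); all
abundance-based steps first convert each sample column to proportions, so
sequencing-depth differences between samples never enter a comparison.

## Replicate QC and pooling

Bray-Curtis dissimilarity is computed on relative abundances (not raw
counts). The replicate test partitions all pairwise sample distances into
within-habitat (replicate pairs) and between-habitat sets and applies a
one-sided Welch (unequal-variance) t-test of `within < between`. Welch was
chosen because the two sets differ greatly in size and spread; the test is
run per domain table and each domain is reported separately. Passing
requires both `mean(within) < mean(between)` and `p < α` (default
α = 0.001). Habitats with a single replicate contribute no within pairs and
raise a warning; a design with no within pairs at all is an error.

Pooling sums counts over the replicates of a habitat (it does not average):
the pooled habitat has triple the read depth, so an OTU detected in any
replicate is detected in the pooled habitat. Pooling conserves total reads
and is invariant to replicate order.

## Main-OTU selection and habitat clustering

The main-OTU rule keeps OTUs whose relative abundance is **strictly**
greater than 1‰ in at least one pooled habitat, applied independently per
domain. The strict reading means an OTU sitting exactly at the threshold
everywhere is removed. Filtering is whole-row: an OTU is kept or dropped
globally, never per habitat, which would break table semantics.

Habitats are clustered by average linkage (UPGMA) on Bray-Curtis
dissimilarity of the joint community profile. UPGMA is implemented directly
(rather than delegated) so tie-breaking is fully specified: among equally
distant cluster pairs, the lexicographically smallest pair (by sorted leaf
tuples) merges first, making the dendrogram invariant to input order. The
implementation is cross-checked against an independent average-linkage
oracle (scipy `linkage`/`cophenet`) to 1e-12 in the test suite.

The clustering input stacks the three domains' main-OTU relative-abundance
profiles. By default each domain block is renormalized to equal weight so
the domain with the most OTUs does not dominate the dissimilarity; a flag
(`weight_domains=False`) concatenates raw relative abundances instead —
both behaviours exist because either convention is defensible for a joint
community dissimilarity. Newick export uses the ultrametric half-height
convention (a pair joined at height 0.5 renders as `(A:0.25,B:0.25);`).

## Habitat breadth

Detection is pooled count ≥ 1 by default (`min_count` is exposed; there is
no deeper detection model than sequencing sensitivity). Classes over the 21
pooled habitats: occurrence ≥ 16 → generalist, occurrence = 1 → specialist,
otherwise intermediate; OTUs detected nowhere are excluded. "One habitat"
means one pooled site × depth. The intermediate class is named explicitly
rather than leaving a silent gap between occurrence 2 and 15. Raising
`min_count` can only lower occurrences (classification is monotone), and
the three classes partition the detected OTUs exactly.

## Co-occurrence network

Candidates are OTUs above 1% relative abundance in ≥ 1 habitat, merged
across the three domains over the shared habitat columns (OTU ids are
domain-prefixed, so the merge is collision-free). Correlations are
tie-corrected Spearman's ρ (Pearson on mid-ranks — pooled count data will
tie) between all candidate pairs, within and between domains jointly,
across the 21 pooled habitats. Correlating across the 63 replicate-level
samples instead is deliberately not the default: replicates are
pseudo-replicates of the habitat and would inflate n.

P-values are one-sided for positive association by default, because the
edge rule keeps only ρ > 0.6 — a two-sided option exists. Two methods are
provided: `t_approx` (the t-distributed statistic on n−2 df) and
`exact_perm` (full enumeration of all n! rank permutations for n ≤ 8,
Monte-Carlo permutation beyond); ρ is identical across methods, and the
tests require the t-approximation to agree with enumeration within a
factor of 2 at n = 8. Constant profiles have undefined ρ and are skipped
with a log entry.

No multiple-testing correction is applied by default; a Benjamini-Hochberg
flag exists and either choice is logged. Edges require ρ > 0.6 **and**
p < 0.001; the rule is literal, so strong negative associations are
excluded. Nodes default to OTUs incident to at least one edge (a drawn
network's node set); a flag includes all filtered candidates as isolated
nodes.

Descriptors report both degree conventions side by side: the mean degree
2E/N and the connectivity index E/N (edges per node). The E/N convention is
reported because published network summaries of this kind often quote it as
"average connectivity"; the two must not be conflated. Taxon-pair summaries
report the edge count between two taxa and the maximum endpoint-degree sum
over those edges as separate columns — they answer different questions and
no equivalence is claimed.

## Synthetic communities

The generator is the source of ground truth for every recovery test. Model,
per domain:

* **Base abundances.** Background OTUs draw log-abundance
  `μ ~ N(0, base_sigma²)` with `base_sigma = 1.5` (heavy-tailed, so some
  OTUs are rare enough to drop out at finite depth, producing genuine
  intermediates); planted generalists and specialists draw
  `μ ~ N(planted_mu, planted_sigma²)` = N(1.5, 0.5²) — moderately abundant
  and narrowly spread so their detectability reflects the design, not a
  lottery over base abundance.
* **Habitat structure.** Every multi-habitat OTU gets i.i.d. habitat noise
  `N(0, habitat_sigma²)` (0.6) plus a preferred habitat block — forested
  soils {DH, CF}, open soils {AS, FL}, shore-to-lake {SH, LA, SE} — whose
  habitats get its abundance multiplied by `block_effect` (default 6).
  With `block_effect = 1` and no planted pairs or specialists, habitat
  columns are i.i.d. — this is the null configuration used for edge-rule
  calibration.
* **Specialists** are nonzero in exactly one (randomly assigned) habitat;
  the zeros are structural and survive sampling exactly.
* **Correlated pairs** are drawn from the background pool, made abundant
  everywhere (`μ ~ N(2.0, 0.3²)`), and share one latent habitat factor per
  pair. The factor loading is sized via the Gaussian-copula relation
  `r = 2·sin(π·ρ_target/6)` so the expected profiles reach the target
  Spearman correlation (default 0.9).
* **Sampling.** Each habitat column is renormalized to proportions per
  domain (each domain is its own amplicon pool). Replicate proportions are
  a Dirichlet perturbation with concentration `1/dispersion`
  (`dispersion = 0.002`; 0 means replicates sit exactly at the habitat
  expectation), then `reads_per_sample` (5 000) reads are drawn
  multinomially. Dirichlet keeps replicate-level compositions valid and
  preserves structural zeros.
* **Sizes.** Defaults: 120/90/60 OTUs for bacteria/fungi/archaea with
  3/6/3 planted generalists, 25/20/12 planted specialists and 10 planted
  pairs. These sizes keep a full pipeline run under a second while leaving
  every stage statistically non-trivial; the defaults as a whole are
  calibrated so that planted-structure recovery is robust, not to match any
  particular field data set.

One seed drives everything; per-stage generators are spawned from it
deterministically, so identical spec + seed reproduces tables byte-for-byte.

### What the generator does and does not emulate

It reproduces the *statistical* structure the analysis assumes: replicate
similarity, habitat-block community turnover, occupancy classes, and
positively correlated abundance pairs. It does not emulate amplicon
reality: no PCR/primer bias, chimeras, sequencing error, taxon-specific
copy-number variation, or realistic rank-abundance tails; taxonomy labels
are random draws from small per-domain pools. Synthetic communities also
contain proportionally more generalists than real gradient communities,
because background OTUs are present everywhere in expectation. Passing
recovery tests therefore demonstrates that the pipeline's inferences are
correct when its assumptions hold — not that those assumptions hold for any
particular real community.

## Numerical conventions and degenerate inputs

* Thresholds (`1‰`, `1%`) are strict inequalities; edge selection is
  `ρ > ρ_min` and `p < α`, both strict.
* Bray-Curtis of two all-zero profiles is undefined → error naming the
  sample; all-zero sample columns are flagged at table validation.
* UPGMA on a matrix containing NaN is an error; merge heights are
  non-decreasing by construction of average linkage on a metric input.
* Outputs are canonical: OTUs/samples sorted lexicographically, fixed float
  formatting, no timestamps — identical config + seed gives byte-identical
  output trees (the output directory path itself is excluded from the
  manifest for this reason).
* Seeds below 2³¹ everywhere; sub-streams via `SeedSequence.spawn`.

## Known limitations

* Plain Spearman correlation on relative abundances is blind to
  compositional coupling; with few candidate OTUs the closure effect can
  induce spurious negative (and occasionally positive) associations.
  Compositionality-aware estimators are out of scope.
* The t-approximation for Spearman p-values is approximate at n = 21,
  particularly in the extreme tail; the permutation mode exists as the
  exact reference but enumerates only to n = 8.
* The replicate t-test treats pairwise distances as independent
  observations, which they are not (each sample participates in many
  pairs); the test is calibrated empirically in the suite (type-I ≈ α on
  permuted labels) but remains an approximation, as does any t-test on
  distance sets.
* UPGMA assumes ultrametric-like divergence; single and complete linkage
  are available through the library surface (`upgma(dm, linkage=...)`),
  but the pipeline default is average linkage, the community-ecology
  convention, and only that default has recovery guarantees in the suite.
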