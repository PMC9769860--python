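# Methods

This note documents the models, rules and numerical choices behind
`gutcohort`: what each statistic assumes, what the synthetic cohort
emulates (and does not), and where a design was genuinely open.

## Study design the package targets

A cross-sectional survey of healthy adults across several regions (one
region subdivided into sampling locations), profiled by shotgun
metagenomics, plus a longitudinal arm in which a handful of participants
are sampled monthly for about a year. The package consumes the outputs
of the upstream profiling tools (taxonomic abundance tables, read-to-gene
alignments) rather than running them; every analysis can also run on the
built-in synthetic cohort, which is how the test suite validates it.

## Genetic similarity (GS)

GS measures sequence-level overlap between two samples as the average,
over `reps = 10` repetitions, of the shared count between two
`sketch_size = 10,000`-element sketches of their canonical 31-mer sets,
divided by N_sum (100,000 in the saturating default configuration).

The sketches are *bottom-k under a repetition-salted hash* (MinHash
style), not uniform random subsamples. This is a deliberate reading of a
randomized-sketch protocol: under a shared hash, identical k-mer sets
produce identical sketches, so a sample scores GS = 1 against itself and
E[GS] tracks the containment of the smaller set in the larger — which is
what makes within-person values (~0.25 on the synthetic longitudinal
pairs) interpretable against between-person values (~0.08). Uniform
resampling of 10,000 k-mers from multi-million-k-mer samples would drive
GS toward 0 even for identical samples and destroy that scale. The hash
is a 2-bit k-mer packing mixed through splitmix64 with one salt per
repetition; everything is reproducible from the integer seed.

For non-saturating inputs (fewer than `sketch_size` distinct k-mers) the
denominator falls back to Σ_i min(|a_i|, |b_i|), keeping GS in [0,1] and
self-similarity at 1; with `sketch_size ≥ |A∪B|` GS equals the exact
overlap fraction. Which sequence fraction to sketch (e.g. reads left
unclassified by the taxonomic profiler) is the caller's choice: the API
takes arbitrary sequence sets and does not impose a filtering policy.

Accuracy: on planted containments 0.1–0.9 with 10⁵-k-mer universes the
absolute GS error stays below 0.01 (the acceptance script measures
~0.004); the estimator has a small negative bias of order
min-threshold concentration, ≪ the 0.02 the tests allow.

## Presence rules and their boundaries

All of the screening thresholds are *strict* inequalities, and the tests
pin the boundaries:

* alignment identity must exceed 80% (a hit at exactly 80.0% is
  discarded);
* merged coverage must exceed 90% (90/100 covered bases is absent);
* a watch-list (DRM) species is retained only above 0.1% relative
  abundance in at least one sample (exactly 0.1% everywhere is not
  retained);
* a metagenome bin is labeled only when one phylum strictly exceeds 50%
  of its contigs, unclassified contigs counting in the denominator;
* a virulence factor is stable within a person only when present in
  strictly more than 60% of that person's samples.

Coverage is computed per (sample, gene) by pooling all identity-passing
hits and taking the union of their reference intervals (1-based
inclusive; touching intervals merge because per-base coverage is the
underlying quantity). Pooling across the whole sample is the only
reading under which >90% coverage is attainable from short reads.
SAM identity is computed over aligned (M/=/X) columns as
`100·(aligned − mismatches)/aligned`, with inserted and deleted bases
subtracted from the NM edit distance so indels are not double-counted as
column mismatches; the MD tag is used when NM is absent. Secondary and
supplementary alignments count toward coverage by default (multi-mapped
reads legitimately cover catalog genes); a flag excludes them.

The core-taxon rule is the one inclusive threshold: a taxon is core when
its relative abundance is ≥ 0.01% in every sample. The same floor is the
default detection limit for richness/diversity (the appropriate floor is
profiler-dependent and configurable). The coefficient of variation is
computed over positive samples only, where an intermittent taxon's
volatility is actually observed. Confidence intervals on mean abundance
are t-based normal-theory intervals.

Enterotypes use the deterministic dominant-marker rule (ET_P iff
Prevotella > Bacteroides, ties to ET_B, marker pair configurable) rather
than a clustering method: it is reproducible, needs no fitted model, and
captures the Prevotella-driven enterotype switching the longitudinal
design is meant to expose.

## Dissimilarity statistics

Bray-Curtis is computed on renormalized percent profiles. PERMANOVA uses
the distance-based decomposition SS_total = Σ_{i<j} d²_ij/n and
SS_within = Σ_g Σ_{i<j∈g} d²_ij/n_g, R² = 1 − SS_within/SS_total,
pseudo-F with (a−1, n−a) degrees of freedom, and free label permutation
with p = (1+b)/(1+m) so p is never zero; the permutation loop is
vectorized and seeded. The factor sweep runs one *marginal* PERMANOVA
per factor (dropping samples missing that factor), so R² values are not
a joint decomposition. No multiple-testing correction is applied by
default, matching common practice for these descriptive sweeps.

The within- vs between-group contrasts feed pairwise distance lists into
a Wilcoxon rank-sum test (exact enumeration when the pooled size is ≤ 12
without ties, otherwise the normal approximation with midranks, tie and
continuity corrections — implemented via `scipy.stats.mannwhitneyu`
behind the package's method-selection rule). **Caveat:** pairwise
distances sharing a sample are not independent, so these p-values are
descriptive, not exact; this mirrors how such cohort contrasts are
usually reported and is deliberately left uncorrected.

PCoA is classical metric scaling (double-centered −d²/2, symmetric
eigendecomposition). Negative eigenvalues — expected for Bray-Curtis —
are dropped and their relative magnitude reported rather than corrected,
since the plots are descriptive.

Sampling intervals classify as *short* when two samples of one person
are from consecutive months (|Δ| = 1), *long* when more than 6 months
apart, *other* in between.

## Synthetic cohort: what it emulates

Per-sample log-abundance of taxon k is

    base_k + region_{r,k} + individual_{p,k} + drift_{p,k}(t) + noise

with independent Gaussian effects (defaults: region SD 0.3, individual
SD 0.8, noise SD 0.2, drift a per-month random walk with SD 0.15),
softmaxed and scaled to percent. Log-normal offsets + softmax was chosen
over a Dirichlet model so each effect is additive and can be switched
off independently, making planted orderings directly testable: the
random walk gives expected dissimilarity that grows with the sampling
interval, and individual ≫ region gives the within/between and R²
orderings the real cohorts show. The default individual/region ratio
reflects the field's consistent finding that who you are explains far
more community variance than where you live.

Core taxa get elevated base means and a post-hoc floor clamp (with a 2×
margin, followed by one renormalization) so the ≥ 0.01%-everywhere
guarantee is exact; each non-core taxon is forced absent in at least one
sample so the planted core set is identifiable. Enterotype-ET_P
participants (default 15% of the cohort) receive an individual-level
Prevotella offset large enough to dominate Bacteroides; with
individual effects disabled there are, by construction, no per-person
differences and hence no ET_P participants — the fully degenerate
configuration (all SDs zero) produces bit-identical samples.

Gene-screen truth is realized exactly: a planted (coverage c, identity)
pair emits left-to-right tiled intervals whose union is exactly
`round(c·L)` bases, with identities jittered by at most ±0.8 points so
planted values never cross the 80% filter. Planted k-mer universes share
exactly `round(c·n)` elements. Persistence designs plant cohort-stable,
individual-stable, transient and absent genes whose implied presence
matrix is the oracle for the stability classifier.

What the generator does *not* emulate: read-level sequencing error and
chimeras, compositional zero-inflation beyond the Bernoulli transient
model, taxon-taxon correlations, database/classifier bias, or uneven
per-participant sampling. Passing tests therefore demonstrate that the
statistics recover the structure they target under a clean generative
model — not that upstream profiling artifacts are handled.

## Problem sizes and numerical choices

The validation suite runs at deliberately modest sizes chosen to make
the checks sharp but cheap: GS sweeps use 10⁵-k-mer universes (the scale
at which default sketches saturate), the null-calibration study uses 400
simulated 20-sample datasets with 199 permutations (nominal 0.05 size,
binomial SE ≈ 0.011), effect-direction recovery uses 20 seeds of a
4-region × 3-participant × 12-month design (144 samples), and the screen
truth grid uses 10 samples × 20 kilobase-scale genes (200 pairs covering
the 90%-coverage and 75/85/99% identity boundaries). Distance matrices
are validated for symmetry/zero diagonal on construction; permutation
p-values use the (1+b)/(1+m) convention; F-ties at machine precision
count as exceedances (ε = 10⁻¹²); all child seeds derive
deterministically from one integer seed.

## Known limitations

* Wilcoxon on pairwise distances ignores pair dependence (see above).
* PERMANOVA permutes labels freely; nested designs (participants within
  regions) would need restricted permutation, which is not implemented
  for the sweep.
* The packaged pathogen watch list and drug-class prefix map are small
  editable stand-ins, not authoritative references; users should supply
  their own lists for real analyses.
* Kraken-report parsing uses clade-level percentages at the chosen rank
  by default (`counts="direct"` recomputes from direct-assignment reads);
  which convention an upstream pipeline used should be checked.
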