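# gutcohort

Analysis toolkit for spatial and temporal structure in gut-microbiome
cohorts, built around the design of a multi-region shotgun-metagenomics
survey with a small longitudinal arm (participants sampled monthly for a
year). It is aimed at microbiome researchers who have upstream profiles
in hand — taxonomic abundance tables (e.g. Kraken-2 reports), read-to-gene
alignments against ARG/virulence-factor catalogs (SAM or BLAST tabular) —
and want the cohort-level statistics downstream of them.

## What it computes

**Genetic similarity (GS).** Sequence-level overlap between two samples
via repeated bottom-k sketches of their canonical 31-mer sets. For each
of 10 repetitions, the 10,000 k-mers with the smallest values under a
repetition-salted hash are selected from each sample and the shared count
N_i recorded:

    GS = (N_1 + N_2 + … + N_10) / N_sum

with N_sum = 10 × 10,000 when both samples saturate every sketch, else
Σ_i min(|sketch_a_i|, |sketch_b_i|). GS is an estimator of the
containment |A∩B| / min(|A|,|B|) of the two k-mer sets: identical samples
score exactly 1, disjoint samples 0.

**Community profile.** Core taxa (relative abundance ≥ 0.01% in *every*
sample), alpha diversity (richness S, Shannon H = −Σ p_i ln p_i, Pielou
J = H/ln S), coefficient of variation of core taxa over positive samples,
a pathogen watch-list screen (species retained when > 0.1% in at least
one sample), and dominant-marker enterotypes (ET_P iff Prevotella >
Bacteroides, else ET_B).

**Gene screen.** A catalog gene is present in a sample when, after
discarding alignments with identity ≤ 80%, the union of surviving hit
intervals covers > 90% of the gene (coverage % = total match region /
gene size). Present ARGs roll up into curated drug classes; metagenome
bins inherit a phylum label only when one phylum strictly exceeds 50% of
the bin's contigs.

**Cohort statistics.** Bray-Curtis dissimilarity d = Σ|x−y| / Σ(x+y),
principal-coordinate analysis, within- vs between-group contrasts of
pairwise distances (Wilcoxon rank-sum), one-factor PERMANOVA
(R² = SS_between/SS_total, permutation p = (1+b)/(1+m)) with a marginal
factor sweep, short (consecutive months) vs long (> 6 months) sampling-
interval contrasts, and per-feature stability labels (individual-stable =
present at all of a person's time points; cohort-stable = present in
every sample of every person; virulence factors flagged stable at the
strict > 60%-of-samples rule).

**Synthetic cohort.** All inputs can be generated with planted structure:
log-normal region/individual effects + per-month random-walk drift +
noise through a softmax, guaranteed core taxa, Prevotella-dominant
participants, gene hits realizing exact planted coverage/identity, and
k-mer sets with exact planted containment. Every generator is a pure
function of its seed.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (seed 1) and write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py      # inputs: 48-sample cross-sectional + 84-sample longitudinal arm
python analysis/02_community_profile.py
python analysis/04_kmer_similarity.py
python analysis/05_spatial_temporal_stats.py
```

Selected output (what the scripts actually print):

```
30 core genera (present >=0.01% in all samples); most abundant:
  Bacteroides: mean 20.42% (95% CI 16.70-24.15), CV 0.63
mean GS: within-person 0.249 vs between-person 0.080 (higher within-person overlap recovered)
  participant: within mean 0.2162 vs between mean 0.5508 (Wilcoxon p = 1.19e-258)
  interval: short (consecutive months) mean 0.1874 vs long (>6 months) mean 0.2364 (Wilcoxon p = 3.65e-07)
PERMANOVA factor sweep (pooled arms, sorted by R^2):
participant_id     0.8941   12.0329   0.0050
region             0.0573    2.5940   0.0050
```

Reading: all 30 planted core genera are recovered; two samples from the
same (simulated) person share far more 31-mer content (GS 0.249) than
samples from different people (0.080); communities drift apart with the
sampling interval; and the individual explains an order of magnitude more
community variance than geography — the qualitative structure such
cohorts show.

There is also a thin CLI (`gutcohort simulate|profile|screen|gs|cohort|run-all`)
over the same functions.

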