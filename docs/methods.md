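# Methods

This note documents the models and procedures implemented in `vebakit`, the
parameter choices that matter, the synthetic-data conventions, and the known
limitations. It states nothing the test suite or `scripts/acceptance.py`
does not itself compute.

## Naming and identifier plumbing (`core_io`)

MAG names follow one scheme per domain:
`[SampleID]_[Algorithm]_P.[Iteration]_[Name]` (prokaryotes),
`..._E.[Iteration]_[Name]` (eukaryotes), and `[SampleID]_[Algorithm]_[Name]`
(viruses, which are detected per contig in a single pass and carry no
iteration tag). `_` is reserved as the field separator: sample ids and
algorithm names may not contain it, local names may. A viral local name
whose leading token matches the `P.<k>`/`E.<k>` iteration pattern is
rejected at render time because the rendered string would be ambiguous on
parse; with that single exclusion, render/parse is a lossless round trip.

Simplified eukaryotic gene identifiers use the template
`[ContigID]_[GeneStart]:[GeneEnd]([strand])`. Exact coordinate duplicates —
possible in principle from overlapping predictions — get a `.k` suffix with
k the 1-based duplicate ordinal, bumped further if the suffixed form itself
collides; emitted ids are therefore always unique.

The harmonized GFF3 output places every gene, eukaryotic or prokaryotic,
under one shared attribute key, **`gene_id`** (plus a `contig_id` attribute
and a GFF3 `ID`). The key was chosen to match the default grouping
attribute of common feature-counting tools so a single counting invocation
covers both gene sets. GFF3 coordinates are 1-based inclusive; the gene
tables consumed and produced at the I/O boundary use the same convention,
while internal interval arithmetic (the coding-span union behind coding
density) works half-open before converting back.

Assembly statistics: N50 is the largest contig length L such that contigs
of length ≥ L cover at least half the total assembly; GC fraction is
(G+C)/(A+C+G+T) with ambiguity codes excluded from numerator and
denominator; coding density is the union of coding spans divided by total
bp, so overlapping annotations are not double-counted.

## Bin-level domain consensus (`domain_consensus`)

Per-contig domain-prediction probability vectors are combined per bin as

    logit_d = Σ_c w_c · ln(max(p_{c,d}, ε)),    ε = 1e-10,

followed by a softmax over categories. The log-sum is the only aggregation
consistent with turning probabilities into additive logits; the ε floor
keeps a single zero probability from vetoing a bin (it contributes a large
but finite penalty instead). Weights are uniform by default;
`weighting="length"` multiplies each contig's log term by length/mean
length, on the reasoning that a 100 kb contig carries more signal than a
2 kb one. Both modes are exposed because neither is canonical. Ties in the
final argmax break by the configured category order. Bin-level calls
partition into eukaryotic / prokaryotic / undetermined by whether the
summed probability over the eukaryote category set (typically eukarya +
organelle, so organelles ride with their host genome) reaches
`min_probability` (default 0.5).

## Consensus taxonomy (`taxonomy_consensus`)

Each protein hit carries an ordered lineage (coarse → fine) and a score.
For every lineage prefix P at level i observed among a genome's hits,

    score(P) = s_i · Σ {score of hits whose lineage starts with P},
    s_i = i^(1/leniency),  i = 1..N.

The genome is assigned to the argmax; ties break toward the deeper prefix,
then lexicographically. The functional form of s_i is this package's
choice: the leniency parameter is defined behaviorally (leniency 1 rewards
depth linearly with weights 1, 2, 3, …; leniency → ∞ flattens to all-ones
so coarse ranks, which accumulate all descendant scores, win). Other
published consensus classifiers may use a different scaling array, so
absolute scores are comparable only within one run of this implementation —
assignments, not scores, are the stable output. Hits below a
marker-specific noise cutoff are discarded before scoring; a genome whose
hits are all discarded is returned flagged unclassified rather than
raising.

Cluster-level consensus pools the member genomes' hit tables and classifies
the pool (default). A voting mode is provided in which each member genome
is classified first and the assignments vote with unit score; pooling
weights genomes by their total score mass, voting weights them equally.
Consensus habitat is a plurality vote over non-missing member labels, ties
going to the lexicographically first label with a tie flag.

A useful monotonicity property holds by construction: because every
deep-vs-shallow pairwise comparison shifts toward the shallow prefix as
leniency grows (the weight ratio (j/i)^(1/leniency) decreases in leniency
for j > i), the assignment depth is non-increasing in leniency. The suite
verifies this over randomized tables.

## Quality gates (`quality_filters`)

Prokaryotic default: a genome is removed when completeness ≤ 50 or
contamination > 10 (pass requires completeness > 50 AND contamination
≤ 10). Source conventions differ on whether the completeness boundary is
strict, so both boundaries carry explicit inclusivity flags; the
`high_quality` preset is completeness ≥ 70 AND contamination < 2. CPR
(candidate phyla radiation) genomes — detected by lineage substring match
against a configurable set, default `Patescibacteria` — are re-scored
through an adapter implementing the appropriate marker-set assessment, then
the whole set is refiltered; non-CPR genomes are byte-identical before and
after, and a failing adapter produces a per-genome error record instead of
aborting the batch.

Viral contigs pass when all of: candidate p-value < 0.05, viral genes ≥ 5 ×
host genes, completeness ≥ 50%, and both the quality tier and the MIUViG
tier in {medium, high, complete}; proviruses are excluded unless opted in.
Eukaryotic bins pass at ≥ 2,000,000 bp; contigs pass at ≥ 1500 bp. Printed
thresholds without an explicit operator are treated as inclusive.

## Iterative consensus binning (`iterative_binning`)

Per iteration t: all binner adapters run on the remaining pool with seed
`seed_policy(base_seed, t) = (base_seed + t·1000003) mod 2³¹` (an explicit
pure function so runs are replayable); candidate bins are dereplicated to a
consensus set; the QC gate runs **after** dereplication and **before**
contig removal, so contigs of rejected bins recycle into the next
iteration; accepted bins are named with the iteration tag and their contigs
leave the pool. The loop stops at `n_iter`, when the pool empties, or —
since deterministic adapters would just repeat themselves — when an
iteration accepts zero bins (a flag forces all iterations for stochastic
adapters). Invariants maintained and tested: accepted contig sets are
pairwise disjoint, their union with the remaining pool is the initial pool,
the pool never grows, and `n_iter=1` reproduces a plain single-pass
consensus binning.

The built-in dereplicator is deliberately naive: candidate bins ranked by
score (default: member count) are accepted greedily unless any member
contig is already claimed, with deterministic tie-breaks. Real workflows
should plug an external consensus tool through the same adapter contract.

Pseudo-coassembly: the union of per-sample unbinned contigs (≥ 1500 bp),
each id prefixed `sample__contig` — a double-underscore separator so the
source sample parses back unambiguously even when sample ids contain single
underscores.

## Species-level clustering (`genome_clustering`)

Genomes are nodes; edges with ANI ≥ threshold (default 95%, the
conventional species boundary) survive; clusters are connected components,
so species membership is transitive through chains of high-ANI pairs.
Asymmetric ANI pairs are symmetrized by the maximum before thresholding.
Cluster ids are dense, numbered from 0, ordered by descending size then by
lexicographically smallest member — deterministic across runs. Isolated
genomes are singleton clusters, so the assignment is total.

SSO ids namespace per-SLC orthogroup labels as `SLC_label`, making them
globally unique; proteins placed in no orthogroup are flagged unclustered
and excluded from functional compression. The marker presence/absence
filter for phylogeny inputs drops rare markers first (present in fewer than
`min_genomes_ratio` of genomes), then drops genomes holding fewer than
`min_markers_ratio` of the retained markers — one pass, no fixpoint
iteration; the order matters and is fixed.

## Feature compression (`feature_compression`)

Aggregation sums feature columns by their group; with a total grouping,
per-sample totals are conserved, and aggregation composes along the
hierarchy (contig→MAG then MAG→SLC equals contig→SLC). Counts may be
integers or non-negative reals (coverage-normalized tables).
FCR = 1 − N_clusters/N_features, in [0, 1); the functional variant is the
same ratio computed over clustered ORFs only, so the caller must exclude
unclustered ORFs before forming the numerator. Percent rendering rounds
half-even to one decimal.

## Compositional networks (`compositional_networks`)

CLR uses a pseudo-count of 1/m² (m = number of features) and the natural
log; each transformed row sums to zero, and CLR is invariant to per-sample
closure. Aitchison distance is the Euclidean distance on CLR rows. ρ
proportionality uses the unbiased (n−1) variance estimator in both
algebraically equivalent forms, 1 − var(x−y)/(var x + var y) =
2·cov/(var x + var y), which the suite checks agree to 1e-12.

The ensemble network bootstraps samples with replacement, recomputes all
pairwise ρ per iteration (vectorized through the covariance matrix), and
averages element-wise, NaN-aware: a bootstrap draw can leave a feature with
zero variance, and such undefined entries are simply excluded from the
mean. Bootstrap-with-mean is this package's concrete reading of "ensemble";
the iteration count (default 1000) follows common practice. The degenerate
setting (one iteration, no resampling) reproduces the plain ρ network
exactly.

Differential connectivity D = ρ_a − ρ_b is reported for pairs that are
positive in both conditions and have |D| ≥ 0.1 (both enrichment directions
are kept; the sign of D is preserved). Prevalence filtering keeps features
with count > 0 in at least 40% of samples (boundary inclusive). The 1 − ρ
dissimilarity (range [0, 2]) feeds standard average-linkage agglomeration.

**Known limitation.** For a feature pair that is genuinely independent in
one condition, the CLR transform induces a small negative expected
association (≈ −1/m, the classic compositional closure bias), so such a
pair sits on the wrong side of the positive-in-both filter about half the
time. A differential edge whose association is near zero in the reference
condition is therefore retained in roughly 40% of replicates, not
near-always; recovering such edges reliably requires either a positive
baseline association in both conditions or relaxing the positivity rule.
The suite documents this behavior directly.

## Synthetic fixtures (`synthetic_fixtures`)

All generators are pure functions of a `FixtureSpec` (seed included).
Conventions: contig lengths log-normal (median ≈ 3 kb, σ = 0.7 in log
space); domain probability vectors Dirichlet-concentrated on the planted
domain (one-hot in the infinite-concentration limit); ANI fixtures plant
clusters with within-cluster ANI 96–99% and between-cluster 80–90%, ranges
that any threshold in (90, 96) separates exactly; counts fixtures draw
per-feature Gaussian log-abundances (σ = 1), give planted pairs a shared
latent factor with correlation 0.9 in condition A (and a configurable
baseline, default 0, in condition B), and close each sample to a fixed
depth of 100,000 reads by multinomial sampling; annotation fixtures plant a
5-level lineage with a 10% contamination fraction diverging at level 4,
recoverable at leniency 1. Sizes default to 40 samples and 20 features for
counts and 12 genomes in 3 clusters for ANI — small enough that the full
suite runs in well under a minute while leaving the planted structure
unambiguous.

What the fixtures do **not** emulate: read-level error, assembly artifacts,
uneven coverage, strain microdiversity, or realistic taxon abundance
distributions. Passing tests demonstrate the correctness of the
orchestration, scoring, clustering, and compositional arithmetic on inputs
with known ground truth — not end-to-end recovery performance on real
metagenomes, which depends on the external tools behind the adapter
contracts.

## Acceptance computations

`scripts/acceptance.py` reruns the feature-compression pathway at the
stated cardinalities — a random counts table of 200 MAG features aggregated
through a surjective 50-cluster grouping, and an 1100-ORF table of which
1000 ORFs carry SSO assignments aggregated into 100 SSOs — and reports the
compression ratios measured from the aggregated shapes. The seed controls
the random count values; the ratios depend only on the cardinalities, which
is itself a property worth seeing hold.
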