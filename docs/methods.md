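# Methods

This note documents the models behind `domprof`, the default parameters and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that make results reproducible.

## The profiling method

A genome or metagenome sample is summarised as a column of the domain count
matrix **X** (domains × samples): `X[d, s]` is the number of occurrences of
domain `d` among the proteins (or translated read peptides) of sample `s`.
Occurrences are counted individually — two hits of the same domain on one
protein contribute 2. Three representations are supported:

| transform | value | use |
|---|---|---|
| `raw` | occurrence count | default for genome profiling |
| `binary` | 1 if count ≥ 1 else 0 | suppresses high-copy domains entirely |
| `log1p` | ln(count + 1) | damps high-copy domains smoothly |
| `frequency` | count / column sum | environmental samples (unequal depth) |

Samples are compared by the Pearson correlation of their columns over the
**full** shared row set, including rows where both samples are zero. This
convention matters: joint absences carry phylogenetic signal here (domain
repertoires are sparse), and dropping them changes `r`. Pairs involving a
constant (zero-variance) profile are NaN, reported, and excluded from
downstream summaries with a logged count — never silently dropped.

## Concordance with marker genes

For every species pair present in both a profile-similarity matrix and a
marker distance matrix, the pair contributes a point (`r_domain`,
`d_marker`); the Pearson correlation of this cloud is the concordance
statistic. Because similarity and distance point in opposite directions, a
real signal makes this correlation *negative*; reports carry both the
signed `r` and |r|, since the magnitude is what published analyses usually
quote.

Two p-values are offered. The conventional t-test
(`t = r sqrt((n−2)/(1−r²))` on n−2 df) treats the n(n−1)/2 points as
independent, which they are not — each species appears in n−1 pairs — so it
is optimistic and is labelled as such. The Mantel permutation test
(permute species labels of one matrix, ≥999 permutations, two-sided on |r|)
is the statistically defensible alternative and is what the acceptance
checks use.

Marker distances: p-distance (proportion of differing sites, pairwise
deletion of gaps/ambiguities) is the default because it is assumption-free
and the concordance statistic is only mildly model-sensitive;
Jukes–Cantor (`−(3/4) ln(1 − 4p/3)`, DNA) and Poisson (`−ln(1 − p)`,
protein) corrections are available. Inputs must be pre-aligned; alignment
construction is out of scope. Before distance work, sequences shorter than
half the median (non-gap) length are removed, and groups of byte-identical
sequences are removed entirely by default (`drop_all`) — identical markers
carry no pairwise signal and usually flag a database artefact; `keep_one`
is available.

## Short-read pipeline

Fragments of fixed length (default 100 bp) are cut uniformly at random,
with replacement and from both strands, so that the expected total length
is `depth_multiple` (default 10) times the genome; the fragment count is
exactly `round(depth · L / frag_len)`. Genomes are treated as linear — at
100 bp the origin edge effect is negligible.

Each fragment is translated in all six frames; codons containing N
translate to X; each frame is split at stop codons into maximal stop-free
peptides (matching how domain scanners handle ORFs, and maximising
detectable material), then length-filtered. Two filter conventions are
used: ≥ 8 aa for the genome-fragment benchmark (short enough that a motif
inside a stop-split piece still counts) and ≥ 30 aa for the environmental
workflow, the standard threshold for read-level peptides. A
`subsample_reads` step (uniform, without replacement) models fixed-size
read sets.

## Community analysis

Environmental samples are clustered on the correlation distance
`d = 1 − r` of their frequency profiles with the Ward.D2 criterion — the
convention of R's `hclust(method="ward.D2")`: input dissimilarities are
used as-is and the merge criterion minimises the within-cluster variance
increase, via the Lance–Williams update

    d(k, i∪j)² = [(n_i+n_k) d_ik² + (n_j+n_k) d_jk² − n_k d_ij²] / (n_i+n_j+n_k).

Ties are broken by the lexicographically smallest node-index pair (leaves
first, then merge-creation order), so the merge sequence is deterministic
for a given input order. The implementation is checked in the test suite
against two independent routes: a brute-force evaluation of the closed
centroid form of the Ward distance, and scipy's `linkage(..., "ward")` on
the same condensed distances.

Cluster support is the plain bootstrap proportion: domain rows are
resampled with replacement B times (default 1000), the whole
similarity → distance → Ward.D2 chain is recomputed, and a node's BP is the
percentage of replicates containing the same leaf set. Multiscale-bootstrap
AU p-values would be a natural extension; BP preserves the qualitative use
(support for cluster structure) at a fraction of the complexity. If a
resampled profile has zero variance its correlations are set to 0 for that
replicate.

Flat clusters (cut at k) are compared to sample covariates with the
adjusted Rand index. PCA is computed by SVD of the column-centred
(optionally unit-variance scaled) samples × domains matrix; component signs
follow the convention that each component's largest-magnitude loading is
positive; explained-variance fractions are relative to total variance and
sum to 1 when all components are kept. Covariates are ranked by the mean
silhouette of their grouping in score space (Euclidean metric; singleton
groups take silhouette 0). Heatmap layout clusters columns by Ward.D2 on
correlation distance and rows by Ward.D2 on Euclidean distance of log1p
counts (row treatment is a package choice; nothing downstream depends on it).

The cold/warm season dichotomy (December–April vs May–November) is the
standard grouping for the coastal time-series design this emulates; it is
derived from the collection date and overridable.

## Synthetic data: what it emulates

The generator provides ground-truth inputs with the statistical structure
the method assumes. Defaults are the package's standard study conditions;
all rates are stand-ins chosen for realism at desk scale, not estimates
from data.

* **Tree** — random topology by uniform sequential joins; branch lengths
  i.i.d. exponential with mean 0.1 substitutions/site-equivalent.
* **Vocabulary** — 600 domain types, each a fixed 8–12 aa motif; motifs are
  mutually non-nested so exact-match scanning is unambiguous, and short
  enough to fit inside the 33-aa translation of a 100 bp read frame.
* **Repertoires** — the root carries 150 single-copy types. Along a branch
  of length t each type is lost with prob 1 − exp(−loss·t); survivors
  duplicate as a per-copy birth process (each copy adds one with prob
  1 − exp(−copy·t)); Poisson(gain·t) new types arrive at copy 1. Defaults
  gain = 450, loss = 3, copy = 2 keep the equilibrium repertoire near
  gain/loss = 150 types while (a) turning domains over fast enough that
  each species carries only ~35–40% of the domains seen across a study —
  matching the sparsity of real domain matrices, where a genome holds a
  small minority of the union's domains — and (b) producing overdispersed
  copy numbers, since real profiles are heavy-tailed. Duplication acts per
  copy rather than once per type because gene duplication operates on gene
  copies; at copy number 1 the two formulations coincide.
* **Genomes** — every domain copy becomes one random protein (60–300 aa,
  leading M) with the motif embedded at a random position, uniformly
  reverse-translated into an ATG…stop ORF; ORFs sit head-to-tail on the
  forward strand with random intergenic filler sized to a target coding
  density (default 0.8, the realistic bacterial 70–90% range). Stop codons
  make the realised coding ratio sit ~1–2 points below the target — well
  inside the ±5-point tolerance the tests assert. No codon bias is
  modelled; it is irrelevant to domain counting.
* **Scanner** — exact, case-insensitive motif matching with 1-based
  inclusive coordinates, emitting the same 11-field hit records the
  InterProScan parser produces. Exactness is the point: on the emitted
  proteome the scan recovers every embedded copy and nothing else, so
  matrix-level tests have exact expectations. It stands in for a
  profile-HMM search, and deliberately shares none of its sensitivity
  behaviour.
* **Markers** — symmetric (Jukes–Cantor-style) site substitution on the
  same tree, DNA (4 states) or protein (20 states), gap-free output.
  `calibrate_marker_rate` inverts p = (3/4)(1 − exp(−(4/3) r D̄)) at the
  tree's mean patristic distance to hit a target mean p-distance (0.1 in
  the standard recovery study).
* **Communities** — per-sample reads are 100 bp fragments drawn from a
  genome pool with sample-specific mixture weights. The standard design
  assigns each filter pore class (0.2, 0.8, 5 μm) a disjoint dominant
  genome set carrying 90% of the weight; an optional season effect splits
  the 0.8 μm dominant set into cold- and warm-favoured halves. Depth class
  and station follow balanced patterns orthogonal to the season
  alternation, so season is the only composition-driving covariate besides
  pore size. Defaults: 4 samples per pore class, 8000 reads per sample —
  scaled down from the half-million-read scale of real surveys, but large
  enough (~800 domain detections per sample) that multinomial sampling
  noise stays well below the between-class effect.

Not emulated: sequencing error, quality scores, paired-end structure,
indels, rRNA secondary structure, GTR-class substitution heterogeneity,
codon bias, strand placement of genes, and profile-HMM sensitivity/false
positives. Passing tests therefore demonstrate the correctness and internal
consistency of the pipeline and the qualitative behaviours (phylogenetic
signal in profiles, transform effects, covariate-driven clustering), not
detection performance on real reads.

## Problem sizes and numerical conventions

Standard study sizes: 20 species for tree-recovery concordance, 12 species
× 20 replicate seeds for the transform-effect comparison, 8 species with
full genome emission for the fragment-fidelity benchmark, and 12
environmental samples (3 pore classes × 4) for the community workflow.
These sizes give stable statistics in seconds-to-a-minute per stage on one
CPU.

* Coordinates in hit tables are 1-based inclusive; matrices are written
  domains-as-rows with the transform recorded in a `#transform=` header
  and orientation enforced on read.
* Hit tables are accepted in comma- or tab-separated form; the delimiter is
  sniffed from the first line and can be forced.
* Unknown FASTA residues are masked (X for protein, N for DNA) by default;
  a strict mode rejects them.
* The coding-ratio species filter defaults to 50%: complete proteomes sit
  at 70–90%, incomplete protein sets fall to single digits, so 50%
  separates the regimes with margin on both sides. Ratios above 100%
  (overlapping ORFs) are allowed with a warning.
* Newick output encodes branch lengths as merge-height differences (leaves
  at height 0) and bootstrap percentages as internal node labels.
* A single study seed fans out deterministically into per-stage child seeds
  (`child_seed(seed, tag)`, CRC-based, < 2³¹), so each stage is
  independently reproducible.
* Binary thresholding is at count ≥ 1 (presence); frequencies of an empty
  sample stay zero with a warning rather than erroring.

## Known limitations

* The naive concordance p-value ignores pair dependence; use the Mantel
  test for inference.
* Ward.D2 here is O(n³) in pure Python — fine for tens-to-hundreds of
  samples, not for thousands.
* The toy scanner cannot model partial-domain matches across read
  boundaries; a real profile-HMM search finds truncated domains that exact
  matching misses, so fragment-pipeline detection counts are conservative
  relative to InterProScan on the same reads.
* Outlier-species exclusion before concordance is a user-supplied list;
  no automatic criterion is applied.
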