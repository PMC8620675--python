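# Methods

`repeatome` profiles the repetitive fraction of genomes directly from raw
sequencing reads, without a reference assembly or a curated repeat
database. The pipeline has four stages: (1) de novo discovery of putative
repetitive elements ("kChains") by dense biclustering of a bipartite
k-mer/read incidence graph; (2) classification of the discovered library
into nuclear, organellar, and technical-artifact bins by k-mer containment
against user-supplied references; (3) per-sample abundance quantification
as the median per-position read coverage of each element, followed by
filtering, log transformation, and quantile normalization; (4) downstream
analysis of the abundance matrix by PCA biplot association and
neighbor-joining phylogeny over samples.

## The incidence graph and its density

Reads and k-mers form a bipartite graph G{V1, V2, E}: V1 are canonical
k-mers (the lexicographic minimum of a k-mer and its reverse complement,
collapsing strand), V2 are reads, and an edge (m, r) exists exactly when m
or its reverse complement occurs in read r. Edge multiplicity within one
read is collapsed. The density of a subgraph on (Vs, Vt) is

    d(Vs, Vt) = |Est| / (|Vs| * |Vt|),

which lies in [0, 1] and equals 1 exactly for bicliques. A repeat family
present in many genomic copies induces a dense region: its consensus
k-mers co-occur in the many reads drawn from its copies. Discovery runs at
k = 12 and k = 15 by default and merges the two libraries, dropping chains
identical up to reverse complement.

Only k-mers occurring in at least `min_kmer_reads` reads (default 2) enter
V1: singleton k-mers carry no repeat signal and dominate memory otherwise.
Internally k-mers are 2-bit-encoded integers (A=0 < C=1 < G=2 < T=3, so
integer order equals lexicographic order and canonicalization commutes
with encoding); the public graph API uses strings.

## Bicluster search

The search is a deterministic seed-and-grow with batch sweeps:

1. **Seed** at the highest-degree k-mer not yet examined (ties broken
   lexicographically); Vt is initialized to the seed's reads.
2. **Grow** by alternating sweeps: one sweep admits every candidate k-mer
   with at least `min_density * |Vt|` live edges into Vt, the next every
   read with at least `min_density * |Vs|` edges into Vs, until a fixed
   point. By induction this keeps the cluster density at or above
   `min_density` throughout, and because admission is evaluated against
   the whole current cluster (not one vertex at a time) the cluster cannot
   drift stepwise along a chromosome, a failure mode we observed with
   serial admission: each single admitted read re-anchors the window and
   the "cluster" percolates through hundreds of unrelated loci.
3. **Prune** with the dual rule: batch-remove every vertex whose
   in-cluster connectivity has fallen below the same threshold, to a fixed
   point. The result is a `min_density`-quasi-biclique. We deliberately do
   not prune to a strict local density maximum: that collapses the broad
   quasi-biclique of a real repeat family — partially overlapping reads
   from slightly divergent copies — into a tiny perfect biclique whose
   assembled chain falls under the minimum reported length.
4. **Accept** the cluster if it meets the size minima (`min_kmers` >= 5,
   `min_reads` >= 10 by default) and remove its edges; clusters are
   therefore edge-disjoint. Every k-mer examined during a growth, whether
   kept or not, is excluded from later seeding and candidacy, so each
   dense region is explored once and the search is near-linear in graph
   size. Rounds stop when no unexamined k-mer has degree at least
   `ceil(min_density * min_reads)` — any acceptable cluster must contain
   such a k-mer, so nothing findable remains.

All tie-breaks are lexicographic and every sweep's outcome is independent
of iteration order, so the search is bit-reproducible. The procedure is a
greedy heuristic: on small graphs its best cluster is compared against
exhaustive subset enumeration in the test suite and is guaranteed there to
come within a factor of two of the optimum (in practice it recovers
planted bicliques in full).

Search defaults (`min_density` 0.5, `min_kmers` 5, `min_reads` 10,
`max_clusters` 10000) are all CLI-exposed. The density floor of 0.5 lets a
120-bp family be held together by 100-bp reads (a read can contain at most
L - k + 1 of a longer element's k-mers); the size minima suppress chance
clusters from read-to-read overlap at low coverage.

## Chain assembly

Each accepted bicluster's k-mers are assembled over exact (k-1)-overlaps:
both orientations of every member k-mer become nodes of a directed overlap
graph, every maximal non-branching path is emitted, and strand-duplicate
paths are collapsed. Divergent variants branch the graph and yield
separate chains rather than an IUPAC consensus. Chains shorter than
`min_length` (default 30 bp) are discarded. Isolated cycles (possible for
tandem periodicities) are linearized at an arbitrary deterministic entry
point. An optional greedy extension against the full read set is
deliberately not enabled by default; short conservative chains quantify
more reliably than speculative extensions.

Discovery uses a seeded random 10% of the pooled reads by default
(`discovery_fraction`); quantification then maps **all** reads back onto
the discovered library, so the discovery subsample only needs to represent
the repetitive fraction, not every locus.

## Contaminant classification

Highly repetitive reads also arise from chloroplast and mitochondrial
genomes (hundreds of organelle copies per cell) and from technical
artifacts such as sequencing adapters. Each kChain is scored against each
user-supplied reference set by containment: the fraction of the chain's
canonical k-mers (default k = 12) present in the reference's k-mer set.
The chain is assigned the label of the highest-containment index at or
above the threshold (default 0.5), else "nuclear". The nuclear bin feeds
the main analysis; the chloroplast bin can be analyzed as its own
abundance track. Containment with exact k-mers tolerates roughly one
substitution per k bases before dropping below 0.5; strongly divergent
fragments of a contaminant can therefore land in the nuclear bin, but
carry correspondingly little read support and are removed by the
abundance filter (this is exercised in the test suite).

## Abundance quantification and normalization

The abundance of element e in sample s is the **median of per-position
read coverage** over e's sequence, zeros included; the mean is available
as an alternative statistic. Coverage comes either from an external
local-mode aligner via SAM (primary alignments only, M/=/X CIGAR
operations increment depth) or from the built-in mapper: exact seed-k-mer
matching on both strands proposes (reference, diagonal) candidates, each
scored by the best gapless segment under score = matches - mu*mismatches
with mu = min_identity / (1 - min_identity), so a positive-scoring segment
has identity above `min_identity` (default 0.9). Each read contributes to
exactly one reference (best score; ties broken by reference order, then
strand, then offset). The mapper is gapless by design: it serves
substitution-level divergence at desk scale, and production users supply
SAM from any local aligner.

The raw matrix is processed as: filter rows by maximum abundance (strictly
greater than the threshold in at least one sample; defaults 665 for the
kChain track, 150 for known-repeat references, both on the raw coverage
scale), then ln(x + 1) (the pseudo-count keeps zero at zero and is
configurable), then classic quantile normalization (rank each column,
replace each value by the cross-column mean of the values at its rank,
ties receiving the mean of their tied-rank targets; afterwards all columns
share one sorted vector, and re-application is a no-op). A flag moves the
filter after normalization instead; the raw-scale default reflects that
coverage thresholds are naturally stated in raw units.

## Ordination and the biplot

PCA treats repeats as observations and samples as variables: the matrix
is column-mean centered and decomposed by exact SVD, X_c = U S V^T.
Components are ordered by decreasing variance; each component's loading
vector is sign-fixed so its largest-magnitude entry is positive, making
the decomposition deterministic. Repeat coordinates are principal
coordinates U S; sample coordinates are the singular-value-scaled loadings
V S, so both live on the same scale and sample-sample distances reflect
covariance structure; the unit-norm loadings V are also exposed for
display. Each repeat is assigned to the species with the highest
replicate-mean abundance (ties to the lexicographically first species;
all-zero rows are flagged). The biplot association statistic is each
repeat's Euclidean distance on the PC1-PC2 plane to the sample centroid of
its assigned species, summarized per species against every species'
centroid; with species-structured abundance the own-species centroid is
the nearest.

## Phylogeny

Sample-by-sample distances over the normalized matrix (Euclidean default;
Manhattan and correlation distance selectable) feed a neighbor-joining
implementation (Saitou-Nei agglomeration with the Q criterion). Pair
selection ties are broken by the smallest leaf labels contained in the
clusters, making the tree deterministic; negative branch-length estimates,
which NJ can produce on non-additive input, are clamped to zero with a
logged count. On additive matrices the algorithm is exact: the output
tree's path-length matrix reproduces the input to numerical precision
(verified to 1e-9 in tests, including against an independent NJ
implementation). Trees are unrooted, carried as dendropy objects, and
serialized as Newick with branch lengths.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:
taxon-specific repeat amplification shared within species groups. Each
species receives one genome — an i.i.d. uniform background into which
copies of shared family consensi are spliced at uniform positions (the
genome length grows by the inserted material; truth intervals delimit each
copy exactly). Copies are mutated independently at a per-copy divergence
rate (default 0.02, a conservatively recent amplification). Reads are
drawn uniformly from both strands at a target depth with independent
per-base substitution errors; replicates of a species share the genome but
not the reads. The generator refuses designs whose inserts exceed half the
background (the analysis targets repeats embedded in a genome, not
near-pure repeat libraries).

Deliberately not modeled: indels, quality-score profiles, TE nesting and
LTR structure, tandem higher-order repeats, GC bias. None of the pipeline's
defined computations depend on these, so passing tests demonstrate
correctness of the graph/coverage/normalization machinery on
substitution-level divergence — not robustness to the full complexity of
real plant repeatomes.

### The reference study

Tests and `scripts/acceptance.py` use one fixed study: 4 species (A-D) x 3
replicates, 100-kb backgrounds, 100-bp reads at 20x, 0.5% sequencing
error; three 120-bp nuclear families with hierarchical sharing — famAB
{A:300, B:150}, famABC {A:50, B:100, C:300}, famD {D:300} — plus one
120-bp chloroplast-like family at 50 copies in every species, whose
consensus doubles as the contaminant reference. Every family reaches 300
copies in at least one species; insert totals stay below half the
background. At these sizes the full pipeline runs in a few minutes on one
CPU, which is the intended desk scale; per-sample pool coverage is high
enough (~6x) that background loci recur in the discovery pool, so the
search must — and does — separate true multi-copy families from
single-locus read pileups (the latter fail the size minima or die at the
abundance filter).

## Numerical and degenerate-input choices

* `subsample_reads` visits reads in a seeded random permutation and skips
  any read that would push the total past the target: exact for
  equal-length reads, within one read length otherwise; per-seed
  deterministic, exchangeable across seeds.
* Quantile normalization accepts an already-normalized matrix (it is a
  no-op there); all other state transitions are strictly raw -> log ->
  quantile_normalized.
* PCA refuses constant matrices (no variance) and component counts above
  min(rows, cols).
* NJ handles n = 2 (single edge split evenly) and n = 3 (closed-form star)
  explicitly.
* The SAM reader validates header lengths against the caller's reference
  map and rejects alignments running past the reference end, naming the
  record.
* All pipeline randomness (subsampling, discovery) flows from the single
  config seed; reruns are byte-identical.

## Known limitations

* The biclustering is a heuristic; no global optimality is claimed, and
  raising `min_density` can re-partition rather than strictly shrink the
  cluster set.
* The built-in mapper is gapless; indel-rich divergence requires external
  SAM input.
* Chains are conservative fragments of the underlying element (typically
  the well-supported core of the consensus), not full-length repeat
  models; downstream abundance comparisons are unaffected because all
  samples are quantified against the same chains.
* Abundance-based phylogeny is a phenetic signal, not a substitution
  model; the NJ tree over samples is exact for the distances given, but
  the distances themselves are only as meaningful as the normalized
  abundance profiles.
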