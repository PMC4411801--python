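# Methods

This note documents the models, parameter choices and numerical decisions
behind estuarybin, stage by stage, and what the synthetic-community tests do
and do not demonstrate about real sediment metagenomes.

## Synthetic communities

Artificial genomes are order-3 Markov chains over ACGT: the minimal
generative model whose genomes differ in tetranucleotide composition, which
is precisely the signal tetranucleotide binning exploits. Each genome's
transition table is a mixture

    table_g = (1 - divergence) · base + divergence · perturb_g

of a shared base table and a per-genome perturbation, both drawn row-wise
from a flat Dirichlet. `divergence` therefore tunes compositional
separability continuously: 0 makes all genomes statistically identical, 1
makes them independent. Mean inter-genome tetramer distance is monotone in
`divergence` (property-tested at 0, 0.3, 0.7, 1.0).

Single-copy markers are literal 300-nt random tags (default M = 104, the
first 16 named after the ribosomal-protein set), mutually non-matching at
k = 21, written once each into the genome at non-overlapping uniform
positions (in place, so genome length is preserved). This lets marker
detection work by exact k-mer containment, with no gene calling or HMM
machinery, while still exercising the completeness/redundancy estimators
downstream.

Genomes are sheared into contigs with log-normal lengths (default log-mean
ln 20 000, log-sd 0.5, minimum 1 kb); the contigs tile the genome exactly,
so base counts are conserved and every contig has exactly one genome of
origin. Reads are error-free substrings (half reverse-complemented),
sampled proportional to `abundance × genome length` per library;
per-library abundances default to Dirichlet draws, or are set explicitly
when a study condition requires a specific contrast. Base qualities follow
a two-state model (good ≈ Q35, bad ≈ Q12, geometric run lengths of mean
50 and 10) — enough structure to exercise windowed trimming. Configured
read fractions are corrupted to violate each QC rule (≥ 3 N's; mean
quality < 20; length < 50).

All randomness flows from one community seed through named sub-seeds
(`crc32(stage) XOR seed`), so each stage is reproducible in isolation and
every output is a pure function of (config, seed).

**What the generator does not emulate:** sequencing errors, indels,
paired-end inserts, strain microdiversity, repeats shared between genomes
(other than the planted markers), and uneven GC-dependent coverage.
Passing tests on these communities show the pipeline's machinery is
correct and that its decision rules behave as specified under the model's
assumptions — not that real estuarine assemblies, with chimeras, strain
clouds and conserved-gene fragmentation, will bin equally cleanly.

## Read QC

Rules: artifact screening by exact 28-mer identity (step 1) against the
artifact set and its reverse complements (implemented as canonical-k-mer
matching, which is equivalent); removal at ≥ 3 N's, mean quality < Q20, or
length < 50 bp; then two-sided quality trimming at cutoff 5; then the
length rule is re-checked (trimming can shorten a read below 50 bp).

The trimmer is a windowed scan with window = max(1, ⌊0.1·len⌋): from each
end, the retained interval begins in the first window whose mean quality
reaches the cutoff, refined to the first base at or above the cutoff inside
that window. The refinement step is how windowed trimmers conventionally
behave and is required for a low-quality flank shorter than the window to
be clipped at all; without it a 3-base Q2 flank in front of a Q30 read
would survive (the window mean passes immediately). The window fraction and
cutoff are configurable.

The mean-quality rule is evaluated before trimming (the screening/removal
stage precedes trimming in the pipeline); whether to re-evaluate it on the
trimmed read is a genuine ambiguity, and the post-trim re-check covers only
length.

## Tetranucleotide signatures

Contigs shorter than 2 500 bp are not fragmented; fragments are consecutive
5-kb windows, with a terminal remainder kept as its own fragment iff
≥ 2 500 bp (half the window) and merged into the previous window otherwise.
Halving is the least-surprising default for both thresholds and both are
configurable.

Signatures are canonical (strand-collapsed) tetramer frequencies over all
overlapping windows: 136 classes — (256 − 16)/2 strand pairs plus 16
palindromes — because contig orientation is arbitrary and the signature
must not depend on it. Windows containing non-ACGT bases are skipped. A raw
256-class mode exists for comparison with older pipelines that did not
collapse strands.

Features are normalized per column by robust z-score, (x − median)/MAD.
The MAD of a sparse column (a rare tetramer class that is zero in most
fragments) is 0; dividing by a tiny floor would inflate occasional nonzero
frequencies by many orders of magnitude and destroy SOM training, so the
scale falls back to the standard deviation when the MAD is degenerate, and
to 1 for a truly constant column (which then maps to exact zeros). The
stored location/scale make the transform invertible.

## ESOM and delineation

The map is an emergent SOM: at least 5 neurons per fragment, never smaller
than 50 × 80, in an approximately golden-ratio rectangle, with toroidal
topology so no neuron is privileged by a boundary. Training is online:
per epoch the fragments are presented in seeded random order, the winner is
the Euclidean-nearest neuron, and weights move by a Gaussian neighbourhood
kernel on the torus with learning rate 0.5 → 0.05 and radius
(grid diagonal)/4 → 1, both decaying exponentially over 20 epochs
(updates beyond 3σ are skipped as negligible). Weights are initialized from
randomly drawn data rows plus 1% jitter. These hyperparameters are
defaults, reported in output headers, and configurable; training is
deterministic given the seed.

Cluster delineation automates what was historically done by hand on the
U-matrix image: neurons at or below the `boundary_quantile` (default 0.7)
quantile of U form basins; toroidal 8-connected components of basins are
clusters; a fragment whose best-matching unit sits on a ridge attaches to
the nearest basin by toroidal grid distance, with exact ties left
unassigned. 8-connectivity is used for both the U-matrix neighbourhood and
the components, for consistency. An import path accepts externally drawn
fragment→cluster maps (validated for full coverage) so manually curated
maps remain usable.

## Coverage

Read recruitment is best-hit canonical 21-mer containment: a read is
assigned to the contig sharing the largest fraction of its distinct
canonical 21-mers, if that fraction is ≥ 0.6; ties go to the
lexicographically smallest contig id and each read counts once. This is a
deterministic, self-contained stand-in for alignment-based recruitment,
adequate for error-free synthetic reads; the 0.6 threshold is calibrated
only for such reads, and real-data workflows can instead supply external
per-contig count tables. Normalized depth is
`count · mean_read_length / contig_length`, scaled per million library
reads, so libraries of different size are comparable.

Chimera screening flags non-terminal 500-bp windows whose mean depth falls
below 0.2 × the contig's median depth (adjacent flags merge); terminal
windows are exempt because depth ramps down at contig ends for purely
geometric reasons.

When coverage joins the tetra features, the per-library log1p-depth columns
are z-scored with mean and standard deviation — not robustly: across a
community worth binning, depth is multi-modal by construction, and the MAD
of a near-50/50 bimodal column is degenerate (its value depends on which
mode the median lands in). The block is then scaled by
`coverage_weight · sqrt(n_tetra / n_libraries)` so that at the default
weight 1.0 the few coverage columns carry aggregate scale comparable to the
136 tetra columns; without this, two unit-variance coverage columns are
drowned by tetra noise and compositionally identical genomes cannot be
rescued by depth at all.

## Binning rules

Contigs above 15 kb take the plurality label of their fragments, with
plurality ties unassigned. The conservative closure for shorter contigs is
unanimity (any disagreement, including an unlabelled fragment, leaves the
contig unassigned); a plurality mode is available. GC curation is advisory:
contigs whose GC deviates from the bin median by more than 3 robust
deviations (MAD floor 0.005) are flagged, not dropped, and bins with fewer
than 5 contigs are not evaluated.

Multi-genome splitting fits Gaussian mixtures with k = 1..5 full-covariance
components to per-contig (log1p depth_lib1, log1p depth_lib2), selects k by
BIC, and accepts the split only if every sub-bin is non-empty and reduces
the duplicated-marker fraction strictly below the parent's; otherwise the
parent is returned unchanged with the reason logged. The library pair must
be named explicitly (which pair best separates a given merged bin is
data-dependent).

## Quality metrics

Completeness = 100 · (markers present ≥ once)/M; redundancy =
100 · Σ max(count − 1, 0)/M. These are deliberately simple universal-set
analogues of lineage-aware tools: they reproduce the quantity "fraction of
single-copy genes present/duplicated" without taxonomic weighting, and the
redundancy metric is documented as such, not as a contamination clone.
A bin is flagged multi-genome when strictly more than 10% of its present
markers are duplicated — a threshold chosen so that merged genome pairs
(duplication ≈ 100%) are flagged robustly while sporadic duplications from
split or repeated loci are not; it is configurable.

Marker detection on synthetic data counts a copy per maximal run of marker
31-mer hits on a contig (runs closer than 200 bp merge) recovering ≥ 90% of
the marker's k-mers. A marker split by a contig boundary is usually lost to
both pieces; at the default contig lengths this costs 1–3% of markers,
visible as a small negative bias in the completeness-recovery benchmark and
well inside its tolerance. Real-data workflows bypass detection entirely by
supplying a hit table.

rpS3 community profiles recruit reads to a set of labelled rpS3 genes with
the same containment rule and normalize per library to proportions. GH
profiling counts annotation rows whose family is on a degradation-relevant
include list (the shipped default list covers cellulases, hemicellulases,
chitinases, amylases and related hydrolase families and is meant to be
edited); excluded and malformed rows are tallied in a drop report so that
counted + dropped = parsed.

## Phylogeny

Taxa with fewer than half of the 16 ribosomal-protein genes (i.e. < 8) are
excluded; missing genes are gap-filled in the concatenation and partition
boundaries recorded. Distances use Jukes–Cantor generalized to n states
(default 20 for amino-acid alignments; 4-state mode for nucleotides):
d = −((n−1)/n)·ln(1 − (n/(n−1))·p) with p the mismatch fraction under
pairwise gap deletion. Pairwise (not complete) deletion keeps heavily
gapped concatenations comparable; pairs with no shared ungapped column, or
with p within 0.1% of the (n−1)/n ceiling, are errors rather than numbers.

UPGMA merges the closest pair with size-weighted average linkage; node
height is half the merge distance, so the tree is rooted and ultrametric.
Neighbor joining follows the standard Q-criterion and returns an unrooted
tree (serialized with a trifurcating root); negative branch lengths are
clamped to zero with a log note. Both builders break ties by the
lexicographically smallest pair of cluster labels, making topologies
deterministic. Bootstrap resamples alignment columns with replacement,
rebuilds with the same builder, and annotates each internal node of the
reference tree with the percentage of replicates containing the same leaf
bipartition; replicates that produce an incomparable pair are dropped and
counted, and more than 20% dropped is an error. Maximum-likelihood
inference is intentionally out of scope; the distance machinery here is the
bootstrap machinery, and published ML topologies are not reproduced by it.

Newick output carries branch lengths at 6 significant figures and integer
supports as internal labels; names containing metacharacters are quoted.

## Pipeline

The `run` pipeline executes qc → fragments/tetra → coverage → SOM →
binning → assessment (optionally refinement) from one YAML config and one
global seed, writing TSV intermediates with provenance headers (tool
version, stage, seed, parameters) and a JSON manifest of SHA-256 digests
for every file consumed and produced. A stage re-runs only when its
recorded parameters or input/output digests no longer match, so a corrupted
intermediate forces recomputation of exactly the affected stages. Two runs
with the same config and seed are bitwise identical (tested).

## Benchmark problem sizes

The reference evaluations run at desk scale on one CPU: the eight-genome
recovery condition uses 260-kb genomes (52 fragments each) and two
416 000-read libraries (~20× depth per library); the coverage-rescue
condition uses two 250-kb genomes with a 10:1/1:10 abundance contrast and
100 000 reads per library; completeness recovery uses 600-kb genomes cut
into ~10-kb contigs, 10 replicate genomes per retention fraction; the
split fixture uses two 200-kb genomes at (10, 2)/(2, 10) expected depths.
These sizes preserve the stated fragment counts, depths and divergences of
the conditions they instantiate while keeping the full suite within a few
minutes.

## Known limitations

- Recruitment is exact-k-mer based and will under-recruit error-containing
  or diverged reads; the BLAST-like sensitivity of alignment recruitment is
  not reproduced.
- U-matrix basin delineation depends on the boundary quantile: maps with
  very few clusters have broad smooth regions and may need a lower
  quantile, and the automated components will never reproduce every
  judgment call of manual curation.
- Completeness/redundancy use one universal marker set; lineage-specific
  marker sets would be more sensitive for lineages with reduced genomes.
- The UPGMA bootstrap assumes rate constancy (ultrametricity); NJ relaxes
  this but supports are still distance-based.
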