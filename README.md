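# estuarybin

Genome reconstruction from sediment metagenomes: tetranucleotide-signature
binning on emergent self-organizing maps (ESOM), enhanced with per-library
coverage signatures, with marker-based bin quality assessment,
differential-coverage refinement of merged bins, rpS3 community profiling,
GH-family functional tabulation, and concatenated ribosomal-protein
phylogenies.

It is aimed at microbial ecologists recovering population genomes from
assembled shotgun metagenomes of stratified environments (e.g. estuarine
sediments sampled across redox zones), where most of the community belongs
to uncultured lineages and genomes must be binned from contigs without
references.

## The method

1. **Read QC** — reads are screened against sequencing artifacts by exact
   28-mer matching (either strand), removed if they carry ≥ 3 N's, mean
   quality < Q20 or length < 50 bp, and trimmed from both ends at a minimum
   quality cutoff of 5 with a sliding-window scan.
2. **Tetranucleotide signatures** — contigs ≥ 2.5 kb are cut into 5-kb
   fragments; each fragment gets a 136-dimensional canonical tetramer
   frequency vector *f*(w), w a strand-collapsed 4-mer class. Genomes differ
   in these signatures, which is the binning signal.
3. **Coverage signatures** — reads of each library are recruited to contigs
   by canonical 21-mer containment (best hit, ≥ 60% of the read's k-mers);
   depth is normalized as `count · read_length / contig_length` per million
   library reads. Differential depth across libraries separates genomes that
   composition cannot.
4. **ESOM binning** — a large toroidal SOM (≥ 5 neurons per fragment,
   minimum 50 × 80) is trained online on the joint feature matrix; the
   U-matrix (mean distance of each neuron to its 8 toroidal neighbours)
   exposes clusters as valleys. Basins below a U-quantile threshold are
   extracted as connected components and fragments inherit their
   best-matching unit's basin.
5. **Contig assignment** — contigs > 15 kb take the majority label of their
   5-kb fragments; shorter contigs require unanimity. GC outliers within a
   bin are flagged for curation.
6. **Quality** — completeness = % of a universal single-copy marker set
   present; redundancy = % of surplus marker copies; bins whose detected
   markers are > 10% duplicated are flagged as multi-genome and split on
   per-contig differential coverage between two libraries (BIC-selected
   Gaussian mixture, accepted only if duplication drops in every sub-bin).
7. **Phylogeny** — per-gene alignments of 16 syntenic ribosomal proteins
   (rpL2, 3, 4, 5, 6, 14, 15, 16, 18, 22, 24; rpS3, 8, 10, 17, 19) are
   concatenated (taxa with < 50% of the genes dropped), distances computed
   under Jukes–Cantor generalized to 20 states,
   `d = -(19/20)·ln(1 - (20/19)·p)`, and trees built by UPGMA or neighbor
   joining with column-bootstrap supports (100 replicates), written as
   Newick.

A synthetic-community generator (order-3 Markov genomes with controllable
compositional divergence, planted single-copy marker tags, log-normal contig
shearing, per-library abundances and QC-violating read fractions) provides
ground truth for every stage.

## Worked example

Simulate a four-genome community and run the pipeline end to end:

```python
from estuarybin.pipeline import PipelineConfig, run_pipeline
import pandas as pd

cfg = PipelineConfig(
    out_dir="demo_out", seed=7,
    simulate=dict(n_genomes=4, genome_length=120_000, divergence=0.4,
                  reads_per_library=48_000, n_markers=104),
)
run_pipeline(cfg)
print(pd.read_csv("demo_out/bin_quality.tsv", sep="\t", comment="#", index_col=0))
```

which prints

```
        completeness  redundancy  multi_genome
bin_id
cl_001     99.038462           0         False
cl_002     98.076923           0         False
cl_003    100.000000           0         False
cl_004     98.076923           0         False
```

Four bins are recovered, one per simulated genome; each contains 98–100% of
the 104 planted single-copy markers with zero redundancy, i.e. the bins are
essentially complete and uncontaminated. The bin summary confirms each bin
holds exactly one genome's 120,000 bp:

```
        n_contigs  total_bp    n50    gc  mean_cov_lib1  mean_cov_lib2
bin_id
cl_001          7    120000  19776  0.52         347.90          82.94
cl_002          5    120000  28580  0.53         269.35         103.57
cl_003          4    120000  31549  0.51         194.23         326.80
cl_004          5    120000  27054  0.52          19.40         317.57
```

The same stages are available as subcommands of the `estuarybin` CLI
(`simulate`, `qc`, `tetra`, `coverage`, `som`, `bin`, `refine`, `assess`,
`profile`, `tree`, `run`).

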