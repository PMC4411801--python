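"""Synthetic metagenome communities with known truth.

Every downstream stage of the pipeline is tested against communities built
here: artificial genomes drawn from order-3 Markov chains (the minimal model
whose genomes differ in tetranucleotide composition — exactly the signal the
binning exploits), with literal single-copy marker tags planted once each,
sheared into contigs, and sequenced into per-library reads whose abundances,
quality structure and QC-violating fractions are all configurable.

All randomness flows from the community seed through named sub-seeds
(:func:`estuarybin._seeds.derive_seed`), so each stage is individually
reproducible and outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_seed
from .markers import MarkerCatalog, make_default_catalog

__all__ = [
    "GenomeModel",
    "CommunityConfig",
    "TruthTable",
    "Community",
    "build_transition_tables",
    "sample_genome",
    "plant_markers",
    "shear_into_contigs",
    "simulate_reads",
    "simulate_community",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GenomeModel:
    """An artificial genome: an order-``order`` Markov chain over ACGT.

    ``transition`` has shape ``(4**order, 4)``; row ``c`` is the conditional
    distribution of the next base given context code ``c`` (bases packed
    2 bits each, most significant = oldest).
    """

    genome_id: str
    length_bp: int
    transition: np.ndarray
    order: int = 3
    marker_loci: list[tuple[str, int, int]] = field(default_factory=list)

    def validate(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if self.transition.shape != (4**self.order, 4):
            raise ValueError("transition table has wrong shape")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        prev_end = -1
        for _mid, start, end in sorted(self.marker_loci, key=lambda t: t[1]):
            if start < 0 or end > self.length_bp or start >= end:
                raise ValueError("marker locus outside genome")
            if start < prev_end:
                raise ValueError("marker loci overlap")
            prev_end = end


@dataclass
class CommunityConfig:
    """Parameters of a simulated community.

    ``abundances`` maps library id to a per-genome relative-abundance vector
    (each sums to 1). ``qc_violation_rates`` are the fractions of reads per
    library corrupted to violate, respectively, the N-count rule (>=3 N's),
    the mean-quality rule (mean Q < 20) and the length rule (< 50 bp).
    """

    n_genomes: int = 8
    genome_length: int = 300_000
    divergence: float = 0.3
    order: int = 3
    libraries: tuple[str, ...] = ("lib1", "lib2")
    abundances: dict[str, np.ndarray] | None = None
    read_length: int = 100
    reads_per_library: int = 480_000
    qc_violation_rates: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_markers: int = 104
    marker_length: int = 300
    contig_log_mean: float = float(np.log(20_000.0))
    contig_log_sd: float = 0.5
    min_contig_len: int = 1_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must lie in [0, 1]")
        for r in self.qc_violation_rates:
            if not 0.0 <= r <= 1.0:
                raise ValueError("qc violation rates must lie in [0, 1]")
        if self.reads_per_library <= 0:
            raise ValueError("reads_per_library must be positive")
        if self.abundances is not None:
            for lib, vec in self.abundances.items():
                v = np.asarray(vec, dtype=float)
                if v.shape != (self.n_genomes,):
                    raise ValueError(f"abundance vector for {lib} has wrong size")
                if abs(v.sum() - 1.0) > 1e-9 or (v < 0).any():
                    raise ValueError(f"abundances for {lib} must be a probability vector")


@dataclass
class TruthTable:
    """Ground truth emitted alongside a community."""

    contig_to_genome: dict[str, str]
    fragment_to_genome: dict[str, str] = field(default_factory=dict)
    #: (marker_id, contig_id, start, end), 0-based half-open, contig coords
    marker_loci: list[tuple[str, str, int, int]] = field(default_factory=list)
    #: library -> genome_id -> expected mean depth
    expected_depth: dict[str, dict[str, float]] = field(default_factory=dict)
    #: library -> genome index per read, aligned with emitted read order
    read_genome: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class Community:
    """A fully realized synthetic community."""

    config: CommunityConfig
    genomes: list[GenomeModel]
    genome_sequences: dict[str, str]
    contigs: dict[str, str]  # contig_id -> sequence, insertion-ordered
    reads: dict[str, list[tuple[str, str, np.ndarray]]]  # lib -> [(id, bases, quals)]
    truth: TruthTable
    catalog: MarkerCatalog

    def write_contigs_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for cid, seq in self.contigs.items():
                fh.write(f">{cid}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def write_reads_fastq(self, library: str, path) -> None:
        with open(path, "w") as fh:
            for rid, bases, quals in self.reads[library]:
                q = "".join(chr(33 + int(x)) for x in quals)
                fh.write(f"@{rid}\n{bases}\n+\n{q}\n")

    def write_truth_tsv(self, contig_path, marker_path) -> None:
        with open(contig_path, "w") as fh:
            fh.write("contig_id\tgenome_id\n")
            for cid, gid in self.truth.contig_to_genome.items():
                fh.write(f"{cid}\t{gid}\n")
        with open(marker_path, "w") as fh:
            fh.write("marker_id\tcontig_id\tstart\tend\n")
            for mid, cid, s, e in self.truth.marker_loci:
                fh.write(f"{mid}\t{cid}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# generators


def build_transition_tables(
    n_genomes: int,
    divergence: float,
    seed: int,
    order: int = 3,
) -> list[np.ndarray]:
    """Per-genome transition tables mixing a shared base with perturbations.

    ``table_g = (1 - divergence) * base + divergence * perturb_g`` with the
    base table and each genome's perturbation drawn row-wise from a flat
    Dirichlet; rows are renormalized. ``divergence=0`` makes all genomes
    compositionally identical; ``divergence=1`` makes them independent.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    n_ctx = 4**order
    base_rng = np.random.default_rng(derive_seed(seed, "base_table"))
    base = base_rng.dirichlet(np.ones(4), size=n_ctx)
    tables = []
    for g in range(n_genomes):
        rng = np.random.default_rng(derive_seed(seed, f"perturb_table:{g}"))
        perturb = rng.dirichlet(np.ones(4), size=n_ctx)
        tab = (1.0 - divergence) * base + divergence * perturb
        tab /= tab.sum(axis=1, keepdims=True)
        tables.append(tab)
    return tables


def sample_genome(model: GenomeModel, seed: int) -> str:
    """Draw one sequence from the genome's Markov chain.

    The first ``order`` bases are uniform; each subsequent base is sampled
    from the transition row of the current context.
    """
    model.validate()
    rng = np.random.default_rng(derive_seed(seed, f"genome:{model.genome_id}"))
    n, order = model.length_bp, model.order
    out = np.empty(n, dtype=np.uint8)
    prefix = rng.integers(0, 4, size=min(order, n))
    out[: prefix.size] = prefix
    if n > order:
        # cumulative rows let the inner loop be three comparisons per base
        cum = np.cumsum(model.transition, axis=1)
        c0, c1, c2 = cum[:, 0].tolist(), cum[:, 1].tolist(), cum[:, 2].tolist()
        u = rng.random(n)
        mask = 4**order - 1
        ctx = 0
        for b in prefix:
            ctx = ((ctx << 2) | int(b)) & mask
        ob = out
        for i in range(order, n):
            ui = u[i]
            if ui < c0[ctx]:
                b = 0
            elif ui < c1[ctx]:
                b = 1
            elif ui < c2[ctx]:
                b = 2
            else:
                b = 3
            ob[i] = b
            ctx = ((ctx << 2) | b) & mask
    return _BASES[out].tobytes().decode("ascii")


def plant_markers(
    sequence: str,
    catalog: MarkerCatalog,
    seed: int,
) -> tuple[str, list[tuple[str, int, int]]]:
    """Write each marker tag once into the sequence at a random position.

    Positions are drawn uniformly and rejected until non-overlapping; each
    tag replaces the resident bases in place, so the genome length is
    unchanged. Returns the modified sequence and sorted loci.
    """
    if len(catalog) == 0:
        return sequence, []
    lens = [len(s) for s in catalog.sequences.values()]
    if sum(lens) > len(sequence):
        raise ValueError("genome too short to host all markers")
    rng = np.random.default_rng(derive_seed(seed, "plant_markers"))
    occupied: list[tuple[int, int]] = []
    loci: list[tuple[str, int, int]] = []
    buf = bytearray(sequence, "ascii")
    for mid, mseq in catalog.sequences.items():
        L = len(mseq)
        for _attempt in range(10_000):
            start = int(rng.integers(0, len(sequence) - L + 1))
            end = start + L
            if all(end <= s or start >= e for s, e in occupied):
                break
        else:
            raise ValueError("genome too short to place markers without overlap")
        occupied.append((start, end))
        buf[start:end] = mseq.encode("ascii")
        loci.append((mid, start, end))
    loci.sort(key=lambda t: t[1])
    return buf.decode("ascii"), loci


def shear_into_contigs(
    sequence: str,
    length_log_mean: float,
    length_log_sd: float,
    min_len: int,
    seed: int,
) -> list[tuple[int, int]]:
    """Partition a genome into contig intervals with log-normal lengths.

    Returns 0-based half-open ``(start, end)`` intervals that tile the
    sequence exactly. A terminal remainder shorter than ``min_len`` is merged
    into the previous contig.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    rng = np.random.default_rng(derive_seed(seed, "shear"))
    n = len(sequence)
    cuts = [0]
    while cuts[-1] < n:
        step = max(min_len, int(round(rng.lognormal(length_log_mean, length_log_sd))))
        cuts.append(min(n, cuts[-1] + step))
    if len(cuts) > 2 and cuts[-1] - cuts[-2] < min_len:
        del cuts[-2]
    return list(zip(cuts[:-1], cuts[1:]))


def _two_state_qualities(rng, n_reads: int, length: int) -> np.ndarray:
    """Two-state quality model: good runs near Q35, bad runs near Q12, with
    geometric run lengths (mean 50 good / 10 bad)."""
    p_gb, p_bg = 1.0 / 50.0, 1.0 / 10.0
    states = np.empty((n_reads, length), dtype=bool)  # True = good
    states[:, 0] = rng.random(n_reads) < 0.9
    u = rng.random((n_reads, length - 1))
    for j in range(1, length):
        prev = states[:, j - 1]
        flip = np.where(prev, u[:, j - 1] < p_gb, u[:, j - 1] >= p_bg)
        states[:, j] = prev ^ flip
    jitter = rng.integers(-2, 3, size=(n_reads, length))
    quals = np.where(states, 35, 12) + jitter
    return np.clip(quals, 2, 41).astype(np.int16)


def simulate_reads(
    genome_sequences: dict[str, str],
    config: CommunityConfig,
) -> tuple[dict[str, list[tuple[str, str, np.ndarray]]], dict[str, np.ndarray], dict[str, dict[str, float]]]:
    """Simulate one read set per library.

    Reads are error-free substrings of the genomes (half reverse-complemented)
    sampled proportional to ``abundance * genome_length``, with qualities from
    the two-state model. The configured fractions of reads are then corrupted
    to violate each QC rule. Returns ``(reads, read_genome, expected_depth)``.
    """
    config.validate()
    gids = list(genome_sequences)
    glens = np.array([len(genome_sequences[g]) for g in gids], dtype=float)
    L = config.read_length
    reads: dict[str, list[tuple[str, str, np.ndarray]]] = {}
    read_genome: dict[str, np.ndarray] = {}
    expected_depth: dict[str, dict[str, float]] = {}
    comp = str.maketrans("ACGTN", "TGCAN")
    for lib in config.libraries:
        if config.abundances is not None:
            ab = np.asarray(config.abundances[lib], dtype=float)
        else:
            ab_rng = np.random.default_rng(derive_seed(config.seed, f"abundance:{lib}"))
            ab = ab_rng.dirichlet(np.ones(len(gids)))
        w = ab * glens
        w /= w.sum()
        rng = np.random.default_rng(derive_seed(config.seed, f"reads:{lib}"))
        n = config.reads_per_library
        gidx = rng.choice(len(gids), size=n, p=w)
        starts = (rng.random(n) * (glens[gidx] - L)).astype(np.int64)
        flip = rng.random(n) < 0.5
        quals = _two_state_qualities(rng, n, L)

        frac_n, frac_lowq, frac_short = config.qc_violation_rates
        perm = rng.permutation(n)
        n_n = int(round(frac_n * n))
        n_q = int(round(frac_lowq * n))
        n_s = int(round(frac_short * n))
        idx_n = set(perm[:n_n].tolist())
        idx_q = set(perm[n_n : n_n + n_q].tolist())
        idx_s = set(perm[n_n + n_q : n_n + n_q + n_s].tolist())

        out = []
        for i in range(n):
            g = gids[int(gidx[i])]
            s = int(starts[i])
            bases = genome_sequences[g][s : s + L]
            if flip[i]:
                bases = bases.translate(comp)[::-1]
            q = quals[i]
            if i in idx_n:
                pos = rng.choice(L, size=3, replace=False)
                b = bytearray(bases, "ascii")
                for p in pos:
                    b[p] = ord("N")
                bases = b.decode("ascii")
            elif i in idx_q:
                q = np.clip(rng.integers(5, 18, size=L), 2, 41).astype(np.int16)
            elif i in idx_s:
                short = int(rng.integers(20, 50))
                bases, q = bases[:short], q[:short]
            out.append((f"{lib}_r{i:07d}", bases, q))
        reads[lib] = out
        read_genome[lib] = gidx
        expected_depth[lib] = {
            g: float(n * w[j] * L / glens[j]) for j, g in enumerate(gids)
        }
    return reads, read_genome, expected_depth


def simulate_community(config: CommunityConfig) -> Community:
    """Run the full generator: tables -> genomes -> markers -> contigs -> reads."""
    config.validate()
    tables = build_transition_tables(
        config.n_genomes, config.divergence, config.seed, order=config.order
    )
    catalog = (
        make_default_catalog(config.n_markers, config.marker_length, seed=config.seed)
        if config.n_markers > 0
        else MarkerCatalog()
    )
    genomes: list[GenomeModel] = []
    genome_sequences: dict[str, str] = {}
    contigs: dict[str, str] = {}
    truth = TruthTable(contig_to_genome={})
    for g in range(config.n_genomes):
        gid = f"g{g + 1:02d}"
        model = GenomeModel(
            genome_id=gid, length_bp=config.genome_length,
            transition=tables[g], order=config.order,
        )
        seq = sample_genome(model, config.seed)
        seq, loci = plant_markers(seq, catalog, derive_seed(config.seed, gid))
        model.marker_loci = loci
        genomes.append(model)
        genome_sequences[gid] = seq
        intervals = shear_into_contigs(
            seq, config.contig_log_mean, config.contig_log_sd,
            config.min_contig_len, derive_seed(config.seed, f"shear:{gid}"),
        )
        contig_bounds = []
        for ci, (s, e) in enumerate(intervals):
            cid = f"{gid}_c{ci + 1:04d}"
            contigs[cid] = seq[s:e]
            truth.contig_to_genome[cid] = gid
            contig_bounds.append((cid, s, e))
        # markers intersected with contig intervals (contig coordinates)
        for mid, ms, me in loci:
            for cid, s, e in contig_bounds:
                os_, oe = max(ms, s), min(me, e)
                if os_ < oe:
                    truth.marker_loci.append((mid, cid, os_ - s, oe - s))
    reads, read_genome, expected_depth = simulate_reads(genome_sequences, config)
    truth.read_genome = read_genome
    truth.expected_depth = expected_depth
    return Community(
        config=config, genomes=genomes, genome_sequences=genome_sequences,
        contigs=contigs, reads=reads, truth=truth, catalog=catalog,
    )
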