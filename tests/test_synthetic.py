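"""Generator correctness: mixing identities, chain statistics, conservation."""

import numpy as np
import pytest

from estuarybin.markers import make_default_catalog
from estuarybin.signatures import tetra_frequencies
from estuarybin.synthetic import (
    CommunityConfig,
    GenomeModel,
    build_transition_tables,
    plant_markers,
    sample_genome,
    shear_into_contigs,
    simulate_community,
    simulate_reads,
)
from estuarybin.qc import QCParams, ReadRecord, run_qc


def _mean_tv(t1: np.ndarray, t2: np.ndarray) -> float:
    return float(0.5 * np.abs(t1 - t2).sum(axis=1).mean())


class TestTransitionTables:
    def test_zero_divergence_collapses_to_base(self):
        tables = build_transition_tables(4, 0.0, seed=7)
        for t in tables[1:]:
            np.testing.assert_allclose(t, tables[0], atol=1e-12)

    def test_full_divergence_tables_distinct(self):
        tables = build_transition_tables(4, 1.0, seed=7)
        for i in range(4):
            for j in range(i + 1, 4):
                assert _mean_tv(tables[i], tables[j]) > 0.05

    def test_divergence_monotone_between_endpoints(self):
        tvs = {
            d: _mean_tv(*build_transition_tables(2, d, seed=3))
            for d in (0.0, 0.5, 1.0)
        }
        assert tvs[0.0] < tvs[0.5] < tvs[1.0]
        assert tvs[0.0] == 0.0

    def test_rows_are_distributions(self):
        for t in build_transition_tables(3, 0.7, seed=1):
            np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-9)

    def test_divergence_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_transition_tables(2, 1.5, seed=0)


class TestSampleGenome:
    def test_degenerate_chain_emits_all_a(self):
        table = np.zeros((64, 4))
        table[:, 0] = 1.0
        model = GenomeModel("g", 10, table)
        seq = sample_genome(model, seed=0)
        assert seq[3:] == "A" * 7  # after the uniform prefix the chain locks

    def test_determinism(self):
        t = build_transition_tables(1, 0.5, seed=9)[0]
        m = GenomeModel("g", 5000, t)
        assert sample_genome(m, seed=4) == sample_genome(m, seed=4)
        assert sample_genome(m, seed=4) != sample_genome(m, seed=5)

    def test_tetramer_frequencies_match_chain(self):
        """Empirical tetramer distribution of a long sample converges to the
        one implied by the transition table (stationary chain oracle)."""
        t = build_transition_tables(1, 0.8, seed=11)[0]
        m = GenomeModel("g", 500_000, t)
        seq = sample_genome(m, seed=2)
        # oracle: stationary context distribution by power iteration over the
        # 64-state context chain, then P(tetramer) = pi(ctx) * P(base | ctx)
        P = np.zeros((64, 64))
        for ctx in range(64):
            for b in range(4):
                nxt = ((ctx << 2) | b) & 63
                P[ctx, nxt] += t[ctx, b]
        pi = np.full(64, 1 / 64)
        for _ in range(200):
            pi = pi @ P
        expected = np.zeros(256)
        for ctx in range(64):
            for b in range(4):
                expected[(ctx << 2) | b] = pi[ctx] * t[ctx, b]
        empirical = tetra_frequencies(seq, canonical=False).values
        tv = 0.5 * np.abs(expected - empirical).sum()
        assert tv < 0.02


class TestPlantMarkers:
    def test_empty_catalog_is_identity(self):
        from estuarybin.markers import MarkerCatalog

        seq = "ACGT" * 100
        out, loci = plant_markers(seq, MarkerCatalog(), seed=0)
        assert out == seq and loci == []

    def test_loci_non_overlapping_and_roundtrip(self):
        cat = make_default_catalog(104, 300, seed=5)
        t = build_transition_tables(1, 0.5, seed=5)[0]
        seq = sample_genome(GenomeModel("g", 300_000, t), seed=5)
        out, loci = plant_markers(seq, cat, seed=5)
        assert len(out) == len(seq)
        assert len(loci) == 104
        prev_end = -1
        for mid, s, e in loci:
            assert s >= prev_end
            assert out[s:e] == cat.sequences[mid]
            prev_end = e

    def test_too_short_genome_rejected(self):
        cat = make_default_catalog(10, 300, seed=1)
        with pytest.raises(ValueError):
            plant_markers("ACGT" * 100, cat, seed=0)


class TestShear:
    def test_partition_and_conservation(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 57_123))
        iv = shear_into_contigs(seq, np.log(8000), 0.5, 1000, seed=3)
        assert iv[0][0] == 0 and iv[-1][1] == len(seq)
        assert all(a[1] == b[0] for a, b in zip(iv, iv[1:]))
        assert sum(e - s for s, e in iv) == len(seq)
        assert "".join(seq[s:e] for s, e in iv) == seq

    def test_contig_count_near_target(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 1_000_000))
        # lognormal(mean of log 20 kb) => about 50 contigs over 1 Mb
        mu = np.log(20_000) - 0.5 * 0.5**2  # arithmetic mean 20 kb
        iv = shear_into_contigs(seq, mu, 0.5, 1000, seed=7)
        assert 25 <= len(iv) <= 100


class TestSimulateReads:
    def test_clean_config_passes_all_qc(self):
        cfg = CommunityConfig(
            n_genomes=2, genome_length=50_000, reads_per_library=2000,
            n_markers=0, qc_violation_rates=(0.0, 0.0, 0.0), seed=8,
        )
        com = simulate_community(cfg)
        for lib in cfg.libraries:
            reads = [ReadRecord(r, b, q) for r, b, q in com.reads[lib]]
            out, report = run_qc(reads, [], QCParams())
            assert report.n_out == len(reads)

    def test_abundance_proportions_binomial(self):
        cfg = CommunityConfig(
            n_genomes=2, genome_length=50_000, reads_per_library=10_000,
            libraries=("lib1",), n_markers=0,
            abundances={"lib1": np.array([0.8, 0.2])}, seed=12,
        )
        com = simulate_community(cfg)
        n1 = int((com.truth.read_genome["lib1"] == 0).sum())
        sigma = np.sqrt(10_000 * 0.8 * 0.2)
        assert abs(n1 - 8000) <= 3 * sigma

    def test_reads_deterministic_and_conserved(self, tmp_path):
        cfg = CommunityConfig(
            n_genomes=2, genome_length=30_000, reads_per_library=500,
            n_markers=0, qc_violation_rates=(0.1, 0.1, 0.05), seed=4,
        )
        com1 = simulate_community(cfg)
        com2 = simulate_community(cfg)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        com1.write_reads_fastq("lib1", p1)
        com2.write_reads_fastq("lib1", p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert len(com1.reads["lib1"]) == 500
        assert len(com1.reads["lib2"]) == 500

    def test_violation_fractions_planted(self):
        cfg = CommunityConfig(
            n_genomes=1, genome_length=40_000, reads_per_library=1000,
            libraries=("lib1",), n_markers=0,
            qc_violation_rates=(0.1, 0.1, 0.1), seed=6,
        )
        reads, _, _ = simulate_reads(
            {"g01": sample_genome(
                GenomeModel("g01", 40_000, build_transition_tables(1, 0.3, 6)[0]), 6
            )},
            cfg,
        )
        recs = [ReadRecord(r, b, q) for r, b, q in reads["lib1"]]
        n_with_n = sum(1 for r in recs if r.bases.count("N") >= 3)
        n_short = sum(1 for r in recs if len(r.bases) < 50)
        n_lowq = sum(1 for r in recs if len(r.bases) >= 50 and np.mean(r.quals) < 20)
        assert n_with_n == 100
        assert n_short == 100
        assert n_lowq >= 100  # the planted 100 plus rare two-state outliers


class TestCommunityInvariants:
    def test_base_conservation(self, small_community):
        com = small_community
        total_contigs = sum(len(s) for s in com.contigs.values())
        total_genomes = sum(len(s) for s in com.genome_sequences.values())
        assert total_contigs == total_genomes

    def test_every_contig_has_one_genome(self, small_community):
        com = small_community
        assert set(com.contigs) == set(com.truth.contig_to_genome)

    def test_signature_separability_monotone_in_divergence(self):
        """Mean inter-genome tetramer distance grows with divergence."""
        seps = []
        for d in (0.0, 0.3, 0.7, 1.0):
            cfg = CommunityConfig(
                n_genomes=3, genome_length=60_000, divergence=d,
                reads_per_library=10, n_markers=0, seed=21,
            )
            tables = build_transition_tables(3, d, seed=21)
            seqs = [
                sample_genome(GenomeModel(f"g{i}", 60_000, tables[i]), cfg.seed)
                for i in range(3)
            ]
            vecs = [tetra_frequencies(s).values for s in seqs]
            dists = [
                np.abs(vecs[i] - vecs[j]).sum()
                for i in range(3)
                for j in range(i + 1, 3)
            ]
            seps.append(np.mean(dists))
        assert seps[0] < seps[1] < seps[2] < seps[3]
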