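"""Reference evaluations of the pipeline on synthetic study conditions.

Each function sets up a fixed synthetic scenario — the community parameters
are the study conditions and are not tunable here — runs the relevant
pipeline stages end to end, and measures recovery against the generator's
truth tables. They back both the acceptance test suite and the acceptance
script, which only vary the seed.

Problem sizes are chosen for a single-CPU desk run: genomes of a few
hundred kb and hundreds of thousands of reads per library, preserving the
stated fragment counts, depths and divergences.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import binning, esom
from ._seeds import derive_seed
from .coverage import LibraryInfo, normalize_coverage, recruit_reads
from .qc import ReadRecord
from .quality import completeness, detect_markers, flag_multigenome
from .signatures import fragment_contigs, normalize_features, tetra_feature_matrix
from .synthetic import CommunityConfig, simulate_community

__all__ = [
    "binning_recovery",
    "coverage_rescue",
    "completeness_recovery",
    "multigenome_split",
]


def _records(com, lib):
    return [ReadRecord(r, b, q) for r, b, q in com.reads[lib]]


def _coverage_matrix(com):
    reads = {lib: _records(com, lib) for lib in com.config.libraries}
    counts = recruit_reads(com.contigs, reads)
    libs = {
        lib: LibraryInfo(lib, len(rr), float(np.mean([len(x.bases) for x in rr])))
        for lib, rr in reads.items()
    }
    return normalize_coverage(counts, libs, {c: len(s) for c, s in com.contigs.items()})


def _som_clusters(feat, seed):
    rows, cols = esom.default_grid_shape(len(feat.data))
    grid = esom.train(feat, esom.SOMConfig(rows, cols, seed=derive_seed(seed, "som")))
    um = esom.compute_umatrix(grid)
    bmu = esom.assign_bmu(grid, feat)
    return esom.delineate_clusters(um, bmu)


def _ari(truth, clusters, frags):
    pred = [clusters[f.fragment_id] or "unassigned" for f in frags]
    return float(adjusted_rand_score(truth, pred))


def binning_recovery(seed: int = 0) -> dict:
    """Eight order-3 Markov genomes at divergence 0.3, two libraries at
    about 20x depth each, >= 50 fragments per genome: full pipeline
    (signatures + coverage -> ESOM -> delineation -> contig assignment),
    scored as fragment-level ARI against truth and per-bin purity in bp.
    """
    cfg = CommunityConfig(
        n_genomes=8, genome_length=260_000, divergence=0.3,
        reads_per_library=416_000, seed=seed,
    )
    com = simulate_community(cfg)
    frags = fragment_contigs(com.contigs)
    tetra = normalize_features(tetra_feature_matrix(frags))
    cov = _coverage_matrix(com)
    joint = binning.combine_features(tetra, cov, frags)
    clusters = _som_clusters(joint, seed)
    truth = [com.truth.contig_to_genome[f.contig_id] for f in frags]
    ari = _ari(truth, clusters, frags)

    assignment = binning.assign_contigs(
        clusters, frags, {c: len(s) for c, s in com.contigs.items()}
    )
    purities = []
    for members in assignment.bins().values():
        bp_by_genome: dict[str, int] = {}
        for c in members:
            g = com.truth.contig_to_genome[c]
            bp_by_genome[g] = bp_by_genome.get(g, 0) + len(com.contigs[c])
        purities.append(max(bp_by_genome.values()) / sum(bp_by_genome.values()))
    return {
        "ari": ari,
        "min_bin_purity_pct": 100.0 * min(purities),
        "n_bins": len(purities),
        "n_fragments": len(frags),
    }


def coverage_rescue(seed: int = 0) -> dict:
    """Two compositionally identical genomes (divergence 0) with a 10x
    coverage contrast between two libraries: clustering on joint
    tetra+coverage features must recover what tetra-only cannot."""
    cfg = CommunityConfig(
        n_genomes=2, genome_length=250_000, divergence=0.0,
        abundances={
            "lib1": np.array([10 / 11, 1 / 11]),
            "lib2": np.array([1 / 11, 10 / 11]),
        },
        reads_per_library=100_000, n_markers=0, seed=seed,
    )
    com = simulate_community(cfg)
    frags = fragment_contigs(com.contigs)
    tetra = normalize_features(tetra_feature_matrix(frags))
    cov = _coverage_matrix(com)
    joint = binning.combine_features(tetra, cov, frags)
    truth = [com.truth.contig_to_genome[f.contig_id] for f in frags]
    ari_tetra = _ari(truth, _som_clusters(tetra, seed), frags)
    ari_joint = _ari(truth, _som_clusters(joint, derive_seed(seed, "joint")), frags)
    return {
        "ari_tetra": ari_tetra,
        "ari_joint": ari_joint,
        "ari_gain": ari_joint - ari_tetra,
        "n_fragments": len(frags),
    }


def completeness_recovery(seed: int = 0, retentions=(0.3, 0.6, 0.9), n_seeds: int = 10) -> dict:
    """Plant the 104-marker catalog, shear, keep a random fraction f of the
    contigs, and compare the marker-based completeness estimate with 100f.

    Returns the mean absolute error per retention fraction over ``n_seeds``
    replicate genomes.
    """
    out = {}
    for f in retentions:
        errors = []
        for rep in range(n_seeds):
            rep_seed = derive_seed(seed, f"completeness:{f}:{rep}")
            cfg = CommunityConfig(
                n_genomes=1, genome_length=600_000, divergence=0.5,
                libraries=("lib1",), reads_per_library=1, n_markers=104,
                contig_log_mean=float(np.log(10_000.0)), seed=rep_seed,
            )
            com = simulate_community(cfg)
            cids = sorted(com.contigs)
            rng = np.random.default_rng(derive_seed(rep_seed, "retain"))
            keep = rng.choice(len(cids), size=int(round(f * len(cids))), replace=False)
            subset = {cids[i]: com.contigs[cids[i]] for i in keep}
            hits = detect_markers(subset, com.catalog)
            est = completeness(hits, com.catalog)
            errors.append(abs(est - 100.0 * f))
        out[f"mae_f{int(f * 100)}"] = float(np.mean(errors))
    out["max_mae"] = max(v for v in out.values())
    return out


def multigenome_split(seed: int = 0) -> dict:
    """Two complete genomes merged into one bin with mirrored depths of
    about (10, 2) / (2, 10) across two libraries: the BIC-selected Gaussian
    mixture on differential coverage must find two components and each
    sub-bin must shed the duplicated markers."""
    cfg = CommunityConfig(
        n_genomes=2, genome_length=200_000, divergence=0.3,
        abundances={
            "lib1": np.array([10 / 12, 2 / 12]),
            "lib2": np.array([2 / 12, 10 / 12]),
        },
        reads_per_library=48_000, n_markers=104,
        contig_log_mean=float(np.log(10_000.0)), seed=seed,
    )
    com = simulate_community(cfg)
    cov = _coverage_matrix(com)
    merged = sorted(com.contigs)

    def marker_hits(members):
        return detect_markers({c: com.contigs[c] for c in members}, com.catalog)

    parent_hits = marker_hits(merged)
    assert flag_multigenome(parent_hits)
    subs = binning.split_by_differential_coverage(
        merged, cov, ("lib1", "lib2"), marker_hits,
        seed=derive_seed(seed, "split"),
    )

    def dup_pct(hits):
        present = sum(1 for v in hits.values() if v >= 1)
        dup = sum(1 for v in hits.values() if v >= 2)
        return 100.0 * dup / max(present, 1)

    sub_dups = [dup_pct(marker_hits(s)) for s in subs]
    purities = []
    for s in subs:
        by_g: dict[str, int] = {}
        for c in s:
            by_g[com.truth.contig_to_genome[c]] = by_g.get(com.truth.contig_to_genome[c], 0) + 1
        purities.append(max(by_g.values()) / sum(by_g.values()))
    return {
        "n_components": len(subs),
        "parent_dup_pct": dup_pct(parent_hits),
        "max_sub_dup_pct": max(sub_dups),
        "min_sub_purity_pct": 100.0 * min(purities),
        "n_contigs": len(merged),
    }
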