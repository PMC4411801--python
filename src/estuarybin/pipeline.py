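"""End-to-end pipeline orchestration.

Runs qc -> fragments/tetra -> coverage -> SOM -> binning -> assessment (and
optionally refinement, community/GH profiling and a marker tree) from one
config with a single global seed, writing TSV intermediates with
provenance headers and a JSON manifest of input/output digests per stage.
A stage is skipped on rerun when its outputs exist and its recorded input
digests still match, so a corrupted intermediate forces recomputation of
exactly the stages that consumed or produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeds import derive_seed
from . import binning, coverage, esom, qc, quality, signatures, synthetic

__all__ = ["PipelineConfig", "RunManifest", "validate_config", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "estuarybin_out"
    seed: int = 0
    # synthetic community (used when contigs/reads paths are not given)
    simulate: dict = field(default_factory=dict)
    contigs_fasta: str | None = None
    reads_fastq: dict[str, str] = field(default_factory=dict)  # lib -> path
    artifacts_fasta: str | None = None
    qc_params: dict = field(default_factory=dict)
    fragment_window: int = 5000
    min_contig: int = 2500
    canonical: bool = True
    recruit_k: int = 21
    min_kmer_fraction: float = 0.6
    coverage_weight: float = 1.0
    som: dict = field(default_factory=dict)
    boundary_quantile: float = 0.7
    long_contig_bp: int = 15_000
    refine: bool = False
    refine_library_pair: tuple[str, str] | None = None
    marker_k: int = 31
    stages: tuple[str, ...] = ("qc", "tetra", "coverage", "som", "bin", "assess")


@dataclass
class RunManifest:
    stages: dict[str, dict] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self.stages, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        m = cls()
        if path.exists():
            m.stages = json.loads(path.read_text())
        return m


def load_config(path) -> PipelineConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark else ""
        raise ValueError(f"unparseable config{line}: {exc}") from exc
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    if cfg.refine_library_pair is not None:
        cfg.refine_library_pair = tuple(cfg.refine_library_pair)
    cfg.stages = tuple(cfg.stages)
    return cfg


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems: list[str] = []
    if config.som.get("epochs", 20) <= 0:
        problems.append("som.epochs: must be positive")
    if not 0 < config.boundary_quantile <= 1:
        problems.append("boundary_quantile: must lie in (0, 1]")
    if not 0 < config.min_kmer_fraction <= 1:
        problems.append("min_kmer_fraction: must lie in (0, 1]")
    if config.fragment_window <= 0:
        problems.append("fragment_window: must be positive")
    synthetic_mode = bool(config.simulate) or config.contigs_fasta is None
    if not synthetic_mode:
        if not Path(config.contigs_fasta).exists():
            problems.append(f"contigs_fasta: path does not exist: {config.contigs_fasta}")
        for lib, p in config.reads_fastq.items():
            if not Path(p).exists():
                problems.append(f"reads_fastq.{lib}: path does not exist: {p}")
    try:
        synthetic.CommunityConfig(**config.simulate, seed=config.seed).validate()
    except (TypeError, ValueError) as exc:
        problems.append(f"simulate: {exc}")
    return problems


# ---------------------------------------------------------------------------
# helpers


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _header(stage: str, seed: int, **params) -> str:
    kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"# estuarybin v{__version__} stage={stage} seed={seed} {kv}\n"


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, seed: int, **params) -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, seed, **params))
        df.to_csv(fh, sep="\t", float_format="%.10g")


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


class _Stage:
    """Digest-checked stage wrapper."""

    def __init__(self, manifest: RunManifest, name: str, out_dir: Path):
        self.manifest, self.name, self.out_dir = manifest, name, out_dir

    def fresh(self, inputs: list[Path], outputs: list[Path], params: dict) -> bool:
        rec = self.manifest.stages.get(self.name)
        if rec is None or rec.get("status") != "ok":
            return False
        if rec.get("parameters") != _jsonable(params):
            return False
        if any(not p.exists() for p in outputs):
            return False
        if rec.get("inputs") != {str(p): _digest(p) for p in inputs if p.exists()}:
            return False
        if rec.get("outputs") != {str(p): _digest(p) for p in outputs}:
            return False
        return True

    def record(self, inputs: list[Path], outputs: list[Path], params: dict, status: str, t0: float) -> None:
        self.manifest.stages[self.name] = {
            "status": status,
            "parameters": _jsonable(params),
            "inputs": {str(p): _digest(p) for p in inputs if p.exists()},
            "outputs": {str(p): _digest(p) for p in outputs if p.exists()},
            "wall_seconds": round(time.time() - t0, 3),
        }


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str, sort_keys=True))


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages; see the module docstring.

    Identical config + seed yields bitwise-identical TSV/FASTA outputs. A
    stage failure raises after the manifest (with the failing stage marked)
    is written.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest.load(out / "manifest.json")
    seed = config.seed

    synthetic_mode = config.contigs_fasta is None
    contigs_path = out / "contigs.fasta" if synthetic_mode else Path(config.contigs_fasta)

    community = None
    if synthetic_mode:
        st = _Stage(manifest, "simulate", out)
        ccfg = synthetic.CommunityConfig(**config.simulate, seed=seed)
        params = {"community": config.simulate, "seed": seed}
        reads_paths = {lib: out / f"reads_{lib}.fastq" for lib in ccfg.libraries}
        outputs = [contigs_path, out / "truth_contigs.tsv", out / "truth_markers.tsv", *reads_paths.values()]
        t0 = time.time()
        if not st.fresh([], outputs, params):
            community = synthetic.simulate_community(ccfg)
            community.write_contigs_fasta(contigs_path)
            community.write_truth_tsv(out / "truth_contigs.tsv", out / "truth_markers.tsv")
            for lib, p in reads_paths.items():
                community.write_reads_fastq(lib, p)
            st.record([], outputs, params, "ok", t0)
        reads_fastq = {lib: str(p) for lib, p in reads_paths.items()}
    else:
        reads_fastq = dict(config.reads_fastq)

    def _fail(stage: str, exc: Exception):
        manifest.stages.setdefault(stage, {})["status"] = f"failed: {exc}"
        manifest.save(out / "manifest.json")
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- qc ---------------------------------------------------------------
    qc_out_paths = {lib: out / f"qc_{lib}.fastq" for lib in reads_fastq}
    if "qc" in config.stages:
        st = _Stage(manifest, "qc", out)
        params = {"qc": config.qc_params}
        inputs = [Path(p) for p in reads_fastq.values()]
        outputs = [*qc_out_paths.values(), out / "qc_report.tsv"]
        t0 = time.time()
        if not st.fresh(inputs, outputs, params):
            try:
                qparams = qc.QCParams(**config.qc_params)
                artifacts = (
                    list(_read_fasta(config.artifacts_fasta).values())
                    if config.artifacts_fasta
                    else []
                )
                report_rows = []
                for lib, p in reads_fastq.items():
                    reads = qc.read_fastq(p)
                    survivors, rep = qc.run_qc(reads, artifacts, qparams)
                    qc.write_fastq(survivors, qc_out_paths[lib])
                    row = {"library": lib, "n_in": rep.n_in, "n_out": rep.n_out}
                    row.update({f"removed_{k}": v for k, v in rep.removed.items()})
                    report_rows.append(row)
                _write_tsv(
                    pd.DataFrame(report_rows).set_index("library"),
                    out / "qc_report.tsv", "qc", seed, **config.qc_params,
                )
                st.record(inputs, outputs, params, "ok", t0)
            except Exception as exc:
                _fail("qc", exc)
        qc_reads_paths = qc_out_paths
    else:
        qc_reads_paths = {lib: Path(p) for lib, p in reads_fastq.items()}

    contigs = _read_fasta(contigs_path)

    # --- fragments + tetra ------------------------------------------------
    frag_path, tetra_path = out / "fragments.tsv", out / "tetra.tsv"
    st = _Stage(manifest, "tetra", out)
    params = {"window": config.fragment_window, "min_contig": config.min_contig, "canonical": config.canonical}
    t0 = time.time()
    if not st.fresh([contigs_path], [frag_path, tetra_path], params):
        try:
            frags = signatures.fragment_contigs(
                contigs, window=config.fragment_window, min_contig=config.min_contig
            )
            fdf = pd.DataFrame(
                [(f.fragment_id, f.contig_id, f.start, f.end) for f in frags],
                columns=["fragment_id", "contig_id", "start", "end"],
            ).set_index("fragment_id")
            _write_tsv(fdf, frag_path, "tetra", seed, **params)
            tetra = signatures.tetra_feature_matrix(frags, canonical=config.canonical)
            _write_tsv(tetra.data, tetra_path, "tetra", seed, **params)
            st.record([contigs_path], [frag_path, tetra_path], params, "ok", t0)
        except Exception as exc:
            _fail("tetra", exc)

    fdf = pd.read_csv(frag_path, sep="\t", comment="#").set_index("fragment_id")
    frags = [
        signatures.Fragment(r.contig_id, int(fid.split("|")[-1]), int(r.start), int(r.end),
                            contigs[r.contig_id][int(r.start):int(r.end)])
        for fid, r in fdf.iterrows()
    ]
    tetra = signatures.FeatureMatrix(pd.read_csv(tetra_path, sep="\t", comment="#", index_col=0))

    # --- coverage ---------------------------------------------------------
    cov_path, counts_path = out / "coverage.tsv", out / "read_counts.tsv"
    cov = None
    if "coverage" in config.stages:
        st = _Stage(manifest, "coverage", out)
        params = {"k": config.recruit_k, "min_kmer_fraction": config.min_kmer_fraction}
        inputs = [contigs_path, *qc_reads_paths.values()]
        t0 = time.time()
        if not st.fresh(inputs, [cov_path, counts_path], params):
            try:
                reads_by_lib = {lib: qc.read_fastq(p) for lib, p in qc_reads_paths.items()}
                counts = coverage.recruit_reads(
                    contigs, reads_by_lib, k=config.recruit_k,
                    min_kmer_fraction=config.min_kmer_fraction,
                )
                libs = {
                    lib: coverage.LibraryInfo(
                        lib, len(rr), float(np.mean([len(x.bases) for x in rr])) if rr else 0.0
                    )
                    for lib, rr in reads_by_lib.items()
                }
                covm = coverage.normalize_coverage(
                    counts, libs, {c: len(s) for c, s in contigs.items()}
                )
                _write_tsv(counts, counts_path, "coverage", seed, **params)
                _write_tsv(covm, cov_path, "coverage", seed, **params)
                st.record(inputs, [cov_path, counts_path], params, "ok", t0)
            except Exception as exc:
                _fail("coverage", exc)
        cov = pd.read_csv(cov_path, sep="\t", comment="#", index_col=0)

    # --- som + delineation ------------------------------------------------
    cluster_path = out / "clusters.tsv"
    st = _Stage(manifest, "som", out)
    som_kwargs = dict(config.som)
    params = {"som": som_kwargs, "boundary_quantile": config.boundary_quantile,
              "coverage_weight": config.coverage_weight if cov is not None else 0.0}
    som_inputs = [tetra_path] + ([cov_path] if cov is not None else [])
    som_outputs = [cluster_path, out / "umatrix.tsv", out / "weights.tsv"]
    t0 = time.time()
    if not st.fresh(som_inputs, som_outputs, params):
        try:
            feat = signatures.normalize_features(tetra)
            if cov is not None:
                feat = binning.combine_features(feat, cov, frags, config.coverage_weight)
            rows, cols = esom.default_grid_shape(len(feat.data))
            som_cfg = esom.SOMConfig(
                rows=som_kwargs.get("rows", rows), cols=som_kwargs.get("cols", cols),
                epochs=som_kwargs.get("epochs", 20),
                seed=derive_seed(seed, "som"),
            )
            grid = esom.train(feat, som_cfg)
            um = esom.compute_umatrix(grid)
            bmu = esom.assign_bmu(grid, feat)
            clusters = esom.delineate_clusters(um, bmu, config.boundary_quantile)
            cdf = pd.DataFrame(
                sorted((fid, c if c is not None else binning.UNASSIGNED) for fid, c in clusters.items()),
                columns=["fragment_id", "cluster_id"],
            ).set_index("fragment_id")
            _write_tsv(cdf, cluster_path, "som", seed, **{"rows": som_cfg.rows, "cols": som_cfg.cols, "epochs": som_cfg.epochs})
            _write_tsv(pd.DataFrame(um.values), out / "umatrix.tsv", "som", seed)
            wflat = grid.weights.reshape(som_cfg.rows * som_cfg.cols, -1)
            wdf = pd.DataFrame(wflat, columns=list(feat.data.columns))
            wdf.insert(0, "row", np.repeat(np.arange(som_cfg.rows), som_cfg.cols))
            wdf.insert(1, "col", np.tile(np.arange(som_cfg.cols), som_cfg.rows))
            _write_tsv(wdf.set_index(["row", "col"]), out / "weights.tsv", "som", seed)
            st.record(som_inputs, som_outputs, params, "ok", t0)
        except Exception as exc:
            _fail("som", exc)

    cdf = pd.read_csv(cluster_path, sep="\t", comment="#", index_col=0)
    fragment_clusters = {
        fid: (None if row.cluster_id == binning.UNASSIGNED else row.cluster_id)
        for fid, row in cdf.iterrows()
    }

    # --- binning ----------------------------------------------------------
    assign_path, summary_path = out / "bins.tsv", out / "bin_summary.tsv"
    st = _Stage(manifest, "bin", out)
    params = {"long_contig_bp": config.long_contig_bp}
    t0 = time.time()
    if not st.fresh([cluster_path, frag_path], [assign_path, summary_path], params):
        try:
            assignment = binning.assign_contigs(
                fragment_clusters, frags, {c: len(s) for c, s in contigs.items()},
                long_contig_bp=config.long_contig_bp,
            )
            adf = pd.DataFrame(
                sorted(assignment.contig_to_bin.items()), columns=["contig_id", "bin_id"]
            ).set_index("contig_id")
            _write_tsv(adf, assign_path, "bin", seed, **params)
            summary = binning.bin_summary(assignment, contigs, cov)
            _write_tsv(summary, summary_path, "bin", seed, **params)
            st.record([cluster_path, frag_path], [assign_path, summary_path], params, "ok", t0)
        except Exception as exc:
            _fail("bin", exc)

    adf = pd.read_csv(assign_path, sep="\t", comment="#", index_col=0)
    bins: dict[str, dict[str, str]] = {}
    for cid, row in adf.iterrows():
        if row.bin_id != binning.UNASSIGNED:
            bins.setdefault(row.bin_id, {})[cid] = contigs[cid]

    # --- assessment -------------------------------------------------------
    if "assess" in config.stages:
        st = _Stage(manifest, "assess", out)
        quality_path = out / "bin_quality.tsv"
        params = {"marker_k": config.marker_k}
        t0 = time.time()
        if not st.fresh([assign_path, contigs_path], [quality_path], params):
            try:
                ccfg = synthetic.CommunityConfig(**config.simulate, seed=seed)
                catalog = quality.make_default_catalog(
                    ccfg.n_markers, ccfg.marker_length, seed=seed
                )
                qdf = quality.assess_bins(bins, catalog, k=config.marker_k)
                _write_tsv(qdf, quality_path, "assess", seed, **params)
                st.record([assign_path, contigs_path], [quality_path], params, "ok", t0)
            except Exception as exc:
                _fail("assess", exc)

    # --- optional refinement ---------------------------------------------
    if config.refine and cov is not None:
        st = _Stage(manifest, "refine", out)
        refined_path = out / "bins_refined.tsv"
        pair = config.refine_library_pair or tuple(cov.columns[:2])
        params = {"library_pair": list(pair)}
        t0 = time.time()
        if not st.fresh([assign_path, cov_path], [refined_path], params):
            try:
                ccfg = synthetic.CommunityConfig(**config.simulate, seed=seed)
                catalog = quality.make_default_catalog(
                    ccfg.n_markers, ccfg.marker_length, seed=seed
                )
                rows_out = []
                for bin_id, members in sorted(bins.items()):
                    hits = quality.detect_markers(members, catalog, k=config.marker_k)
                    if quality.flag_multigenome(hits):
                        subs = binning.split_by_differential_coverage(
                            sorted(members), cov, pair,
                            lambda cc: quality.detect_markers(
                                {c: contigs[c] for c in cc}, catalog, k=config.marker_k
                            ),
                            seed=derive_seed(seed, f"refine:{bin_id}"),
                        )
                    else:
                        subs = [sorted(members)]
                    for si, sub in enumerate(subs):
                        label = bin_id if len(subs) == 1 else f"{bin_id}.{si + 1}"
                        rows_out += [(c, label) for c in sub]
                rdf = pd.DataFrame(sorted(rows_out), columns=["contig_id", "bin_id"]).set_index("contig_id")
                _write_tsv(rdf, refined_path, "refine", seed, **params)
                st.record([assign_path, cov_path], [refined_path], params, "ok", t0)
            except Exception as exc:
                _fail("refine", exc)

    manifest.save(out / "manifest.json")
    return manifest
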