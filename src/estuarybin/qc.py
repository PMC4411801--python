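"""Read screening, filtering and end-trimming.

The pipeline applied to each shotgun library is:

1. **screen** — discard reads sharing any exact 28-mer (sliding window,
   step 1) with a known sequencing artifact (adapters, spike-ins), on either
   strand;
2. **filter** — discard reads with >= 3 N's, or mean quality below Q20, or
   length below 50 bp;
3. **trim** — clip both ends at a minimum quality cutoff of 5 using a
   sliding-window scan (window = 10% of the read length, minimum 1); after
   trimming the minimum-length rule is re-applied.

The trimming rule is a self-contained emulation of windowed quality trimmers
(Sickle-style): scanning inward from each end, the retained interval begins
at the first window whose mean quality reaches the cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .kmers import canonical_kmer_codes

__all__ = [
    "ReadRecord",
    "QCParams",
    "QCReport",
    "screen_artifacts",
    "filter_reads",
    "trim_ends",
    "run_qc",
    "read_fastq",
    "write_fastq",
]

logger = logging.getLogger(__name__)


class ReadRecord(NamedTuple):
    read_id: str
    bases: str
    quals: np.ndarray  # integer Phred scores, len == len(bases)


@dataclass
class QCParams:
    artifact_k: int = 28
    artifact_step: int = 1
    max_n: int = 2          # remove at >= max_n + 1 N's
    min_mean_q: float = 20.0
    min_len: int = 50
    trim_q: float = 5.0
    trim_window_frac: float = 0.1

    def validate(self) -> None:
        if self.artifact_k < 1 or self.min_len < 1:
            raise ValueError("artifact_k and min_len must be >= 1")


@dataclass
class QCReport:
    """Per-library removal tally; ``n_in == n_out + sum(removed.values())``."""

    n_in: int = 0
    n_out: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {
            "artifact": 0, "n_bases": 0, "low_quality": 0, "short": 0,
            "short_after_trim": 0,
        }
    )

    def check(self) -> None:
        assert self.n_in == self.n_out + sum(self.removed.values())


def _artifact_kmer_set(artifact_sequences: Iterable[str], k: int) -> set[int]:
    kmers: set[int] = set()
    for seq in artifact_sequences:
        if len(seq) < k:
            logger.warning("artifact sequence shorter than k=%d skipped", k)
            continue
        kmers.update(int(c) for c in canonical_kmer_codes(seq, k))
    return kmers


def screen_artifacts(
    reads: Iterable[ReadRecord],
    artifact_sequences: Iterable[str],
    params: QCParams | None = None,
) -> tuple[list[ReadRecord], int]:
    """Remove reads sharing an exact k-mer with any artifact (either strand).

    Canonical k-mer matching makes the screen strand-symmetric, matching a
    screen against artifacts and their reverse complements. Returns the
    surviving reads and the number removed.
    """
    params = params or QCParams()
    k, step = params.artifact_k, params.artifact_step
    bad = _artifact_kmer_set(artifact_sequences, k)
    if not bad:
        reads = list(reads)
        return reads, 0
    kept: list[ReadRecord] = []
    removed = 0
    for rec in reads:
        codes = canonical_kmer_codes(rec.bases, k)[::step]
        if any(int(c) in bad for c in codes):
            removed += 1
        else:
            kept.append(rec)
    return kept, removed


def _filter_reason(rec: ReadRecord, params: QCParams) -> str | None:
    if rec.bases.count("N") >= params.max_n + 1:
        return "n_bases"
    if len(rec.bases) == 0 or float(np.mean(rec.quals)) < params.min_mean_q:
        return "low_quality"
    if len(rec.bases) < params.min_len:
        return "short"
    return None


def filter_reads(
    reads: Iterable[ReadRecord],
    params: QCParams | None = None,
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Remove reads with >= 3 N's, mean quality < Q20, or length < 50 bp.

    The three rules are independent (a read failing any is removed); the
    tally attributes each removal to the first failing rule in the order
    N-count, quality, length.
    """
    params = params or QCParams()
    kept: list[ReadRecord] = []
    removed = {"n_bases": 0, "low_quality": 0, "short": 0}
    for rec in reads:
        reason = _filter_reason(rec, params)
        if reason is None:
            kept.append(rec)
        else:
            removed[reason] += 1
    return kept, removed


def trim_ends(rec: ReadRecord, params: QCParams | None = None) -> ReadRecord:
    """Clip low-quality flanks with a windowed scan from both ends.

    Window size is ``max(1, floor(trim_window_frac * len))``. The retained
    interval starts in the first 5' window whose mean quality >= ``trim_q``,
    refined to the first base in that window at or above the cutoff (the
    usual windowed-trimmer behaviour, so an isolated low-quality flank inside
    a passing window is still clipped); the 3' end is handled symmetrically.
    If no window qualifies the read becomes empty (and is removed by the
    subsequent length re-check).
    """
    params = params or QCParams()
    n = len(rec.bases)
    if n == 0:
        return rec
    w = max(1, int(params.trim_window_frac * n))
    q = np.asarray(rec.quals, dtype=float)
    means = np.convolve(q, np.ones(w) / w, mode="valid")  # window starts
    ok = means >= params.trim_q
    if not ok.any():
        return ReadRecord(rec.read_id, "", rec.quals[:0])
    w0 = int(np.argmax(ok))             # first qualifying window from 5'
    in_w = np.nonzero(q[w0 : w0 + w] >= params.trim_q)[0]
    start = w0 + int(in_w[0])
    wl = int(len(ok) - 1 - np.argmax(ok[::-1]))  # last qualifying window
    in_w = np.nonzero(q[wl : wl + w] >= params.trim_q)[0]
    end = wl + int(in_w[-1]) + 1
    return ReadRecord(rec.read_id, rec.bases[start:end], rec.quals[start:end])


def run_qc(
    reads: Iterable[ReadRecord],
    artifact_sequences: Iterable[str] = (),
    params: QCParams | None = None,
) -> tuple[list[ReadRecord], QCReport]:
    """Apply screen -> filter -> trim -> re-check length; tally removals."""
    params = params or QCParams()
    params.validate()
    reads = list(reads)
    report = QCReport(n_in=len(reads))
    survivors, n_art = screen_artifacts(reads, artifact_sequences, params)
    report.removed["artifact"] = n_art
    survivors, removed = filter_reads(survivors, params)
    for key, v in removed.items():
        report.removed[key] += v
    out: list[ReadRecord] = []
    for rec in survivors:
        trimmed = trim_ends(rec, params)
        if len(trimmed.bases) < params.min_len:
            report.removed["short_after_trim"] += 1
        else:
            out.append(trimmed)
    report.n_out = len(out)
    report.check()
    return out, report


# ---------------------------------------------------------------------------
# FASTQ I/O (Sanger Phred+33)


def read_fastq(path) -> list[ReadRecord]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    out = []
    with open(path) as fh:
        try:
            for i, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
                quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
                out.append(ReadRecord(title.split()[0], seq.upper(), quals))
        except ValueError as exc:
            raise IOError(f"malformed FASTQ record near index {len(out)}: {exc}") from exc
    return out


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in reads:
            q = "".join(chr(33 + int(x)) for x in rec.quals)
            fh.write(f"@{rec.read_id}\n{rec.bases}\n+\n{q}\n")
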