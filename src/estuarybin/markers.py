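"""Single-copy marker catalogs.

The package estimates bin completeness and redundancy by counting members of
a universal single-copy marker set. On synthetic communities the catalog is a
set of literal nucleotide tags planted once per genome, detectable by exact
k-mer matching; on real data a user-supplied hit table takes its place.

The 16 syntenic ribosomal proteins used for concatenated phylogenies form a
named subset of the catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_seed
from .kmers import canonical_kmer_codes

__all__ = ["MarkerCatalog", "make_default_catalog", "RIBOSOMAL_PROTEINS"]

#: The 16 syntenic ribosomal proteins used for concatenated marker phylogeny.
RIBOSOMAL_PROTEINS: tuple[str, ...] = (
    "rpL2", "rpL3", "rpL4", "rpL5", "rpL6", "rpL14", "rpL15", "rpL16",
    "rpL18", "rpL22", "rpL24", "rpS3", "rpS8", "rpS10", "rpS17", "rpS19",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class MarkerCatalog:
    """A universal single-copy marker set with representative sequences.

    ``sequences`` maps marker id to its representative nucleotide sequence.
    Representatives are mutually non-matching at the detection k-mer size, so
    exact k-mer containment identifies markers unambiguously.
    """

    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def validate(self, k: int = 21) -> None:
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("marker ids must be unique")
        seen: dict[int, str] = {}
        for mid, seq in self.sequences.items():
            for code in canonical_kmer_codes(seq, k):
                other = seen.get(int(code))
                if other is not None and other != mid:
                    raise ValueError(
                        f"markers {other!r} and {mid!r} share a {k}-mer"
                    )
                seen[int(code)] = mid


def make_default_catalog(
    n_markers: int = 104,
    length: int = 300,
    seed: int = 0,
    k: int = 21,
) -> MarkerCatalog:
    """Generate ``n_markers`` random tags, mutually non-matching at ``k``.

    The first 16 markers are named after the ribosomal-protein subset; the
    rest are ``scg_017`` ... (single-copy gene). Random 300-mers collide at
    k=21 with vanishing probability; collisions are resampled anyway.
    """
    rng = np.random.default_rng(derive_seed(seed, "marker_catalog"))
    names = list(RIBOSOMAL_PROTEINS[:n_markers])
    names += [f"scg_{i + 1:03d}" for i in range(len(names), n_markers)]
    seqs: dict[str, str] = {}
    seen: set[int] = set()
    for name in names:
        for _attempt in range(100):
            s = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
            codes = set(int(c) for c in canonical_kmer_codes(s, k))
            if len(codes) == length - k + 1 and not (codes & seen):
                seen |= codes
                seqs[name] = s
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw a non-matching marker tag")
    cat = MarkerCatalog(seqs)
    return cat
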