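"""Deterministic per-stage sub-seed derivation.

All randomness in the package flows from a single integer seed. Each stage
(or repeated sub-task) derives its own sub-seed by hashing the stage name
together with the global seed, so stages are individually reproducible and
reordering one stage never perturbs another.
"""

from __future__ import annotations

import zlib

__all__ = ["derive_seed"]


def derive_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific RNG seed from a global seed.

    The derivation is ``crc32(stage) XOR seed`` folded into ``[0, 2**31)``,
    which is stable across platforms and Python versions (unlike ``hash``).
    """
    return (zlib.crc32(stage.encode("utf-8")) ^ (int(seed) & 0xFFFFFFFF)) % (2**31)
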