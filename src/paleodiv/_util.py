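"""Small shared helpers."""

from __future__ import annotations

import zlib

__all__ = ["stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the run seed.

    Stable across runs and platforms (CRC32 of the stage name mixed with
    the run seed), so stages can be rerun independently yet reproducibly.
    Result is kept below 2**31.
    """
    return (zlib.crc32(stage.encode("utf8")) ^ (seed & 0x7FFFFFFF)) % (2**31)
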