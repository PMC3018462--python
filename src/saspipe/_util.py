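"""Small shared helpers: sequence ops, seeding, hashing, rounding."""

from __future__ import annotations

import hashlib
import zlib
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def stage_rng(seed: int, stage: int, *labels: str) -> np.random.Generator:
    """One RNG stream per logical pipeline stage.

    Streams are derived from the master seed plus a stage index and optional
    string labels (hashed with CRC32, which is stable across interpreter
    runs), so re-running a single stage reproduces its draws exactly.
    """
    entropy = [int(seed), int(stage)] + [zlib.crc32(s.encode()) for s in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding (bankers' rounding is never used in reports)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
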