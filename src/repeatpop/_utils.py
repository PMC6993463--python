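"""Shared low-level helpers: sequence coding, reverse complement, seeded RNG."""

from __future__ import annotations

import zlib

import numpy as np

BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# uint8 byte value -> 2-bit code; anything not ACGT (incl. N) -> 4
_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE_LUT[_b] = _i


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N, case preserved)."""
    return seq.translate(_RC_TABLE)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes A=0 C=1 G=2 T=3, other=4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw]


def decode_seq(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_seq` for code arrays without 4s."""
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def random_sequence(rng: np.random.Generator, length: int) -> str:
    """Uniform random ACGT string."""
    return decode_seq(rng.integers(0, 4, size=length, dtype=np.uint8))


def rng_for(seed: int, stage: str = "") -> np.random.Generator:
    """Generator derived from a run seed and a stage name.

    Per-stage streams are decoupled by mixing a stable hash of the stage
    name into the seed sequence, so adding a stage never perturbs another
    stage's draws.
    """
    if stage:
        return np.random.default_rng(
            np.random.SeedSequence([int(seed), zlib.crc32(stage.encode("utf-8"))])
        )
    return np.random.default_rng(int(seed))
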