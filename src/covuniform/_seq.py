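"""Low-level nucleotide sequence helpers shared across modules.

Sequences are plain Python strings over {A, C, G, T, N}; hot paths work on
uint8 code arrays (A=0, C=1, G=2, T=3, N/other=4).
"""

from __future__ import annotations

import zlib

import numpy as np

BASES = "ACGT"
N_CODE = 4

_CODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case

_BYTES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N

_COMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to a nucleotide string."""
    return _BYTES[codes].tobytes().decode("ascii")


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes]


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMP_TABLE)[::-1]


def substream(seed: int, label: str) -> np.random.Generator:
    """Named RNG substream derived from one master seed.

    Each (seed, label) pair yields an independent, reproducible stream, so
    adding a new labelled consumer never perturbs draws made by existing ones.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
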