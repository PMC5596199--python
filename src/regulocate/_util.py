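"""Small shared helpers: alphabet encoding and deterministic seed derivation."""

from __future__ import annotations

import zlib

import numpy as np

ALPHABET = "ACGT"
COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENC[_b] = _i


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to int8 codes A=0 C=1 G=2 T=3, anything else 4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] if c < 4 else "N" for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def derive_seed(master: int, label: str) -> int:
    """Stable per-stage seed below 2**31 derived from a master seed."""
    return (int(master) * 2654435761 + zlib.crc32(label.encode())) % (2**31 - 1)
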