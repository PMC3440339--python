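"""Small sequence utilities shared across the pipeline stages."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Canonical form of a k-mer: the lexicographic min of the k-mer and its
    reverse complement.  For odd k no k-mer equals its own reverse complement,
    so the strand of the canonical form is unambiguous."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def encode(seq: str) -> np.ndarray:
    """Encode ACGT into uint8 codes 0..3 for vectorised mismatch counting."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def decode_codes(codes: np.ndarray) -> str:
    """Inverse of the 0..3 base coding used by the simulator."""
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def seq_to_codes(seq: str) -> np.ndarray:
    """Map ACGT to integer codes 0..3 (simulator representation)."""
    arr = encode(seq)
    out = np.empty_like(arr)
    for base, code in _BASE_TO_CODE.items():
        out[arr == ord(base)] = code
    return out
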