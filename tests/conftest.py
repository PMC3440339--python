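from __future__ import annotations

import numpy as np
import pytest

from multikc.assembly import Contig, ContigSet
from multikc.sim import Read, TranscriptRecord

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=p))


def repeat_free_seq(rng: np.random.Generator, n: int, k: int) -> str:
    """Random sequence with no repeated canonical k-mer (rejection sampling)."""
    from multikc.util import canonical

    while True:
        s = random_seq(rng, n)
        kmers = [canonical(s[i:i + k]) for i in range(n - k + 1)]
        if len(set(kmers)) == len(kmers):
            return s


def tiling_reads(seq: str, read_len: int = 75, step: int = 3) -> list[Read]:
    """Error-free reads tiling a sequence end to end."""
    starts = list(range(0, len(seq) - read_len + 1, step))
    if starts[-1] != len(seq) - read_len:
        starts.append(len(seq) - read_len)
    return [Read(id=f"t{i:05d}", sequence=seq[s:s + read_len], quality="I" * read_len)
            for i, s in enumerate(starts)]


def make_contigs(seqs: list[str], sample: str = "S") -> ContigSet:
    return ContigSet(
        Contig(id=f"{sample}_c{i:03d}", sequence=s, sample=sample,
               k_used=31, C_used=0.0, mean_kmer_coverage=1.0)
        for i, s in enumerate(seqs)
    )


def make_transcript(tid: str, seq: str, weight: float = 1.0, taxon: str = "host",
                    polya: bool = True, group=None) -> TranscriptRecord:
    return TranscriptRecord(id=tid, taxon=taxon, sequence=seq,
                            abundance_weight=weight, polyadenylated=polya,
                            gene_group=group)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
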