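"""Bounded-mismatch read-back mapping and the per-nucleotide depth statistic.

Each read is assigned to at most one contig: its minimum-mismatch placement
within ``max_mismatches`` over both strands, ties broken by (fewest
mismatches, lexicographically smallest contig id, smallest position, forward
strand).  Multi-mapping reads are therefore counted once, mirroring
single-best short-read mappers; no RPKM-style normalisation is applied —
relative abundance is summarised as depth = reads x read_length / contig
length, truncated to 2 decimals.

Mapping is seed-and-verify: exact ``seed_length`` words of the read are
looked up in a contig word index and candidate placements verified by
mismatch counting.  The pigeonhole guarantee of the tiled seeds only covers
placements with up to ``read_len // seed_length - 1`` mismatches, so whenever
the seeded search cannot certify the global optimum a complete scan of all
positions and strands is run instead; results are exactly those of the
brute-force scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import floor
from typing import Optional, Sequence

import numpy as np

from .assembly import ContigSet
from .util import encode, revcomp


@dataclass(frozen=True)
class MappingParams:
    max_mismatches: int = 3
    # 75 // 18 = 4 disjoint seed windows, so any placement with <= 3
    # mismatches has an exact seed: the seeded search is complete for the
    # default mismatch limit and the fallback scan never fires.
    seed_length: int = 18
    best_hit_only: bool = True   # single-best counting is the only policy

    def validate(self) -> None:
        if not 0 <= self.max_mismatches <= 5:
            raise ValueError("max_mismatches must be in [0, 5]")
        if self.seed_length < 8:
            raise ValueError("seed_length must be >= 8")
        if not self.best_hit_only:
            raise ValueError("only best-hit-only counting is supported")


@dataclass(frozen=True)
class Placement:
    contig_id: str
    position: int        # 0-based start on the contig, forward coordinates
    strand: int          # +1 read maps forward, -1 reverse complement
    mismatches: int

    def key(self) -> tuple:
        return (self.mismatches, self.contig_id, self.position, self.strand != 1)


@dataclass
class MappingResult:
    counts: dict[str, int]               # contig id -> reads assigned
    placements: dict[str, Optional[Placement]]   # read id -> best placement
    n_mapped: int
    n_unmapped: int


class _ContigIndex:
    def __init__(self, contigs: ContigSet, seed_length: int):
        self.seed_length = seed_length
        self.order = sorted(contigs, key=lambda c: c.id)
        self.arrays = {c.id: encode(c.sequence) for c in self.order}
        self.seqs = {c.id: c.sequence for c in self.order}
        index: dict[str, list[tuple[str, int]]] = {}
        for c in self.order:
            s = c.sequence
            for i in range(len(s) - seed_length + 1):
                index.setdefault(s[i:i + seed_length], []).append((c.id, i))
        self.index = index


def _mismatches(carr: np.ndarray, qarr: np.ndarray, start: int) -> int:
    return int(np.count_nonzero(carr[start:start + len(qarr)] != qarr))


def _full_scan(read_seq: str, idx: _ContigIndex) -> Optional[Placement]:
    L = len(read_seq)
    best: Optional[Placement] = None
    queries = [(encode(read_seq), 1), (encode(revcomp(read_seq)), -1)]
    for cid in sorted(idx.arrays):
        carr = idx.arrays[cid]
        if len(carr) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(carr, L)
        for qarr, strand in queries:
            mm = np.count_nonzero(windows != qarr, axis=1)
            pos = int(mm.argmin())
            # argmin returns the smallest position among minima, as required
            p = Placement(cid, pos, strand, int(mm[pos]))
            if best is None or p.key() < best.key():
                best = p
    return best


def _seeded_best(read_seq: str, idx: _ContigIndex) -> Optional[Placement]:
    L = len(read_seq)
    w = idx.seed_length
    if L < w:
        return None
    offsets = list(range(0, L - w + 1, w))
    if offsets[-1] != L - w:
        offsets.append(L - w)
    best: Optional[Placement] = None
    for q, strand in ((read_seq, 1), (revcomp(read_seq), -1)):
        qarr = encode(q)
        seen: set[tuple[str, int]] = set()
        for off in offsets:
            for cid, pos in idx.index.get(q[off:off + w], ()):
                start = pos - off
                if start < 0 or start + L > len(idx.arrays[cid]):
                    continue
                if (cid, start) in seen:
                    continue
                seen.add((cid, start))
                mm = _mismatches(idx.arrays[cid], qarr, start)
                p = Placement(cid, start, strand, mm)
                if best is None or p.key() < best.key():
                    best = p
    return best


def map_reads(reads: Sequence, contigs: ContigSet,
              params: MappingParams = MappingParams()) -> MappingResult:
    """Assign each read to its best placement within the mismatch bound."""
    params.validate()
    if not len(contigs):
        raise ValueError("contigs must be non-empty")
    idx = _ContigIndex(contigs, params.seed_length)
    counts = {c.id: 0 for c in contigs}
    placements: dict[str, Optional[Placement]] = {}
    n_mapped = 0
    for r in reads:
        seq = getattr(r, "sequence", r)
        rid = getattr(r, "id", seq)
        guarantee = max(len(seq) // params.seed_length - 1, 0)
        best = _seeded_best(seq, idx)
        if best is not None and best.mismatches <= guarantee:
            pass    # certified global best: every <=guarantee placement seen
        elif best is None and guarantee >= params.max_mismatches:
            pass    # certifiably unmapped within the mismatch limit
        else:
            best = _full_scan(seq, idx)   # seeds cannot certify: complete scan
        if best is not None and best.mismatches <= params.max_mismatches:
            counts[best.contig_id] += 1
            placements[rid] = best
            n_mapped += 1
        else:
            placements[rid] = None
    return MappingResult(counts=counts, placements=placements,
                         n_mapped=n_mapped, n_unmapped=len(reads) - n_mapped)


# ---------------------------------------------------------------------------
# relative abundance

def compute_depth(n_reads: int, read_length: int, contig_len: int) -> float:
    """Per-nucleotide depth: n_reads x read_length / contig_len, truncated to
    2 decimals (the convention of the printed abundance tables)."""
    if contig_len <= 0:
        raise ValueError("contig_len must be > 0")
    if isinstance(n_reads, int) and isinstance(read_length, int) and isinstance(contig_len, int):
        cents = Fraction(n_reads * read_length * 100, contig_len)
        return floor(cents) / 100.0
    return floor(n_reads * read_length / contig_len * 100) / 100.0


def depth_exact(n_reads: float, read_length: float, contig_len: float) -> float:
    """Unrounded depth (scale-consistent: linear in n_reads)."""
    if contig_len <= 0:
        raise ValueError("contig_len must be > 0")
    return n_reads * read_length / contig_len


@dataclass(frozen=True)
class AbundanceRecord:
    contig_id: str
    n_reads_assembled: int
    contig_len: int
    depth: float
    rank: int


def abundance_records(result: MappingResult, contigs: ContigSet,
                      read_length: int = 75) -> list[AbundanceRecord]:
    """Per-contig abundance with dense ranks over descending read counts."""
    rows = sorted(
        ((c, result.counts.get(c.id, 0)) for c in contigs),
        key=lambda t: (-t[1], t[0].id),
    )
    records = []
    rank = 0
    prev_count = None
    for c, n in rows:
        if n != prev_count:
            rank += 1
            prev_count = n
        records.append(AbundanceRecord(
            contig_id=c.id, n_reads_assembled=n, contig_len=len(c),
            depth=compute_depth(n, read_length, len(c)), rank=rank,
        ))
    return records


@dataclass
class TopTable:
    records: list[AbundanceRecord]
    fold_range: float
    requested_n: int
    complete: bool    # False when fewer records than requested were available


def top_n_table(records: Sequence[AbundanceRecord], n: int) -> TopTable:
    """Top n records by reads assembled (ties: contig id) plus the fold range
    max/min of the listed read counts, rounded to 1 decimal."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(records, key=lambda r: (-r.n_reads_assembled, r.contig_id))
    top = ordered[:n]
    if not top:
        return TopTable(records=[], fold_range=float("nan"),
                        requested_n=n, complete=False)
    counts = [r.n_reads_assembled for r in top]
    lo = min(counts)
    fold = float("inf") if lo == 0 else round(max(counts) / lo, 1)
    return TopTable(records=top, fold_range=fold, requested_n=n,
                    complete=len(top) == n)
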