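"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — plain dictionaries, exhaustive
scans, no word filters, no seed indexes — and written against different
internal representations than the package (raw oriented k-mer strings
instead of canonical+strand tuples, full position scans instead of seeded
lookups), so agreement is a genuine dual-route check.
"""

from __future__ import annotations

from collections import defaultdict

import edlib
import numpy as np

COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(COMP)[::-1]


def kmer_counts(reads, k: int) -> dict[str, int]:
    """Canonical k-mer multiplicities by direct dictionary counting."""
    counts: dict[str, int] = defaultdict(int)
    for r in reads:
        seq = getattr(r, "sequence", r)
        for i in range(len(seq) - k + 1):
            km = seq[i:i + k]
            counts[min(km, rc(km))] += 1
    return dict(counts)


def unitigs(reads, k: int, C: float = 0.0) -> set[str]:
    """Unitig decomposition by exhaustive path enumeration on a raw oriented
    k-mer graph (every observed k-mer and its reverse complement is a node).
    Returns canonical (lexicographically smaller strand) sequences."""
    counts = kmer_counts(reads, k)
    alive = {km for km, c in counts.items() if c > C}

    succ: dict[str, set[str]] = defaultdict(set)
    pred: dict[str, set[str]] = defaultdict(set)
    nodes: set[str] = set()
    for r in reads:
        seq = getattr(r, "sequence", r)
        for s in (seq, rc(seq)):
            kms = [s[i:i + k] for i in range(len(s) - k + 1)]
            kms = [km for km in kms]  # keep order
            for km in kms:
                if min(km, rc(km)) in alive:
                    nodes.add(km)
            for a, b in zip(kms, kms[1:]):
                if min(a, rc(a)) in alive and min(b, rc(b)) in alive:
                    succ[a].add(b)
                    pred[b].add(a)

    def is_start(x: str) -> bool:
        ps = pred.get(x, set())
        if len(ps) != 1:
            return True
        return len(succ.get(next(iter(ps)), set())) != 1

    out: set[str] = set()
    visited: set[str] = set()
    for x in sorted(nodes):
        if x in visited or not is_start(x):
            continue
        path = [x]
        used = {min(x, rc(x))}
        while True:
            ss = succ.get(path[-1], set())
            if len(ss) != 1:
                break
            y = next(iter(ss))
            if len(pred.get(y, set())) != 1 or min(y, rc(y)) in used:
                break
            path.append(y)
            used.add(min(y, rc(y)))
        visited.update(path)
        visited.update(rc(p) for p in path)
        seq = path[0] + "".join(p[-1] for p in path[1:])
        out.add(min(seq, rc(seq)))
    # pure cycles have no start node; walk them too
    for x in sorted(nodes):
        if x in visited:
            continue
        path = [x]
        visited.add(x)
        visited.add(rc(x))
        while True:
            ss = succ.get(path[-1], set())
            if len(ss) != 1:
                break
            y = next(iter(ss))
            if y in path:
                break
            path.append(y)
            visited.add(y)
            visited.add(rc(y))
        seq = path[0] + "".join(p[-1] for p in path[1:])
        out.add(min(seq, rc(seq)))
    return out


def greedy_clusters(contigs, identity_threshold: float) -> list[str]:
    """Greedy clustering with no word filter: every earlier representative is
    a candidate.  Returns representative contig ids in processing order."""
    order = sorted(contigs, key=lambda c: (-len(c.sequence), c.id))
    reps: list = []
    for c in order:
        placed = False
        for r in reps:
            short, long_ = ((c.sequence, r.sequence)
                            if len(c.sequence) <= len(r.sequence)
                            else (r.sequence, c.sequence))
            d = min(
                edlib.align(short, long_, mode="HW", task="distance")["editDistance"],
                edlib.align(rc(short), long_, mode="HW", task="distance")["editDistance"],
            )
            ident = (len(short) - d) / len(short)
            if ident >= identity_threshold:
                placed = True
                break
        if not placed:
            reps.append(c)
    return [r.id for r in reps]


def best_placement(read_seq: str, contigs) -> tuple | None:
    """Exhaustive scan of every contig, position and strand; returns
    (mismatches, contig_id, position, strand) for the best placement under
    the (mismatches, contig id, position, forward-first) tie-break."""
    best = None
    for c in sorted(contigs, key=lambda c: c.id):
        s = c.sequence
        for q, strand in ((read_seq, 1), (rc(read_seq), -1)):
            L = len(q)
            for pos in range(len(s) - L + 1):
                mm = sum(1 for i in range(L) if s[pos + i] != q[i])
                key = (mm, c.id, pos, strand != 1)
                if best is None or key < best:
                    best = key
    if best is None:
        return None
    mm, cid, pos, rev = best
    return (mm, cid, pos, -1 if rev else 1)


def interval_union_mask(intervals, ref_len: int) -> int:
    mask = np.zeros(ref_len, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return int(mask.sum())
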