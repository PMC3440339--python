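"""Greedy CD-HIT-style redundancy depletion of contig sets.

Contigs are processed longest-first (ties: lexicographic id).  Each contig
joins the first existing cluster whose representative shares an exact
``word_size`` seed and aligns to it at or above the identity threshold (both
strands); otherwise it founds a new cluster.  Identity uses the shorter
sequence's span as the denominator — ``(len_shorter - edit_distance) /
len_shorter`` under an infix (end-free) alignment of the shorter sequence
into the longer, computed with edlib — so a contained fragment of a longer
contig collapses into it, which is what drives the large redundancy
reductions of pooled multi-parameter assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .assembly import Contig, ContigSet
from .util import revcomp


@dataclass(frozen=True)
class ClusterParams:
    identity_threshold: float = 0.95
    word_size: int = 8
    coverage_mode: str = "shorter"   # identity denominator: the shorter span

    def validate(self) -> None:
        if not 0.5 < self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must be in (0.5, 1.0]")
        if not 1 <= self.word_size <= 12:
            raise ValueError("word_size must be in [1, 12]")
        if self.coverage_mode != "shorter":
            raise ValueError("only coverage_mode='shorter' is supported")


@dataclass
class Cluster:
    representative: Contig
    members: list[Contig] = field(default_factory=list)
    identities: list[float] = field(default_factory=list)


def pair_identity(a: str, b: str) -> float:
    """Identity of the shorter sequence against the longer, best of both
    strands: (len_shorter - edit_distance) / len_shorter with the shorter
    sequence aligned end-free (infix) into the longer."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    d_fwd = edlib.align(short, long_, mode="HW", task="distance")["editDistance"]
    d_rev = edlib.align(revcomp(short), long_, mode="HW", task="distance")["editDistance"]
    d = min(d_fwd, d_rev)
    return max(0.0, (len(short) - d) / len(short))


def _words(seq: str, w: int) -> set[str]:
    return {seq[i:i + w] for i in range(len(seq) - w + 1)}


def deplete_with_clusters(
    contigs: ContigSet, params: ClusterParams
) -> tuple[ContigSet, list[Cluster]]:
    """Greedy incremental clustering; returns (representatives, clusters)."""
    params.validate()
    order = sorted(contigs, key=lambda c: (-len(c), c.id))
    clusters: list[Cluster] = []
    word_index: dict[str, set[int]] = {}
    w = params.word_size
    for c in order:
        qwords = _words(c.sequence, w) | _words(revcomp(c.sequence), w)
        candidates: set[int] = set()
        for word in qwords:
            candidates |= word_index.get(word, set())
        joined = False
        for ci in sorted(candidates):
            ident = pair_identity(c.sequence, clusters[ci].representative.sequence)
            if ident >= params.identity_threshold:
                clusters[ci].members.append(c)
                clusters[ci].identities.append(ident)
                joined = True
                break
        if not joined:
            ci = len(clusters)
            clusters.append(Cluster(representative=c))
            for word in _words(c.sequence, w):
                word_index.setdefault(word, set()).add(ci)
    reps = ContigSet(cl.representative for cl in clusters)
    return reps, clusters


def deplete(contigs: ContigSet, params: ClusterParams) -> ContigSet:
    """Representatives only, in descending length order."""
    reps, _ = deplete_with_clusters(contigs, params)
    return reps


def pool_and_deplete(sets: list[ContigSet], params: ClusterParams) -> ContigSet:
    """Concatenate same-sample contig sets, then deplete.  Provenance
    (k_used, C_used) of every surviving representative is preserved because
    representatives are the original contig objects."""
    samples = {c.sample for cs in sets for c in cs}
    if len(samples) > 1:
        raise ValueError(f"cannot pool contig sets from different samples: {sorted(samples)}")
    pooled: list[Contig] = []
    seen_ids: set[str] = set()
    for cs in sets:
        for c in cs:
            if c.id in seen_ids:    # pooling a set with itself is idempotent
                continue
            seen_ids.add(c.id)
            pooled.append(c)
    return deplete(ContigSet(pooled), params)


def clstr_report(clusters: list[Cluster]) -> str:
    """CD-HIT-flavoured plain-text cluster report."""
    out = []
    for i, cl in enumerate(clusters):
        out.append(f">Cluster {i}\n")
        out.append(f"0\t{len(cl.representative)}nt, >{cl.representative.id} ... *\n")
        for j, (m, ident) in enumerate(zip(cl.members, cl.identities), start=1):
            out.append(f"{j}\t{len(m)}nt, >{m.id} ... at {100 * ident:.2f}%\n")
    return "".join(out)
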