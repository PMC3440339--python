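"""Velvet-style de Bruijn assembly of short reads into unitig contigs.

The graph is bidirected over canonical k-mers (k odd, so no k-mer is its own
reverse complement).  An oriented node is ``(kmer, strand)`` with strand +1
meaning the canonical spelling and -1 its reverse complement; every edge is
stored together with its reverse-complement twin, so predecessors of an
oriented node are the flipped successors of its flip.

Assembly is deliberately minimal: coverage-cutoff pruning, tip clipping, and
maximal-unambiguous-path (unitig) compression.  No scaffolding or bubble
popping — at desk scale the unitig decomposition is the honest output, and
determinism (contig order and ids a pure function of the input) is a hard
requirement because contig sets are merged and diffed downstream.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Optional, Sequence

from .util import canonical, revcomp

Oriented = tuple[str, int]


@dataclass(frozen=True)
class AssemblyParams:
    """Parameters of one assembly cell.

    ``k`` is the de Bruijn hash length, ``C`` the coverage cutoff: nodes with
    multiplicity <= C are discarded (survival requires multiplicity > C,
    matching Velvet's cov_cutoff semantics).  ``tip_clip_len`` defaults to 2k.
    """

    k: int
    C: float
    min_contig_len: int = 100
    tip_clip_len: Optional[int] = None
    sample: str = "S"

    def validate(self) -> None:
        if self.k < 15:
            raise ValueError("k must be >= 15")
        if self.k % 2 == 0:
            raise ValueError("k must be odd")
        if self.C < 0:
            raise ValueError("C must be >= 0")
        if self.min_contig_len < self.k:
            raise ValueError("min_contig_len must be >= k")

    @property
    def effective_tip_clip_len(self) -> int:
        return self.tip_clip_len if self.tip_clip_len is not None else 2 * self.k


@dataclass
class Contig:
    id: str
    sequence: str
    sample: str
    k_used: int
    C_used: float
    mean_kmer_coverage: float
    n_reads_assembled: int = 0

    def __len__(self) -> int:
        return len(self.sequence)


class ContigSet:
    """Ordered collection of contigs (ids unique within the set)."""

    def __init__(self, contigs: Iterable[Contig] = ()):
        self.contigs: list[Contig] = list(contigs)
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("contig ids must be unique within a ContigSet")

    def __iter__(self):
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def __getitem__(self, i):
        return self.contigs[i]

    def lengths(self) -> list[int]:
        return [len(c) for c in self.contigs]

    def by_id(self) -> dict[str, Contig]:
        return {c.id: c for c in self.contigs}

    def fasta_str(self) -> str:
        out = []
        for c in self.contigs:
            out.append(
                f">{c.id} sample={c.sample} k={c.k_used} C={c.C_used:g} "
                f"cov={c.mean_kmer_coverage:.2f}\n"
            )
            for i in range(0, len(c.sequence), 70):
                out.append(c.sequence[i:i + 70] + "\n")
        return "".join(out)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.fasta_str())


@dataclass
class KmerGraph:
    """Canonical k-mer multiplicities plus strand-aware (k-1)-overlap edges."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)
    adj: dict[Oriented, set[Oriented]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.counts)

    @property
    def n_edges(self) -> int:
        # each edge is stored with its twin; a self-twin edge appears once
        return sum(len(v) for v in self.adj.values())

    def successors(self, x: Oriented) -> set[Oriented]:
        return self.adj.get(x, set())

    def indegree(self, x: Oriented) -> int:
        return len(self.adj.get((x[0], -x[1]), ()))

    def predecessors(self, x: Oriented) -> list[Oriented]:
        return [(n, -s) for (n, s) in self.adj.get((x[0], -x[1]), ())]


def _oriented(kmer: str, rc_kmer: str) -> Oriented:
    return (kmer, 1) if kmer <= rc_kmer else (rc_kmer, -1)


def build_graph(reads: Sequence, k: int) -> KmerGraph:
    """Count canonical k-mers of the reads and record consecutive-k-mer edges.

    ``reads`` may be Read objects or plain sequence strings.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    counts: dict[str, int] = defaultdict(int)
    adj: dict[Oriented, set[Oriented]] = defaultdict(set)
    for r in reads:
        seq = getattr(r, "sequence", r)
        n = len(seq)
        if n < k:
            raise ValueError(f"read shorter than k={k}")
        rc = revcomp(seq)
        prev: Optional[Oriented] = None
        for i in range(n - k + 1):
            f = seq[i:i + k]
            node = _oriented(f, rc[n - k - i:n - i])
            counts[node[0]] += 1
            if prev is not None:
                adj[prev].add(node)
                adj[(node[0], -node[1])].add((prev[0], -prev[1]))
            prev = node
    return KmerGraph(k=k, counts=dict(counts), adj=dict(adj))


def _subgraph(g: KmerGraph, keep: set[str]) -> KmerGraph:
    counts = {n: c for n, c in g.counts.items() if n in keep}
    adj: dict[Oriented, set[Oriented]] = {}
    for u, vs in g.adj.items():
        if u[0] not in keep:
            continue
        kept = {v for v in vs if v[0] in keep}
        if kept:
            adj[u] = kept
    return KmerGraph(k=g.k, counts=counts, adj=adj)


def apply_coverage_cutoff(g: KmerGraph, C: float) -> KmerGraph:
    """Remove every node with multiplicity <= C (and incident edges).

    C=0 is the identity on graphs whose multiplicities are all >= 1.
    """
    if C < 0:
        raise ValueError("C must be >= 0")
    keep = {n for n, c in g.counts.items() if c > C}
    if len(keep) == len(g.counts):
        return KmerGraph(k=g.k, counts=dict(g.counts),
                         adj={u: set(v) for u, v in g.adj.items()})
    return _subgraph(g, keep)


def _unitig_paths(g: KmerGraph) -> list[list[Oriented]]:
    """Maximal non-branching oriented paths covering every node exactly once.

    Deterministic: starts are scanned in sorted node order, +1 strand first.
    Isolated cycles are traversed from their smallest node.
    """
    visited: set[str] = set()
    paths: list[list[Oriented]] = []

    def is_start(x: Oriented) -> bool:
        preds = g.predecessors(x)
        if len(preds) != 1:
            return True
        return len(g.successors(preds[0])) != 1

    nodes_sorted = sorted(g.counts)
    for n in nodes_sorted:
        if n in visited:
            continue
        for strand in (1, -1):
            x = (n, strand)
            if not is_start(x):
                continue
            path = [x]
            visited.add(n)
            while True:
                succs = g.successors(path[-1])
                if len(succs) != 1:
                    break
                y = next(iter(succs))
                if g.indegree(y) != 1 or y[0] in visited:
                    break
                path.append(y)
                visited.add(y[0])
            paths.append(path)
            break
    # leftover nodes sit on simple cycles
    for n in nodes_sorted:
        if n in visited:
            continue
        x = (n, 1)
        path = [x]
        visited.add(n)
        while True:
            succs = g.successors(path[-1])
            if len(succs) != 1:
                break
            y = next(iter(succs))
            if y[0] in visited:
                break
            path.append(y)
            visited.add(y[0])
        paths.append(path)
    return paths


def _spell(path: list[Oriented]) -> str:
    def s(x: Oriented) -> str:
        return x[0] if x[1] == 1 else revcomp(x[0])

    seq = [s(path[0])]
    for x in path[1:]:
        seq.append(s(x)[-1])
    return "".join(seq)


def clip_tips(g: KmerGraph, tip_len: int) -> KmerGraph:
    """Iteratively remove dead-end unitigs shorter than ``tip_len`` whose mean
    multiplicity is below the graph median (Velvet-style tip clipping)."""
    while True:
        if not g.counts:
            return g
        med = median(g.counts.values())
        drop: set[str] = set()
        for path in _unitig_paths(g):
            x0, xe = path[0], path[-1]
            dead_head = g.indegree(x0) == 0
            dead_tail = len(g.successors(xe)) == 0
            if dead_head == dead_tail:   # internal path or isolated island
                continue
            length = g.k + len(path) - 1
            if length >= tip_len:
                continue
            cov = sum(g.counts[x[0]] for x in path) / len(path)
            if cov < med:
                drop.update(x[0] for x in path)
        if not drop:
            return g
        g = _subgraph(g, set(g.counts) - drop)


def unitig_sequences(g: KmerGraph) -> list[tuple[str, float]]:
    """Canonical-orientation unitig sequences with mean k-mer coverage."""
    out = []
    for path in _unitig_paths(g):
        seq = _spell(path)
        rc = revcomp(seq)
        if rc < seq:
            seq = rc
        cov = sum(g.counts[x[0]] for x in path) / len(path)
        out.append((seq, cov))
    return out


def contigs_from_fasta(path, sample: Optional[str] = None) -> ContigSet:
    """Load contigs from FASTA.  ``sample=... k=... C=... cov=...`` header
    attributes written by :meth:`ContigSet.write_fasta` are honoured when
    present; otherwise defaults are used."""
    from Bio import SeqIO

    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = dict(tok.split("=", 1) for tok in rec.description.split()[1:]
                    if "=" in tok)
        contigs.append(Contig(
            id=rec.id,
            sequence=str(rec.seq).upper(),
            sample=sample or meta.get("sample", "S"),
            k_used=int(meta.get("k", 0)),
            C_used=float(meta.get("C", 0.0)),
            mean_kmer_coverage=float(meta.get("cov", 0.0)),
        ))
    return ContigSet(contigs)


def assemble(reads: Sequence, params: AssemblyParams,
             graph: Optional[KmerGraph] = None) -> ContigSet:
    """build_graph -> coverage cutoff -> tip clipping -> unitigs -> length
    filter.  ``graph`` lets a caller reuse a pre-built graph for the same k
    (the multi-C grid does this); it is never mutated.
    """
    params.validate()
    if graph is None:
        if not len(reads):
            raise ValueError("reads must be non-empty")
        graph = build_graph(reads, params.k)
    elif graph.k != params.k:
        raise ValueError("reused graph was built with a different k")
    g = apply_coverage_cutoff(graph, params.C)
    g = clip_tips(g, params.effective_tip_clip_len)
    seqs = [(s, cov) for s, cov in unitig_sequences(g)
            if len(s) >= params.min_contig_len]
    seqs.sort(key=lambda t: (-len(t[0]), t[0]))
    contigs = [
        Contig(
            id=f"{params.sample}_k{params.k}_C{params.C:g}_{i + 1}",
            sequence=s,
            sample=params.sample,
            k_used=params.k,
            C_used=params.C,
            mean_kmer_coverage=cov,
        )
        for i, (s, cov) in enumerate(seqs)
    ]
    return ContigSet(contigs)
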