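"""Multiple-k/Multiple-C orchestration and assembly summary statistics.

The same reads are assembled under every (k, C) cell of a grid; each cell's
contigs are depleted for redundancy, the depleted cells are pooled per
sample, and the pool is depleted again.  Low-C cells keep rare transcripts
that a stringent cutoff would erase, high-C cells assemble highly expressed
transcripts cleanly through their error noise, so the merged set recovers
more distinct transcripts than any single "optimal" cell.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .assembly import AssemblyParams, ContigSet, assemble, build_graph
from .cluster import ClusterParams, deplete, pool_and_deplete
from .mapping import MappingParams, map_reads


@dataclass(frozen=True)
class GridSpec:
    """The (k, C) grid.  The default brackets the commonly-optimal single
    cell (k=31, C=6) with laxer and stricter settings in both directions."""

    k_values: tuple = (21, 25, 31, 41)
    C_values: tuple = (2.0, 6.0)

    def validate(self) -> None:
        if not self.k_values or not self.C_values:
            raise ValueError("grid must have at least one k and one C")
        for k in self.k_values:
            if k % 2 == 0 or k < 15:
                raise ValueError(f"invalid k={k}: must be odd and >= 15")
        for c in self.C_values:
            if c < 0:
                raise ValueError(f"invalid C={c}: must be >= 0")

    def cells(self) -> list[tuple[int, float]]:
        return [(k, float(c)) for k in self.k_values for c in self.C_values]


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    mean_len: float
    longest: int
    n50: int
    frac_ge_threshold: float
    reads_covered_frac: float


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that contigs of length >= L sum to >= half the total."""
    if not lengths:
        return 0
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for L in ordered:
        acc += L
        if acc >= half:
            return L
    return ordered[-1]


def run_multikc_detailed(
    reads: Sequence,
    grid: GridSpec,
    cluster: ClusterParams = ClusterParams(),
    asm_defaults: AssemblyParams = AssemblyParams(k=31, C=6.0),
) -> tuple[ContigSet, dict[tuple[int, float], ContigSet], list[dict]]:
    """Per-cell assemble -> deplete, pool across the grid, deplete again.

    Returns (final contig set, per-cell depleted contig sets, per-cell log
    rows).  The k-mer graph is built once per k and shared across C values;
    the cutoff never mutates it, so results are identical to independent
    per-cell assembly.
    """
    grid.validate()
    if not len(reads):
        raise ValueError("reads must be non-empty")
    per_cell: dict[tuple[int, float], ContigSet] = {}
    log: list[dict] = []
    for k in grid.k_values:
        graph = build_graph(reads, k)
        for C in grid.C_values:
            params = replace(asm_defaults, k=k, C=float(C))
            raw = assemble(reads, params, graph=graph)
            depleted = deplete(raw, cluster)
            per_cell[(k, float(C))] = depleted
            log.append({
                "k": k, "C": float(C),
                "nodes_before_cutoff": graph.n_nodes,
                "contigs_raw": len(raw),
                "contigs_depleted": len(depleted),
            })
    merged = pool_and_deplete(list(per_cell.values()), cluster)
    final = ContigSet(c for c in merged if len(c) >= asm_defaults.min_contig_len)
    return final, per_cell, log


def run_multikc(reads: Sequence, grid: GridSpec,
                cluster: ClusterParams = ClusterParams(),
                asm_defaults: AssemblyParams = AssemblyParams(k=31, C=6.0)) -> ContigSet:
    final, _, _ = run_multikc_detailed(reads, grid, cluster, asm_defaults)
    return final


def compute_stats(contigs: ContigSet, reads: Sequence = (),
                  len_threshold: int = 500,
                  mapping_params: Optional[MappingParams] = None) -> AssemblyStats:
    """Contig count/length summaries plus the fraction of reads with at least
    one mapping at the mismatch limit ('reads covered')."""
    lengths = contigs.lengths()
    if not lengths:
        return AssemblyStats(0, 0.0, 0, 0, 0.0, 0.0)
    covered = 0.0
    if len(reads):
        result = map_reads(reads, contigs, mapping_params or MappingParams())
        covered = result.n_mapped / len(reads)
    return AssemblyStats(
        n_contigs=len(lengths),
        mean_len=sum(lengths) / len(lengths),
        longest=max(lengths),
        n50=n50(lengths),
        frac_ge_threshold=sum(1 for L in lengths if L >= len_threshold) / len(lengths),
        reads_covered_frac=covered,
    )
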