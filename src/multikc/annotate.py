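"""Cascade top-hit homology annotation and the report arithmetic built on it.

Contigs are first searched at the translated tier: every contig is translated
in six frames and compared against the frame-0 peptides of the labelled
reference by exact-word seeding and ungapped X-drop extension under BLOSUM62.
Contigs without a passing translated hit fall through to a nucleotide tier
(+2/-3 scoring, both strands).  E-values use the ungapped Karlin-Altschul
form E = K * m * n * exp(-lambda * S) with fixed published constants; a hit
is reported only when its e-value passes the cutoff and the HSP is at least
``min_hsp_len`` residues/nt long.  Exactly one hit (the top hit: lowest
e-value, ties by higher score then lexicographic id) is kept per contig, and
a contig with a translated hit is never searched at the nucleotide tier.

The remaining operations are the counting/percentage arithmetic of the
summary tables: non-redundant top-hit sets, two-sample overlap, per-taxon
distribution, gene-set recovery, and reference interval coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .assembly import ContigSet
from .sim import TranscriptRecord
from .util import revcomp

TIER_TRANSLATED = "translated"
TIER_NUCLEOTIDE = "nucleotide"
TIER_NONE = "none"


@dataclass(frozen=True)
class AnnotationParams:
    evalue_cutoff: float = 1e-3
    min_hsp_len: int = 33          # residues (translated) or nt (nucleotide)
    top_hits: int = 1              # fixed: only the top hit is ever reported
    seed_word_aa: int = 4
    seed_word_nt: int = 11
    x_drop: float = 20.0
    # published ungapped Karlin-Altschul constants
    lambda_aa: float = 0.3176
    K_aa: float = 0.134
    lambda_nt: float = 1.28
    K_nt: float = 0.46
    nt_match: int = 2
    nt_mismatch: int = -3

    def validate(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.top_hits != 1:
            raise ValueError("top_hits is fixed at 1 (top-hit-only policy)")
        if self.min_hsp_len < 1:
            raise ValueError("min_hsp_len must be >= 1")


@dataclass(frozen=True)
class HomologyHit:
    contig_id: str
    hit_id: Optional[str]
    taxon: Optional[str]
    tier: str
    score: float = 0.0
    evalue: float = float("inf")
    identity: float = 0.0
    align_len: int = 0
    # aligned interval on the reference transcript, nt, 0-based half-open
    ref_start: int = 0
    ref_end: int = 0


_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_B62: dict[tuple[str, str], float] = {}
for _a in _BLOSUM62.alphabet:
    for _b in _BLOSUM62.alphabet:
        _B62[(_a, _b)] = float(_BLOSUM62[_a, _b])


def _pep_score(a: str, b: str) -> float:
    return _B62.get((a, b), -4.0)


def translate_frame0(seq: str) -> str:
    """Frame-0 translation with '*' for stops (reference peptides)."""
    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())


def six_frame_translations(seq: str) -> list[tuple[str, int, int]]:
    """(peptide, strand, frame) for all six frames."""
    out = []
    rc = revcomp(seq)
    for strand, s in ((1, seq), (-1, rc)):
        for f in range(3):
            sub = s[f:]
            n = len(sub) - len(sub) % 3
            if n >= 3:
                out.append((str(Seq(sub[:n]).translate()), strand, f))
    return out


@dataclass
class _Hsp:
    ref_i: int
    score: float
    matches: int
    align_len: int
    r_start: int
    r_end: int


def _extend(q: str, r: str, qpos: int, rpos: int, w: int, score_fn,
            x_drop: float) -> _Hsp:
    """Ungapped X-drop extension of an exact ``w``-word seed."""
    s = sum(score_fn(q[qpos + i], r[rpos + i]) for i in range(w))
    # right extension
    best, run = 0.0, 0.0
    best_ext = 0
    i = 0
    while qpos + w + i < len(q) and rpos + w + i < len(r):
        run += score_fn(q[qpos + w + i], r[rpos + w + i])
        i += 1
        if run > best:
            best, best_ext = run, i
        if run < best - x_drop:
            break
    right = best_ext
    s += best
    # left extension
    best, run = 0.0, 0.0
    best_ext = 0
    i = 0
    while qpos - 1 - i >= 0 and rpos - 1 - i >= 0:
        run += score_fn(q[qpos - 1 - i], r[rpos - 1 - i])
        i += 1
        if run > best:
            best, best_ext = run, i
        if run < best - x_drop:
            break
    left = best_ext
    s += best
    qs, qe = qpos - left, qpos + w + right
    rs, re = rpos - left, rpos + w + right
    matches = sum(1 for i in range(qe - qs) if q[qs + i] == r[rs + i])
    return _Hsp(ref_i=-1, score=s, matches=matches, align_len=qe - qs,
                r_start=rs, r_end=re)


def _search(query: str, refs: list[str], index: Mapping[str, list[tuple[int, int]]],
            w: int, score_fn, x_drop: float) -> list[_Hsp]:
    """Best HSP per reference for one query string."""
    best: dict[int, _Hsp] = {}
    covered: dict[tuple[int, int], int] = {}   # (ref_i, diagonal) -> q end
    for qpos in range(len(query) - w + 1):
        for ref_i, rpos in index.get(query[qpos:qpos + w], ()):
            diag = qpos - rpos
            if qpos < covered.get((ref_i, diag), -1):
                continue
            hsp = _extend(query, refs[ref_i], qpos, rpos, w, score_fn, x_drop)
            hsp.ref_i = ref_i
            covered[(ref_i, diag)] = qpos - (rpos - hsp.r_start) + (hsp.r_end - hsp.r_start)
            cur = best.get(ref_i)
            if cur is None or hsp.score > cur.score:
                best[ref_i] = hsp
    return list(best.values())


class ReferenceDB:
    """Word-indexed peptide (frame 0) and nucleotide views of the reference."""

    def __init__(self, reference: Sequence[TranscriptRecord],
                 params: AnnotationParams = AnnotationParams()):
        if not reference:
            raise ValueError("reference must be non-empty")
        self.params = params
        self.ids = [r.id for r in reference]
        self.taxa = [r.taxon for r in reference]
        self.peptides = [translate_frame0(r.sequence) for r in reference]
        # only coding records (stop-free frame 0) enter the protein view:
        # a protein database has no entries for rRNA-like sequences, which is
        # why non-coding transcripts are only findable at the nucleotide tier
        self.coding = ["*" not in p for p in self.peptides]
        self.nucs = [r.sequence for r in reference]
        self.total_aa = sum(len(p) for p, c in zip(self.peptides, self.coding) if c)
        self.total_nt = sum(len(s) for s in self.nucs)
        self.pep_index: dict[str, list[tuple[int, int]]] = {}
        w = params.seed_word_aa
        for i, p in enumerate(self.peptides):
            if not self.coding[i]:
                continue
            for j in range(len(p) - w + 1):
                word = p[j:j + w]
                if "*" in word:
                    continue
                self.pep_index.setdefault(word, []).append((i, j))
        self.nuc_index: dict[str, list[tuple[int, int]]] = {}
        w = params.seed_word_nt
        for i, s in enumerate(self.nucs):
            for j in range(len(s) - w + 1):
                self.nuc_index.setdefault(s[j:j + w], []).append((i, j))


def _evalue(K: float, lam: float, m: int, n: int, score: float) -> float:
    return K * m * n * exp(-lam * score)


def _best_hit(cands: list[tuple[float, float, str, _Hsp, int]]) -> Optional[tuple]:
    # candidate tuple: (evalue, -score, hit_id, hsp, unit_nt_factor)
    if not cands:
        return None
    return min(cands, key=lambda t: (t[0], t[1], t[2]))


def annotate_contig(seq: str, contig_id: str, db: ReferenceDB,
                    params: AnnotationParams) -> HomologyHit:
    # tier 1: translated
    cands = []
    for pep, strand, frame in six_frame_translations(seq):
        m = len(pep)
        for hsp in _search(pep, db.peptides, db.pep_index,
                           params.seed_word_aa, _pep_score, params.x_drop):
            if hsp.align_len < params.min_hsp_len:
                continue
            ev = _evalue(params.K_aa, params.lambda_aa, m, db.total_aa, hsp.score)
            if ev <= params.evalue_cutoff:
                cands.append((ev, -hsp.score, db.ids[hsp.ref_i], hsp, 3))
    best = _best_hit(cands)
    tier = TIER_TRANSLATED
    if best is None:
        # tier 2: nucleotide, both strands
        def nt_score(a: str, b: str) -> float:
            return params.nt_match if a == b else params.nt_mismatch

        cands = []
        for q in (seq, revcomp(seq)):
            for hsp in _search(q, db.nucs, db.nuc_index,
                               params.seed_word_nt, nt_score, params.x_drop):
                if hsp.align_len < params.min_hsp_len:
                    continue
                ev = _evalue(params.K_nt, params.lambda_nt, len(seq),
                             db.total_nt, hsp.score)
                if ev <= params.evalue_cutoff:
                    cands.append((ev, -hsp.score, db.ids[hsp.ref_i], hsp, 1))
        best = _best_hit(cands)
        tier = TIER_NUCLEOTIDE
    if best is None:
        return HomologyHit(contig_id=contig_id, hit_id=None, taxon=None,
                           tier=TIER_NONE)
    ev, neg_score, hit_id, hsp, unit = best
    ref_i = db.ids.index(hit_id)
    return HomologyHit(
        contig_id=contig_id, hit_id=hit_id, taxon=db.taxa[ref_i], tier=tier,
        score=-neg_score, evalue=ev,
        identity=hsp.matches / hsp.align_len, align_len=hsp.align_len,
        ref_start=hsp.r_start * unit, ref_end=hsp.r_end * unit,
    )


def annotate_contigs(contigs: ContigSet,
                     reference: Sequence[TranscriptRecord],
                     params: AnnotationParams = AnnotationParams(),
                     db: Optional[ReferenceDB] = None) -> list[HomologyHit]:
    """One HomologyHit per contig (tier 'none' when nothing passes)."""
    params.validate()
    if db is None:
        db = ReferenceDB(reference, params)
    return [annotate_contig(c.sequence, c.id, db, params) for c in contigs]


# ---------------------------------------------------------------------------
# report arithmetic

def nonredundant_top_hits(hits: Iterable[HomologyHit]) -> dict[str, int]:
    """Distinct hit ids among reported hits, with per-id contig counts."""
    out: dict[str, int] = {}
    for h in hits:
        if h.hit_id is not None:
            out[h.hit_id] = out.get(h.hit_id, 0) + 1
    return out


def tier_counts(hits: Iterable[HomologyHit]) -> dict[str, int]:
    out = {TIER_TRANSLATED: 0, TIER_NUCLEOTIDE: 0, TIER_NONE: 0}
    for h in hits:
        out[h.tier] += 1
    return out


def overlap_summary(set_a: set, set_b: set) -> dict:
    """Shared/unique counts of two hit-id sets with percentages of the union
    (1 decimal)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    n_union = len(union)

    def pct(x: int) -> float:
        return round(100.0 * x / n_union, 1) if n_union else 0.0

    n_shared = len(a & b)
    n_a_only = len(a - b)
    n_b_only = len(b - a)
    return {
        "n_shared": n_shared, "n_a_only": n_a_only, "n_b_only": n_b_only,
        "n_union": n_union,
        "pct_shared": pct(n_shared),
        "pct_a_only": pct(n_a_only),
        "pct_b_only": pct(n_b_only),
    }


def taxon_distribution(hits: Iterable[HomologyHit]) -> pd.DataFrame:
    """Non-redundant hits grouped by taxon with percentages (2 decimals) of
    the total non-redundant hits."""
    taxon_of: dict[str, str] = {}
    for h in hits:
        if h.hit_id is not None:
            taxon_of[h.hit_id] = h.taxon
    total = len(taxon_of)
    counts: dict[str, int] = {}
    for t in taxon_of.values():
        counts[t] = counts.get(t, 0) + 1
    rows = [
        {"taxon": t, "n_nonredundant_hits": n,
         "pct": round(100.0 * n / total, 2) if total else 0.0}
        for t, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["taxon", "n_nonredundant_hits", "pct"])


def gene_set_recovery(hits: Iterable[HomologyHit],
                      groups: Mapping[str, str]) -> tuple[pd.DataFrame, int]:
    """Per-group homolog recovery: distinct group members with >= 1 hit and
    the percentage of the group size (2 decimals), plus a Total row.  Hit ids
    absent from ``groups`` are tallied as ungrouped (second return value)."""
    if not groups:
        raise ValueError("groups must be non-empty")
    group_sizes: dict[str, int] = {}
    for g in groups.values():
        group_sizes[g] = group_sizes.get(g, 0) + 1
    recovered: dict[str, set[str]] = {g: set() for g in group_sizes}
    ungrouped: set[str] = set()
    for h in hits:
        if h.hit_id is None:
            continue
        g = groups.get(h.hit_id)
        if g is None:
            ungrouped.add(h.hit_id)
        else:
            recovered[g].add(h.hit_id)
    rows = []
    for g in sorted(group_sizes):
        size = group_sizes[g]
        n_rec = len(recovered[g])
        rows.append({"gene_group": g, "n_genes": size, "n_recovered": n_rec,
                     "pct": round(100.0 * n_rec / size, 2)})
    total_size = sum(group_sizes.values())
    total_rec = sum(len(v) for v in recovered.values())
    rows.append({"gene_group": "Total", "n_genes": total_size,
                 "n_recovered": total_rec,
                 "pct": round(100.0 * total_rec / total_size, 2)})
    return (pd.DataFrame(rows, columns=["gene_group", "n_genes",
                                        "n_recovered", "pct"]),
            len(ungrouped))


Interval = tuple[int, int]


def reference_coverage(hits: Iterable[Union[HomologyHit, Interval]],
                       ref_len: int) -> tuple[int, int]:
    """Union length of aligned reference intervals (overlaps merged) and the
    percentage of ``ref_len`` rounded to the nearest integer.  Accepts
    HomologyHit objects (their ref_start/ref_end) or raw (start, end) pairs,
    0-based half-open."""
    if ref_len <= 0:
        raise ValueError("ref_len must be > 0")
    intervals: list[Interval] = []
    for h in hits:
        s, e = (h.ref_start, h.ref_end) if isinstance(h, HomologyHit) else h
        if s == e:
            continue
        if not (0 <= s < e <= ref_len):
            raise ValueError(f"interval ({s}, {e}) outside [0, {ref_len})")
        intervals.append((s, e))
    intervals.sort()
    covered = 0
    cur_s, cur_e = None, None
    for s, e in intervals:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    pct = round(100.0 * covered / ref_len)
    return covered, int(pct)
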