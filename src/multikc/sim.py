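"""Synthetic host/endosymbiont transcriptome and single-end read simulator.

The generator emulates the data structure an aphid-style RNA-seq experiment
produces: a polyadenylated host transcriptome with heavy-tailed (log-normal)
expression, a high-abundance AT-rich primary-endosymbiont fraction whose
transcripts lack polyA tails (and are therefore depleted by each round of
oligo-dT selection), and a rare secondary endosymbiont contributing only
short rRNA-like fragments.  Reads are fixed-length, single-end, sense-strand,
with an i.i.d. per-base substitution error model.

Randomness is consumed from four documented streams derived from the single
user seed, so any stage can be re-drawn independently by an oracle:

* ``default_rng([seed, 0])`` — abundance weights, one log-normal draw per
  transcript in record order (host block, then primary, then secondary);
  the primary-endosymbiont block is then multiplied by
  ``PRIMARY_ENDO_ABUNDANCE_BOOST``.
* ``default_rng([seed, 1])`` — transcript lengths (host, primary, secondary
  blocks in that order).
* ``default_rng([seed, 2])`` — sequences, transcript by transcript in record
  order; coding sequences are drawn codon-block-wise with rejection
  resampling of stop codons.
* ``default_rng([seed, 3])`` — reads: transcript indices, start positions,
  error mask, substitution offsets, in that order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .util import decode_codes

TAXON_HOST = "host"
TAXON_PRIMARY = "primary_endosymbiont"
TAXON_SECONDARY = "secondary_endosymbiont"

#: GC fraction used for host coding sequence (uniform composition).
HOST_GC = 0.50
#: GC fraction for endosymbiont sequence; obligate endosymbionts such as
#: Buchnera are strongly AT-rich, which makes the taxa separable by alignment.
ENDO_GC = 0.30
#: Constant multiplier applied to primary-endosymbiont abundance weights so
#: that, under a single round of polyA selection with the default per-round
#: retention, roughly 30% of reads derive from non-polyadenylated RNA.
PRIMARY_ENDO_ABUNDANCE_BOOST = 4.0

#: Host transcripts are assigned to a small cycle of functional gene groups so
#: gene-set recovery tables have something to count.
N_HOST_GENE_GROUPS = 8

_STOP_CODONS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA in 0..3 codes


@dataclass(frozen=True)
class TranscriptRecord:
    """One reference transcript with taxon and expression metadata."""

    id: str
    taxon: str
    sequence: str
    abundance_weight: float
    polyadenylated: bool
    gene_group: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 150:
            raise ValueError(f"sequence of {self.id!r} shorter than 150 nt")
        if not self.abundance_weight > 0:
            raise ValueError(f"abundance_weight of {self.id!r} must be > 0")


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic experiment.

    Defaults are desk-scale: tens of transcripts and tens of thousands of
    reads rather than the ~8 million reads per lane of a real GAII run.
    ``polyA_rounds=2`` mirrors the standard two-round oligo-dT protocol;
    set it to 1 to emulate the single-purification sample in which the
    endosymbiont fraction of the reads roughly triples.
    """

    seed: int
    n_host_transcripts: int = 40
    n_primary_endo_transcripts: int = 12
    n_secondary_endo_fragments: int = 4
    read_length: int = 75
    n_reads: int = 20_000
    error_rate: float = 0.005
    abundance_sigma: float = 1.5
    polyA_rounds: int = 2
    nonpolyA_retention_per_round: float = 0.5

    def validate(self) -> None:
        for name in ("n_host_transcripts", "n_primary_endo_transcripts",
                     "n_secondary_endo_fragments", "n_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.abundance_sigma <= 0:
            raise ValueError("abundance_sigma must be > 0")
        if self.polyA_rounds < 0:
            raise ValueError("polyA_rounds must be >= 0")
        if not 0.0 < self.nonpolyA_retention_per_round <= 1.0:
            raise ValueError("nonpolyA_retention_per_round must be in (0, 1]")


@dataclass(frozen=True)
class Read:
    """A fixed-length single-end read; ``truth_id`` is the source transcript
    when the read is synthetic."""

    id: str
    sequence: str
    quality: str
    truth_id: Optional[str] = None


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _draw_coding(rng: np.random.Generator, length: int, gc: float) -> str:
    """Draw an in-frame coding sequence of ``length`` nt (multiple of 3) with
    no stop codon in frame 0, by block draws with rejection resampling."""
    n_codons = length // 3
    probs = _base_probs(gc)
    codons = rng.choice(4, size=(n_codons, 3), p=probs)
    while True:
        bad = np.fromiter(
            (tuple(c) in _STOP_CODONS for c in codons), dtype=bool, count=n_codons
        )
        if not bad.any():
            break
        codons[bad] = rng.choice(4, size=(int(bad.sum()), 3), p=probs)
    return decode_codes(codons.reshape(-1).astype(np.uint8))


def _draw_plain(rng: np.random.Generator, length: int, gc: float) -> str:
    codes = rng.choice(4, size=length, p=_base_probs(gc))
    return decode_codes(codes.astype(np.uint8))


def generate_reference(params: SimulationParams) -> list[TranscriptRecord]:
    """Generate the labelled reference transcriptome for one experiment.

    Host transcripts are polyadenylated, in-frame coding, GC 0.50; primary
    endosymbiont transcripts are non-polyadenylated coding sequences at GC
    0.30 with boosted abundance; secondary endosymbiont records are short
    (150-800 nt) non-coding rRNA-like fragments.  Deterministic given seed.
    """
    params.validate()
    n_host = params.n_host_transcripts
    n_prim = params.n_primary_endo_transcripts
    n_sec = params.n_secondary_endo_fragments
    n_total = n_host + n_prim + n_sec
    if n_total == 0:
        return []

    rng_w = np.random.default_rng([params.seed, 0])
    weights = rng_w.lognormal(mean=0.0, sigma=params.abundance_sigma, size=n_total)
    weights[n_host:n_host + n_prim] *= PRIMARY_ENDO_ABUNDANCE_BOOST

    rng_l = np.random.default_rng([params.seed, 1])
    host_lens = rng_l.integers(100, 801, size=n_host) * 3      # 300..2400 nt
    prim_lens = rng_l.integers(100, 501, size=n_prim) * 3      # 300..1500 nt
    sec_lens = rng_l.integers(150, 801, size=n_sec)            # 150..800 nt

    rng_s = np.random.default_rng([params.seed, 2])
    records: list[TranscriptRecord] = []
    w = iter(weights)
    for i in range(n_host):
        records.append(TranscriptRecord(
            id=f"host_{i:04d}", taxon=TAXON_HOST,
            sequence=_draw_coding(rng_s, int(host_lens[i]), HOST_GC),
            abundance_weight=float(next(w)), polyadenylated=True,
            gene_group=f"grp{i % N_HOST_GENE_GROUPS + 1}",
        ))
    for i in range(n_prim):
        records.append(TranscriptRecord(
            id=f"pend_{i:04d}", taxon=TAXON_PRIMARY,
            sequence=_draw_coding(rng_s, int(prim_lens[i]), ENDO_GC),
            abundance_weight=float(next(w)), polyadenylated=False,
        ))
    for i in range(n_sec):
        records.append(TranscriptRecord(
            id=f"send_{i:04d}", taxon=TAXON_SECONDARY,
            sequence=_draw_plain(rng_s, int(sec_lens[i]), ENDO_GC),
            abundance_weight=float(next(w)), polyadenylated=False,
        ))
    return records


def retention(record: TranscriptRecord, params: SimulationParams) -> float:
    """Fraction of a transcript's molecules surviving polyA selection."""
    if record.polyadenylated:
        return 1.0
    return params.nonpolyA_retention_per_round ** params.polyA_rounds


def sampling_probabilities(
    reference: Sequence[TranscriptRecord], params: SimulationParams
) -> np.ndarray:
    """Normalised per-transcript read-sampling probabilities.

    Proportional to abundance_weight x length x retention: the weight is a
    molar (per-molecule) abundance and libraries sample fragments, so longer
    transcripts contribute proportionally more reads.  Per-nucleotide depth
    (reads x read_length / length) then estimates weight x retention.
    """
    raw = np.array([
        r.abundance_weight * len(r.sequence) * retention(r, params)
        for r in reference
    ])
    total = raw.sum()
    if total <= 0:
        raise ValueError("reference has no sampleable transcripts")
    return raw / total


def simulate_reads(
    reference: Sequence[TranscriptRecord], params: SimulationParams
) -> list[Read]:
    """Simulate fixed-length single-end reads from the reference.

    Each read: (1) transcript chosen with probability proportional to
    abundance_weight x length x retention (fragment-level sampling),
    (2) uniform start position, (3) i.i.d. per-base substitution at
    ``error_rate``.  Reads carry the truth transcript id.  Deterministic
    given seed.
    """
    params.validate()
    if params.n_reads == 0:
        return []
    if not reference:
        raise ValueError("cannot simulate reads from an empty reference")
    L = params.read_length
    for r in reference:
        if len(r.sequence) < L:
            raise ValueError(
                f"transcript {r.id!r} shorter than read_length {L}"
            )

    p = sampling_probabilities(reference, params)
    lens = np.array([len(r.sequence) for r in reference])
    codes = [np.frombuffer(r.sequence.encode(), dtype=np.uint8) for r in reference]
    # map ASCII -> 0..3 once per transcript
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    codes = [lut[c] for c in codes]

    rng = np.random.default_rng([params.seed, 3])
    idx = rng.choice(len(reference), size=params.n_reads, p=p)
    starts = rng.integers(0, lens[idx] - L + 1)
    err_mask = rng.random((params.n_reads, L)) < params.error_rate
    n_err = int(err_mask.sum())
    shifts = rng.integers(1, 4, size=n_err).astype(np.uint8)

    reads: list[Read] = []
    e = 0
    for j in range(params.n_reads):
        t = int(idx[j])
        s = int(starts[j])
        frag = codes[t][s:s + L].copy()
        mask = err_mask[j]
        k = int(mask.sum())
        if k:
            frag[mask] = (frag[mask] + shifts[e:e + k]) % 4
            e += k
        reads.append(Read(
            id=f"r{j:07d}",
            sequence=decode_codes(frag),
            quality="I" * L,
            truth_id=reference[t].id,
        ))
    return reads


# ---------------------------------------------------------------------------
# plain-text interchange

def reference_fasta_str(records: Iterable[TranscriptRecord]) -> str:
    """FASTA with taxon/group/polyA/weight metadata in the header."""
    out = []
    for r in records:
        group = r.gene_group if r.gene_group is not None else "NA"
        out.append(
            f">{r.id} taxon={r.taxon} group={group} "
            f"polyA={int(r.polyadenylated)} weight={r.abundance_weight!r}\n"
        )
        seq = r.sequence
        for i in range(0, len(seq), 70):
            out.append(seq[i:i + 70] + "\n")
    return "".join(out)


def write_reference_fasta(records: Iterable[TranscriptRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(reference_fasta_str(records))


def read_reference_fasta(path) -> list[TranscriptRecord]:
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = dict(tok.split("=", 1) for tok in rec.description.split()[1:])
        group = meta.get("group", "NA")
        records.append(TranscriptRecord(
            id=rec.id,
            taxon=meta["taxon"],
            sequence=str(rec.seq).upper(),
            abundance_weight=float(meta["weight"]),
            polyadenylated=bool(int(meta["polyA"])),
            gene_group=None if group == "NA" else group,
        ))
    return records


def fastq_str(reads: Iterable[Read]) -> str:
    out = []
    for r in reads:
        truth = f" truth={r.truth_id}" if r.truth_id is not None else ""
        out.append(f"@{r.id}{truth}\n{r.sequence}\n+\n{r.quality}\n")
    return "".join(out)


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        fh.write(fastq_str(reads))


def read_fastq(path) -> list[Read]:
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        truth = None
        for tok in rec.description.split()[1:]:
            if tok.startswith("truth="):
                truth = tok[len("truth="):]
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(Read(id=rec.id, sequence=str(rec.seq).upper(),
                          quality=qual, truth_id=truth))
    return reads
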