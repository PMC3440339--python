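# Methods

## Synthetic experiment

The generator emulates bulk RNA-seq of a host insect carrying two kinds of
bacterial endosymbiont, at a scale where every downstream stage can be
exercised and checked in seconds.

**Reference transcriptome.** Three transcript classes:

* *host* — polyadenylated, in-frame coding sequences (no stop codon in frame
  0), GC 0.50, lengths uniform on 300–2400 nt (multiples of 3). Each host
  transcript carries one of eight cyclic gene-group labels so that gene-set
  recovery tables have populated rows.
* *primary endosymbiont* — non-polyadenylated coding sequences at GC 0.30
  (obligate endosymbionts are strongly AT-rich, which is also what makes the
  taxa separable by alignment), lengths 300–1500 nt, with abundance weights
  multiplied by a constant boost of 4.0 (see polyA selection below).
* *secondary endosymbiont* — rare, short (150–800 nt) non-coding rRNA-like
  fragments, GC 0.30.

Abundance weights are log-normal(0, σ) with σ = 1.5 by default; the weight
is a *molar* abundance. Composition is i.i.d. within the GC constraint; no
codon-usage or secondary-structure realism is attempted.

**Read sampling.** Reads are fixed-length (75 nt), single-end, sense-strand.
A read picks its transcript with probability proportional to
`weight × length × retention` — fragment-level sampling, as in a real
library, so that per-nucleotide depth (reads × 75 / length) estimates
`weight × retention`; a length-independent rule would make depth inversely
confounded with transcript length and no depth statistic could recover the
expression ranking. Start positions are uniform; errors are i.i.d.
substitutions (default rate 0.005, a typical short-read scale). No indels —
the downstream mapper counts mismatches only — and no quality modelling
(nothing consumes qualities; FASTQ carries a constant placeholder).

**polyA selection.** Each round of oligo-dT purification retains a fraction
(default 0.5) of every non-polyadenylated molecule; polyadenylated molecules
are unaffected. With the default class sizes (40 host / 12 primary / 4
secondary) the boost of 4.0 is calibrated so that a *single* selection round
leaves ≈30% of reads without a polyA source in expectation — the signature
of a protocol that under-purifies — while the standard two rounds leave
≈15%. Realised fractions vary substantially across seeds because a
log-normal sum over 12 transcripts has heavy tails; the exact-expectation
property is tested on a constructed equal-length reference where both
readings of the sampling rule coincide.

**Determinism.** All randomness flows from four documented `numpy`
Generator streams derived from the one seed (`[seed, 0]` weights, `[seed,
1]` lengths, `[seed, 2]` sequences, `[seed, 3]` reads), so any stage can be
re-drawn independently by a test oracle, and identical configurations yield
byte-identical FASTA/FASTQ/report output.

**What passing tests do not show.** The generator has no splice isoforms, no
gene families with shared domains, no coverage bias (5′/3′, GC), no indels
and no strand ambiguity in the reads; real libraries have all of these, so
results here demonstrate the pipeline's correctness and direction-of-effect
properties, not genome-scale performance.

## Assembly

A bidirected de Bruijn graph over canonical k-mers (k odd, so no k-mer is
its own reverse complement; canonical form = lexicographic min of k-mer and
reverse complement). Node multiplicity counts read k-mer occurrences; edges
record consecutive read k-mers with strand, each stored with its
reverse-complement twin.

Pipeline per (k, C) cell: coverage cutoff (*remove nodes with multiplicity ≤
C*, i.e. survival requires > C, the Velvet `cov_cutoff` convention) → tip
clipping → unitig compression → length filter (≥ 100 nt). Tips are dead-end
unitigs shorter than `2k` whose mean multiplicity is below the graph median;
clipping iterates to a fixed point. No bubble popping and no scaffolding:
the unitig decomposition is the honest desk-scale output, and every reported
contig is a walk in the post-cutoff graph. Contig orientation is the
lexicographically smaller strand; contigs are ordered by (length desc,
sequence) and given ids `{sample}_k{k}_C{C}_{serial}`, so assembly is a pure
function of the input. The k-mer graph is built once per k and shared across
C values (the cutoff never mutates it), which is what keeps the 4×2 grid
cheap.

## Redundancy depletion

Greedy incremental clustering in length order (ties: id): a contig joins the
first existing cluster whose representative shares an exact `word_size`
(default 8) seed and aligns at identity ≥ 0.95, else founds a cluster.
Identity uses the shorter sequence's span as denominator —
`(len_short − edit_distance) / len_short` under an end-free (infix)
alignment of the shorter into the longer, both strands, computed with edlib
— so contained fragments collapse into longer contigs, which is what drives
the large (≈85%) reductions when per-cell assemblies of the same reads are
pooled. With identity 0.95 the word filter is lossless for contigs ≥ 100 nt
(≥ 5 mismatches would be needed to destroy every 8-mer seed window of the
shortest allowed contig only if spaced closer than the pigeonhole bound
permits); the test suite checks the filtered clustering against an
exhaustive no-filter oracle.

## Read-back mapping and abundance

Each read is assigned to at most one contig: the minimum-mismatch placement
within 3 mismatches over both strands, ties broken by (mismatches, contig
id, position, forward strand). Counting is single-best, with no fractional
multi-mapping weights and deliberately no RPKM-style normalisation — with no
genome there is no exon model, and per-nucleotide depth is the abundance
statistic:

    depth = reads assembled × read length / contig length

truncated to 2 decimals (the convention of the printed abundance tables this
reproduces; the unrounded value is exactly linear in the read count).
Ranking uses dense ranks on read counts; the top-N table also reports the
max/min fold range of the listed counts (1 decimal).

Mapping is seed-and-verify with exact 18-nt seeds tiled across the read plus
a final flush seed. 75 // 18 = 4 disjoint windows, so any placement with ≤ 3
mismatches contains an exact seed: at the default limit the seeded search is
provably equivalent to the brute-force scan. Whenever the seeded best cannot
be certified (shorter reads, larger limits), a complete scan of all contigs,
positions and strands runs instead; the suite asserts exact agreement with
an exhaustive oracle.

## Homology annotation

A two-tier cascade with a strict top-hit policy. Tier 1 translates the
contig in six frames and searches the *protein view* of the reference —
frame-0 peptides of the coding records only. Records whose frame-0
translation contains a stop are non-coding (the rRNA-like fragments) and are
excluded from the protein view: a protein database has no rRNA entries,
which is exactly why secondary-endosymbiont rRNA is detectable only at the
nucleotide tier. Seeding uses exact 4-aa words, extension is ungapped with
BLOSUM62 and X-drop 20. Tier 2 (contigs with no passing translated hit)
repeats the search on nucleotides, both strands, 11-nt words, +2/−3.

E-values use the ungapped Karlin–Altschul form `E = K·m·n·exp(−λS)` with
published ungapped constants (protein λ = 0.3176, K = 0.134; nucleotide
λ = 1.28, K = 0.46), m the query length and n the database size. A hit is
reported only if E ≤ 1e−3 and the HSP spans ≥ 33 residues/nt; the best hit
is the lowest e-value (ties: higher score, then id). The constants are
configuration, not fitted: any calibration honouring the cutoff semantics
gives the same top-hit sets on this data.

Coordinates are 0-based half-open internally; the reference interval of a
translated hit is converted to nucleotide coordinates (×3) so interval
coverage is uniform across tiers. The report arithmetic (non-redundant
counting on exact hit ids, overlap percentages to 1 decimal of the union,
taxon and gene-set percentages to 2 decimals, reference coverage rounded to
the nearest integer percent) is plain arithmetic, tested against plain
arithmetic.

## Study conditions used by the acceptance checks

* **Merged-grid gain**: 30 host / 6 primary / 2 secondary transcripts,
  20,000 reads, σ = 2.0, error 0.02, grid {21, 25, 31} × {2, 6}, 10
  replicates. These sizes put the two failure modes in play simultaneously:
  at 2% error the hottest transcripts carry error k-mers above C = 2 (their
  unitigs shatter below the 100 nt floor) while the rarest sit below C = 6.
  Merged recovery is ≥ the best single cell in every replicate and strictly
  larger in aggregate (observed ≈ +4%; the genome-scale analogue of this
  direction-of-effect is much larger because real transcriptomes span a far
  wider dynamic range).
* **Abundance recovery**: default simulator parameters, the stringent cell
  (k = 31, C = 6), 10 replicates. Over transcripts recovered 1:1 as
  near-full-length single contigs (one annotated contig covering ≥ 90% of
  the transcript — a fragment is not the transcript recovered as a single
  contig, and its depth is not an abundance estimate), Spearman rank
  correlation between `weight × retention` and estimated depth is ≥ 0.8 in
  every replicate (observed ≥ 0.96).
* **Demo envelope**: two samples × 25,000 reads under the default 4×2 grid
  complete, end to end with reports, in well under ten minutes on one CPU
  (observed ≈ 1 minute).

## Known limitations

Pure-Python assembly and annotation scale to tens of thousands of reads and
tens of contig-kilobases, not to lane-scale data. The assembler performs no
error correction beyond cutoff + tip clipping, so at permissive C the
abundant-transcript shattering that motivates the multi-C grid is also a
limitation of the assembler itself. The e-value calibration is nominal
(ungapped constants applied to a seeded heuristic search), adequate for
top-hit selection against a labelled reference but not comparable to
BLAST-reported e-values. `n_reads_assembled` on contigs is filled by the
mapping stage; contigs straight out of the assembler carry 0.
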