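#!/usr/bin/env python
"""Map each sample's reads back to its merged contigs and rank contigs by
depth of coverage (reads x 75 / contig length).

Reads results/sim/ and results/assembly/, writes results/abundance/: the full
per-contig abundance table and the top-10 table with its fold range.
"""

from pathlib import Path

import pandas as pd

from multikc.assembly import contigs_from_fasta
from multikc.mapping import abundance_records, map_reads, top_n_table
from multikc.sim import read_fastq

OUT = Path("results/abundance")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name in ("gut", "wa"):
        reads = read_fastq(Path("results/sim") / f"reads_{name}.fastq")
        contigs = contigs_from_fasta(Path("results/assembly") / f"contigs_{name}.fasta")
        result = map_reads(reads, contigs)
        records = abundance_records(result, contigs)
        df = pd.DataFrame([r.__dict__ for r in records])
        df.to_csv(OUT / f"abundance_{name}.tsv", sep="\t", index=False)
        top = top_n_table(records, 10)
        pd.DataFrame([r.__dict__ for r in top.records]).to_csv(
            OUT / f"top10_{name}.tsv", sep="\t", index=False)
        print(f"{name}: {result.n_mapped}/{len(reads)} reads mapped "
              f"({100 * result.n_mapped / len(reads):.1f}%); top-10 read "
              f"counts span a {top.fold_range:g}-fold range")


if __name__ == "__main__":
    main()
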