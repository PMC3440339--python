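#!/usr/bin/env python
"""Annotate each sample's merged contigs by the cascade translated /
nucleotide top-hit search against the labelled reference, then compute the
taxon distribution, the host gene-set recovery, the two-sample hit overlap,
and the secondary-endosymbiont rRNA reference coverage.

Reads results/sim/ and results/assembly/, writes results/annotation/.
"""

from pathlib import Path

import pandas as pd

from multikc.annotate import (AnnotationParams, ReferenceDB, annotate_contigs,
                              gene_set_recovery, nonredundant_top_hits,
                              overlap_summary, reference_coverage,
                              taxon_distribution, tier_counts)
from multikc.assembly import contigs_from_fasta
from multikc.sim import read_reference_fasta

OUT = Path("results/annotation")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    reference = read_reference_fasta("results/sim/reference.fasta")
    groups = {r.id: r.gene_group for r in reference if r.gene_group}
    db = ReferenceDB(reference, AnnotationParams())
    nonred = {}
    all_hits = {}
    for name in ("gut", "wa"):
        contigs = contigs_from_fasta(Path("results/assembly") / f"contigs_{name}.fasta")
        hits = annotate_contigs(contigs, reference, AnnotationParams(), db=db)
        all_hits[name] = hits
        pd.DataFrame([h.__dict__ for h in hits]).to_csv(
            OUT / f"hits_{name}.tsv", sep="\t", index=False)
        tiers = tier_counts(hits)
        nonred[name] = set(nonredundant_top_hits(hits))
        taxon_distribution(hits).to_csv(OUT / f"taxa_{name}.tsv", sep="\t",
                                        index=False)
        recovery, _ = gene_set_recovery(hits, groups)
        recovery.to_csv(OUT / f"gene_set_recovery_{name}.tsv", sep="\t",
                        index=False)
        total_pct = recovery.loc[recovery.gene_group == "Total", "pct"].iloc[0]
        print(f"{name}: tiers {tiers}; {len(nonred[name])} non-redundant hits; "
              f"host gene-set recovery {total_pct}%")

    ov = overlap_summary(nonred["gut"], nonred["wa"])
    pd.DataFrame([ov]).to_csv(OUT / "overlap.tsv", sep="\t", index=False)
    print(f"overlap: {ov['n_shared']} shared ({ov['pct_shared']}% of the "
          f"{ov['n_union']} union), {ov['n_a_only']} gut-only, "
          f"{ov['n_b_only']} wa-only")

    # secondary-endosymbiont rRNA coverage from the wa nucleotide-tier hits
    rows = []
    for frag in (r for r in reference if r.taxon == "secondary_endosymbiont"):
        ivals = [h for h in all_hits["wa"]
                 if h.hit_id == frag.id and h.tier == "nucleotide"]
        covered, pct = reference_coverage(ivals, len(frag.sequence))
        rows.append({"fragment": frag.id, "ref_len": len(frag.sequence),
                     "covered_nt": covered, "pct": pct,
                     "n_contigs": len(ivals)})
    cov = pd.DataFrame(rows)
    cov.to_csv(OUT / "rrna_coverage_wa.tsv", sep="\t", index=False)
    print(cov.to_string(index=False))


if __name__ == "__main__":
    main()
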