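"""Cascade homology annotation and the counting/percentage arithmetic."""

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

import _oracles as oracle
from conftest import make_contigs, random_seq
from multikc.annotate import (AnnotationParams, HomologyHit, ReferenceDB,
                              annotate_contigs, gene_set_recovery,
                              nonredundant_top_hits, overlap_summary,
                              reference_coverage, six_frame_translations,
                              taxon_distribution, tier_counts)
from multikc.sim import SimulationParams, generate_reference
from multikc.util import revcomp


@pytest.fixture(scope="module")
def reference():
    params = SimulationParams(seed=42, n_host_transcripts=10,
                              n_primary_endo_transcripts=3,
                              n_secondary_endo_fragments=2)
    return generate_reference(params)


@pytest.fixture(scope="module")
def db(reference):
    return ReferenceDB(reference, AnnotationParams())


def _mutate(rng, seq, rate):
    s = list(seq)
    for i in range(len(s)):
        if rng.random() < rate:
            s[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[i]]
    return "".join(s)


def test_identical_contig_hits_translated_tier_with_full_identity(reference, db):
    target = reference[0]
    contigs = make_contigs([target.sequence])
    hits = annotate_contigs(contigs, reference, AnnotationParams(), db=db)
    h = hits[0]
    assert h.tier == "translated"
    assert h.hit_id == target.id
    assert h.taxon == target.taxon
    assert h.identity == pytest.approx(1.0)


def test_unrelated_contig_has_no_hit(reference, db, rng):
    contigs = make_contigs([random_seq(rng, 150)])
    hits = annotate_contigs(contigs, reference, AnnotationParams(), db=db)
    assert hits[0].tier == "none" and hits[0].hit_id is None


def test_rrna_like_fragment_falls_through_to_nucleotide_tier(reference, db):
    frag = next(r for r in reference if r.taxon == "secondary_endosymbiont")
    contigs = make_contigs([frag.sequence[10:160], revcomp(frag.sequence[20:200])])
    hits = annotate_contigs(contigs, reference, AnnotationParams(), db=db)
    assert all(h.tier == "nucleotide" and h.hit_id == frag.id for h in hits)


def test_top_hits_match_exhaustive_alignment_oracle(reference, db, rng):
    """30 mutated substrings of known transcripts: the reported top hit must
    be the truth transcript, and must agree with an exhaustive full local
    alignment over all reference peptides and all six frames."""
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -1000.0
    aligner.extend_gap_score = -1000.0

    coding = [r for r in reference if r.taxon != "secondary_endosymbiont"]
    seqs, truths = [], []
    for i in range(30):
        t = coding[i % len(coding)]
        start = int(rng.integers(0, max(len(t.sequence) - 300, 1)))
        seqs.append(_mutate(rng, t.sequence[start:start + 300], 0.01))
        truths.append(t.id)
    contigs = make_contigs(seqs)
    hits = annotate_contigs(contigs, reference, AnnotationParams(), db=db)

    from Bio.Seq import Seq

    pep_db = {r.id: str(Seq(r.sequence[:len(r.sequence) - len(r.sequence) % 3]
                            ).translate())
              for r in coding}
    for h, seq, truth in zip(hits, seqs, truths):
        assert h.hit_id == truth
        best_ref, best_score = None, -1.0
        for pep, _, _ in six_frame_translations(seq):
            for rid, rpep in pep_db.items():
                score = aligner.score(pep.replace("*", "X"), rpep)
                if score > best_score:
                    best_ref, best_score = rid, score
        assert h.hit_id == best_ref


def test_cascade_tiers_partition_the_contig_set(reference, db, rng):
    host = next(r for r in reference if r.taxon == "host")
    frag = next(r for r in reference if r.taxon == "secondary_endosymbiont")
    contigs = make_contigs([host.sequence[:200], frag.sequence[:150],
                            random_seq(rng, 150)])
    hits = annotate_contigs(contigs, reference, AnnotationParams(), db=db)
    counts = tier_counts(hits)
    assert counts == {"translated": 1, "nucleotide": 1, "none": 1}
    assert sum(counts.values()) == len(contigs)


def test_annotation_precision_on_long_contigs(reference, db):
    """Top hit equals the truth transcript for >= 95% of 300+ nt contigs at
    default cutoffs, over 10 replicates."""
    correct = total = 0
    for rep in range(10):
        rng = np.random.default_rng(100 + rep)
        seqs, truths = [], []
        for r in reference:
            if len(r.sequence) < 375:
                continue
            start = int(rng.integers(0, len(r.sequence) - 320))
            seqs.append(_mutate(rng, r.sequence[start:start + 320], 0.01))
            truths.append(r.id)
        hits = annotate_contigs(make_contigs(seqs), reference,
                                AnnotationParams(), db=db)
        for h, truth in zip(hits, truths):
            if h.hit_id is not None:
                total += 1
                correct += h.hit_id == truth
    assert total > 0
    assert correct / total >= 0.95


def test_nonredundant_counting():
    hits = [HomologyHit(f"c{i}", "refA", "host", "translated") for i in range(5)]
    assert nonredundant_top_hits(hits) == {"refA": 5}
    assert nonredundant_top_hits([]) == {}


def test_nonredundant_matches_set_oracle(rng):
    ids = [f"ref{int(i)}" for i in rng.integers(0, 12, size=60)]
    hits = [HomologyHit(f"c{j}", hid, "host", "translated")
            for j, hid in enumerate(ids)]
    nr = nonredundant_top_hits(hits)
    assert set(nr) == set(ids)
    assert sum(nr.values()) == len(ids)


def test_overlap_percentages_of_printed_hit_counts():
    """Shared/unique non-redundant hit percentages of the two-sample
    comparison: 9,244 shared, 1,396 gut-only, 5,617 whole-aphid-only."""
    a = {f"s{i}" for i in range(9244)} | {f"a{i}" for i in range(1396)}
    b = {f"s{i}" for i in range(9244)} | {f"b{i}" for i in range(5617)}
    ov = overlap_summary(a, b)
    assert ov["n_union"] == 16257
    assert ov["pct_shared"] == 56.9
    assert ov["pct_a_only"] == 8.6
    assert ov["pct_b_only"] == 34.6


def test_overlap_identical_sets_is_fully_shared():
    ov = overlap_summary({"x", "y"}, {"x", "y"})
    assert ov["pct_shared"] == 100.0 and ov["n_a_only"] == 0


def test_overlap_matches_set_algebra_oracle(rng):
    a = {int(x) for x in rng.integers(0, 50, size=30)}
    b = {int(x) for x in rng.integers(0, 50, size=30)}
    ov = overlap_summary(a, b)
    assert ov["n_shared"] == len(a & b)
    assert ov["n_a_only"] == len(a - b)
    assert ov["n_b_only"] == len(b - a)
    assert ov["n_union"] == len(a | b)


def _hits_for_taxa(spec):
    hits = []
    i = 0
    for taxon, n in spec.items():
        for j in range(n):
            hits.append(HomologyHit(f"c{i}", f"{taxon}_{j}", taxon, "translated"))
            i += 1
    return hits


def test_taxon_distribution_top_species_percentage():
    """8,730 of 10,640 non-redundant hits to the dominant species = 82.05%."""
    hits = _hits_for_taxa({"A": 8730, "other": 10640 - 8730})
    df = taxon_distribution(hits)
    assert float(df.loc[df.taxon == "A", "pct"].iloc[0]) == 82.05


def test_taxon_distribution_single_taxon_and_sum(rng):
    df = taxon_distribution(_hits_for_taxa({"only": 7}))
    assert float(df.pct.iloc[0]) == 100.00
    spec = {f"t{i}": int(n) for i, n in enumerate(rng.integers(1, 40, size=6))}
    df = taxon_distribution(_hits_for_taxa(spec))
    assert abs(df.pct.sum() - 100.0) <= 0.05
    for t, n in spec.items():
        expected = round(100.0 * n / sum(spec.values()), 2)
        assert float(df.loc[df.taxon == t, "pct"].iloc[0]) == expected


def _recovery_fixture(group_sizes, recovered_counts):
    groups, hits = {}, []
    for g, (size, rec) in enumerate(zip(group_sizes, recovered_counts)):
        for i in range(size):
            gid = f"g{g}_m{i}"
            groups[gid] = f"group{g}"
            if i < rec:
                hits.append(HomologyHit(f"c_{gid}", gid, "host", "translated"))
    return hits, groups


def test_gene_set_recovery_printed_percentages():
    """45 of 47 amino-acid-transporter-sized group = 95.74%; totals
    1,145 of 1,430 = 80.07%."""
    hits, groups = _recovery_fixture([47, 1383], [45, 1100])
    df, n_ungrouped = gene_set_recovery(hits, groups)
    assert n_ungrouped == 0
    assert float(df.loc[df.gene_group == "group0", "pct"].iloc[0]) == 95.74
    total = df.loc[df.gene_group == "Total"].iloc[0]
    assert int(total.n_genes) == 1430 and int(total.n_recovered) == 1145
    assert float(total.pct) == 80.07


def test_gene_set_recovery_no_hits_and_ungrouped():
    _, groups = _recovery_fixture([5, 3], [0, 0])
    df, _ = gene_set_recovery([], groups)
    assert (df.loc[df.gene_group != "Total", "pct"] == 0.0).all()
    hits = [HomologyHit("c0", "not_in_any_group", "host", "translated")]
    df, n_ungrouped = gene_set_recovery(hits, groups)
    assert n_ungrouped == 1


def test_reference_coverage_printed_16s_percentage():
    """1,070 nt covered of a 1,505 nt rRNA reference = 71%."""
    covered, pct = reference_coverage([(0, 1070)], 1505)
    assert (covered, pct) == (1070, 71)


def test_reference_coverage_full_and_merging(rng):
    assert reference_coverage([(0, 500)], 500) == (500, 100)
    intervals = [(int(a), int(a) + int(b)) for a, b in
                 zip(rng.integers(0, 900, 20), rng.integers(1, 100, 20))]
    intervals = [(s, min(e, 1000)) for s, e in intervals]
    covered, pct = reference_coverage(intervals, 1000)
    expected = oracle.interval_union_mask(intervals, 1000)
    assert covered == expected
    assert pct == round(100.0 * expected / 1000)


def test_reference_coverage_out_of_range_interval_is_error():
    with pytest.raises(ValueError, match="outside"):
        reference_coverage([(10, 2000)], 1505)


def test_empty_reference_is_an_input_error():
    with pytest.raises(ValueError, match="non-empty"):
        ReferenceDB([], AnnotationParams())
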