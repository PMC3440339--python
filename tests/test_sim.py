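"""Synthetic transcriptome and read simulator."""

import numpy as np
import pytest
from scipy import stats

from conftest import make_transcript, random_seq
from multikc.sim import (PRIMARY_ENDO_ABUNDANCE_BOOST, SimulationParams,
                         fastq_str, generate_reference, read_fastq,
                         read_reference_fasta, reference_fasta_str,
                         sampling_probabilities, simulate_reads, write_fastq,
                         write_reference_fasta)


def test_all_counts_zero_gives_empty_reference():
    params = SimulationParams(seed=1, n_host_transcripts=0,
                              n_primary_endo_transcripts=0,
                              n_secondary_endo_fragments=0)
    assert generate_reference(params) == []


def test_reference_and_reads_deterministic_given_seed():
    params = SimulationParams(seed=11, n_host_transcripts=5,
                              n_primary_endo_transcripts=2,
                              n_secondary_endo_fragments=1, n_reads=200)
    ref_a, ref_b = generate_reference(params), generate_reference(params)
    assert reference_fasta_str(ref_a) == reference_fasta_str(ref_b)
    reads_a = simulate_reads(ref_a, params)
    reads_b = simulate_reads(ref_b, params)
    assert fastq_str(reads_a) == fastq_str(reads_b)


def test_abundance_weights_match_independent_redraw_of_documented_stream():
    """Weights come from stream [seed, 0], one log-normal draw per transcript
    in record order, with the primary-endosymbiont block boosted."""
    params = SimulationParams(seed=7, n_host_transcripts=50,
                              n_primary_endo_transcripts=10,
                              n_secondary_endo_fragments=3,
                              abundance_sigma=1.5)
    ref = generate_reference(params)
    expected = np.random.default_rng([7, 0]).lognormal(0.0, 1.5, size=63)
    expected[50:60] *= PRIMARY_ENDO_ABUNDANCE_BOOST
    got = np.array([r.abundance_weight for r in ref])
    np.testing.assert_allclose(got, expected, rtol=1e-12)


@pytest.mark.parametrize("field,value", [
    ("read_length", 10),
    ("error_rate", 0.5),
    ("n_reads", -1),
    ("nonpolyA_retention_per_round", 0.0),
    ("polyA_rounds", -2),
    ("abundance_sigma", 0.0),
])
def test_invalid_params_error_names_offending_field(field, value):
    params = SimulationParams(seed=1, **{field: value})
    with pytest.raises(ValueError, match=field.split("_")[0]):
        params.validate()


def test_error_free_reads_are_exact_substrings_with_truth_labels(rng):
    t = make_transcript("tx1", random_seq(rng, 400))
    params = SimulationParams(seed=3, n_reads=300, error_rate=0.0)
    reads = simulate_reads([t], params)
    assert len(reads) == 300
    for r in reads:
        assert r.truth_id == "tx1"
        assert r.sequence in t.sequence


def test_reads_from_empty_reference_is_an_error():
    with pytest.raises(ValueError, match="empty reference"):
        simulate_reads([], SimulationParams(seed=1, n_reads=10))


def test_read_split_converges_to_weight_ratio_within_binomial_bounds(rng):
    """Equal-length transcripts, weights 1 and 3, full retention: the read
    split follows Binomial(n, 3/4)."""
    a = make_transcript("a", random_seq(rng, 500), weight=1.0)
    b = make_transcript("b", random_seq(rng, 500), weight=3.0)
    n = 20_000
    reads = simulate_reads([a, b], SimulationParams(seed=5, n_reads=n))
    n_b = sum(1 for r in reads if r.truth_id == "b")
    lo, hi = stats.binom.interval(0.99, n, 0.75)
    assert lo <= n_b <= hi


def test_single_polya_round_yields_thirty_percent_nonpolya_reads(rng):
    """Retention 3/7 over one selection round on an equal-weight,
    equal-length host/endosymbiont pair gives an expected non-polyA read
    fraction of exactly 0.30; the empirical fraction at 100k reads must be
    within 3 percentage points."""
    host = make_transcript("h", random_seq(rng, 500), weight=1.0, polya=True)
    endo = make_transcript("e", random_seq(rng, 500, gc=0.3), weight=1.0,
                           taxon="primary_endosymbiont", polya=False)
    params = SimulationParams(seed=9, n_reads=100_000, polyA_rounds=1,
                              nonpolyA_retention_per_round=3 / 7)
    p = sampling_probabilities([host, endo], params)
    assert p[1] == pytest.approx(0.30, abs=1e-12)
    reads = simulate_reads([host, endo], params)
    frac = sum(1 for r in reads if r.truth_id == "e") / len(reads)
    assert abs(frac - 0.30) < 0.03


def test_read_fractions_pass_chisquare_goodness_of_fit(rng):
    """Empirical per-transcript read fractions converge to the normalised
    weight x length x retention distribution (alpha = 0.01)."""
    ref = [make_transcript(f"t{i}", random_seq(rng, 400), weight=w)
           for i, w in enumerate([0.2, 0.5, 1.0, 1.0, 2.0, 3.0, 5.0, 10.0])]
    params = SimulationParams(seed=13, n_reads=100_000)
    p = sampling_probabilities(ref, params)
    reads = simulate_reads(ref, params)
    counts = {t.id: 0 for t in ref}
    for r in reads:
        assert r.truth_id in counts       # truth labels exist in the reference
        counts[r.truth_id] += 1
    observed = np.array([counts[t.id] for t in ref])
    res = stats.chisquare(observed, f_exp=p * params.n_reads)
    assert res.pvalue > 0.01


def test_fasta_and_fastq_roundtrip(tmp_path):
    params = SimulationParams(seed=21, n_host_transcripts=3,
                              n_primary_endo_transcripts=2,
                              n_secondary_endo_fragments=1, n_reads=50)
    ref = generate_reference(params)
    write_reference_fasta(ref, tmp_path / "ref.fasta")
    assert read_reference_fasta(tmp_path / "ref.fasta") == ref
    reads = simulate_reads(ref, params)
    write_fastq(reads, tmp_path / "reads.fastq")
    assert read_fastq(tmp_path / "reads.fastq") == reads


def test_reference_composition_and_polya_flags():
    params = SimulationParams(seed=2, n_host_transcripts=4,
                              n_primary_endo_transcripts=3,
                              n_secondary_endo_fragments=2)
    ref = generate_reference(params)
    assert len(ref) == 9
    hosts = [r for r in ref if r.taxon == "host"]
    prim = [r for r in ref if r.taxon == "primary_endosymbiont"]
    sec = [r for r in ref if r.taxon == "secondary_endosymbiont"]
    assert (len(hosts), len(prim), len(sec)) == (4, 3, 2)
    assert all(r.polyadenylated for r in hosts)
    assert all(not r.polyadenylated for r in prim + sec)
    assert all(150 <= len(r.sequence) <= 800 for r in sec)
    assert len({r.id for r in ref}) == 9
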