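import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nbckit import fixtures
from nbckit.kmer_core import (
    ClassificationResult,
    EmptyProfileError,
    build_profile,
    classify_read,
    classify_reads,
    extract_kmers,
    kmer_log_probability,
    reverse_complement,
    score_read,
)


class FakeDB:
    def __init__(self, profiles):
        self.profiles = profiles
        self.n = next(iter(profiles.values())).n if profiles else 0


dna = st.text(alphabet="ACGT", min_size=0, max_size=60)


@pytest.mark.parametrize(
    "seq, n, expected",
    [
        ("ACGNT", 2, ["AC", "CG"]),  # windows touching N are skipped
        ("ACG", 5, []),
        ("AAAA", 2, ["AA", "AA", "AA"]),
        ("acgt", 2, ["AC", "CG", "GT"]),  # lowercase accepted
        ("NNNN", 1, []),
    ],
)
def test_extract_kmers_windows(seq, n, expected):
    assert extract_kmers(seq, n) == expected


def test_extract_kmers_rejects_nonpositive_n():
    with pytest.raises(ValueError):
        extract_kmers("ACGT", 0)


@given(dna, st.integers(min_value=1, max_value=6))
def test_window_count_on_clean_sequences(seq, n):
    assert len(extract_kmers(seq, n)) == max(len(seq) - n + 1, 0)


@pytest.mark.parametrize(
    "seq, expected",
    [("ACGT", "ACGT"), ("AAAC", "GTTT"), ("AN", "NT")],
)
def test_reverse_complement(seq, expected):
    assert reverse_complement(seq) == expected


def test_reverse_complement_rejects_bad_alphabet():
    with pytest.raises(ValueError):
        reverse_complement("ACGU")


@given(dna)
def test_reverse_complement_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


@pytest.mark.parametrize(
    "sequences, strand, expected_counts, expected_total",
    [
        (["ACGTACGT"], "given", {"AC": 2, "CG": 2, "GT": 2, "TA": 1}, 7),
        (["ACG", "ACG"], "given", {"AC": 2, "CG": 2}, 4),
        (["AA"], "both", {"AA": 1, "TT": 1}, 2),
    ],
)
def test_build_profile_counts(sequences, strand, expected_counts, expected_total):
    p = build_profile("t1", sequences, 2, strand_policy=strand)
    assert p.counts == expected_counts
    assert p.total == expected_total
    assert p.total == sum(p.counts.values())
    assert p.source_bp >= p.total


def test_build_profile_requires_one_long_enough_sequence():
    with pytest.raises(EmptyProfileError):
        build_profile("t1", ["ACG"], 4)


def test_kmer_log_probability_values():
    p = build_profile("t1", ["ACGTACGT"], 2)
    assert kmer_log_probability(p, "AC", alpha=1) == pytest.approx(math.log(3 / 23))
    assert kmer_log_probability(p, "GG", alpha=0) == -math.inf
    uniform = build_profile("u", ["".join(k) for k in itertools.product("ACGT", repeat=2)], 2)
    assert uniform.total == 16
    assert kmer_log_probability(uniform, "TT", alpha=0) == pytest.approx(math.log(1 / 16))


def test_kmer_log_probability_rejects_bad_input():
    p = build_profile("t1", ["ACGTACGT"], 2)
    with pytest.raises(ValueError):
        kmer_log_probability(p, "AC", alpha=-0.5)
    with pytest.raises(ValueError):
        kmer_log_probability(p, "ACG", alpha=1)
    with pytest.raises(ValueError):
        kmer_log_probability(p, "AX", alpha=1)


def test_score_read_sums_window_log_probabilities():
    p = build_profile("t1", ["ACGTACGT"], 2)
    score, n_kmers = score_read("ACG", p, alpha=1)
    assert n_kmers == 2
    assert score == pytest.approx(2 * math.log(3 / 23))


def test_training_sequence_scores_higher_on_its_own_profile():
    seq = "ACGTACGTAC"
    own = build_profile("own", [seq], 2)
    disjoint = build_profile("other", ["GGGGGGGGGG"], 2)
    s_own = score_read(seq, own, alpha=1).log_likelihood
    s_disjoint = score_read(seq, disjoint, alpha=1).log_likelihood
    expected = sum(kmer_log_probability(own, k, 1) for k in extract_kmers(seq, 2))
    assert s_own == pytest.approx(expected)
    assert s_own > s_disjoint


def test_all_ambiguous_read_is_unscoreable():
    p = build_profile("t1", ["ACGTACGT"], 2)
    assert score_read("NNNN", p, alpha=1) == (None, 0)


def test_max_of_strands_takes_the_better_orientation():
    p = build_profile("t1", ["AAAAAAAA"], 2)
    fwd = score_read("TTTT", p, alpha=1, strand_policy="forward").log_likelihood
    both = score_read("TTTT", p, alpha=1, strand_policy="max_of_strands").log_likelihood
    assert both > fwd
    assert both == pytest.approx(score_read("AAAA", p, alpha=1).log_likelihood)


def test_probability_normalization_sums_to_one(rng):
    for n in (2, 3, 4):
        genome = fixtures.random_genome(500, 0.45, rng)
        p = build_profile("t", [genome], n)
        for alpha in (0.5, 1.0):
            total = sum(
                math.exp(kmer_log_probability(p, "".join(k), alpha))
                for k in itertools.product("ACGT", repeat=n)
            )
            assert total == pytest.approx(1.0, abs=1e-9)


def test_classify_prefers_matching_composition():
    db = FakeDB(
        {
            "a_genome": build_profile("a_genome", ["AAAAAAAA"], 2),
            "c_genome": build_profile("c_genome", ["CCCCCCCC"], 2),
        }
    )
    res = classify_read("AAAA", db, alpha=1, strand_policy="forward")
    assert res.best_taxon == "a_genome"
    assert res.runner_up_taxon == "c_genome"
    assert res.margin > 0
    # matches the hand-computed two-profile score difference
    sa = score_read("AAAA", db.profiles["a_genome"], 1).log_likelihood
    sc = score_read("AAAA", db.profiles["c_genome"], 1).log_likelihood
    assert res.margin == pytest.approx(sa - sc)


def test_classify_tie_breaks_lexicographically():
    prof = build_profile("x", ["ACGTACGT"], 2)
    db = FakeDB(
        {
            "b": build_profile("b", ["ACGTACGT"], 2),
            "a": build_profile("a", ["ACGTACGT"], 2),
        }
    )
    res = classify_read("ACGT", db, alpha=1)
    assert res.best_taxon == "a"
    assert res.margin == pytest.approx(0.0)


def test_classify_single_profile_has_infinite_margin():
    db = FakeDB({"only": build_profile("only", ["ACGTACGT"], 2)})
    res = classify_read("ACGT", db, alpha=1)
    assert res.best_taxon == "only"
    assert res.runner_up_taxon is None
    assert res.margin == math.inf


def test_classify_empty_database_is_an_error():
    with pytest.raises(ValueError):
        classify_read("ACGT", FakeDB({}), alpha=1)


def test_classify_unscoreable_read_is_unclassified():
    db = FakeDB({"t": build_profile("t", ["ACGTACGT"], 2)})
    res = classify_read("NN", db, alpha=1)
    assert not res.classified
    assert res.best_taxon is None and res.n_scored_kmers == 0


def test_alpha_zero_read_matching_nothing_is_unclassified():
    db = FakeDB(
        {
            "a": build_profile("a", ["AAAAAAAA"], 2),
            "c": build_profile("c", ["CCCCCCCC"], 2),
        }
    )
    res = classify_read("GGGG", db, alpha=0, strand_policy="forward")
    assert not res.classified


def test_exact_substring_reads_recover_their_source(rng):
    """A read copied verbatim from one genome lands on that genome."""
    n = 6
    genomes = {
        f"g{i}": fixtures.random_genome(2000, 0.5, rng) for i in range(5)
    }
    db = FakeDB({t: build_profile(t, [s], n) for t, s in genomes.items()})
    correct = 0
    taxa = sorted(genomes)
    for _ in range(1000):
        taxon = taxa[rng.integers(len(taxa))]
        src = genomes[taxon]
        start = int(rng.integers(0, len(src) - 4 * n + 1))
        read = src[start : start + 4 * n]
        if classify_read(read, db, alpha=1).best_taxon == taxon:
            correct += 1
    assert correct >= 990


def test_classify_reads_bulk_matches_single(rng):
    genomes = {f"g{i}": fixtures.random_genome(1000, 0.5, rng) for i in range(3)}
    db = FakeDB({t: build_profile(t, [s], 4) for t, s in genomes.items()})
    reads = [(f"r{i}", fixtures.random_genome(50, 0.5, rng)) for i in range(10)]
    bulk = classify_reads(reads, db, alpha=1)
    for (rid, seq), res in zip(reads, bulk):
        single = classify_read(seq, db, alpha=1, read_id=rid)
        assert res == single
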