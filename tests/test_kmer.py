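"""4-mer counting, over/under-representation flags, and their VI."""

import itertools
import math

import numpy as np
import pytest

from viratax.genomes import Corpus, Genome
from viratax.kmer import (
    KMERS,
    CorpusBaseline,
    KmerRepresentation,
    binary_entropy,
    corpus_baseline,
    count_kmers,
    kmer_mutual_information,
    kmer_vi,
    kmer_vi_matrix,
    representation_flags,
)


def brute_counts(seq: str, k: int = 4) -> dict[str, int]:
    out: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i: i + k]
        if set(w) <= set("ACGT"):
            out[w] = out.get(w, 0) + 1
    return out


def brute_mi(flags_a: np.ndarray, flags_b: np.ndarray) -> float:
    """Direct four-term evaluation over the 256 types, log base 2."""
    n = flags_a.size
    mi = 0.0
    for va, vb in itertools.product([True, False], repeat=2):
        p_ab = np.sum((flags_a == va) & (flags_b == vb)) / n
        p_a = np.sum(flags_a == va) / n
        p_b = np.sum(flags_b == vb) / n
        if p_ab > 0:
            mi += p_ab * math.log2(p_ab / (p_a * p_b))
    return mi


def _rep(flags: np.ndarray, gid: str = "g") -> KmerRepresentation:
    return KmerRepresentation(gid, flags, float(np.mean(flags)))


def _genome(gid: str, seq: str) -> Genome:
    return Genome(id=gid, name=gid, nt_sequence=seq)


class TestCountKmers:
    def test_worked_example(self):
        kc = count_kmers("ACGACGA")
        by_name = dict(zip(KMERS, kc.counts))
        assert by_name["ACGA"] == 2
        assert by_name["CGAC"] == 1
        assert by_name["GACG"] == 1
        assert kc.total == 4
        assert sum(v for v in by_name.values() if v) == 4

    def test_sequence_shorter_than_k(self):
        kc = count_kmers("ACG")
        assert kc.total == 0 and kc.counts.sum() == 0

    def test_windows_with_n_excluded(self):
        kc = count_kmers("ACGTNACGT")
        # windows touching the N (positions 1..4) are dropped
        assert kc.total == 2
        by_name = dict(zip(KMERS, kc.counts))
        assert by_name["ACGT"] == 2

    def test_matches_bruteforce_on_random_sequences(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGTN"), size=50, p=[0.24] * 4 + [0.04]))
            kc = count_kmers(seq)
            brute = brute_counts(seq)
            for name, n in zip(KMERS, kc.counts):
                assert n == brute.get(name, 0)

    def test_doubling_at_least_doubles_counts(self, rng):
        for _ in range(5):
            s = "".join(rng.choice(list("ACGT"), size=50))
            c1 = count_kmers(s).counts
            c2 = count_kmers(s + s).counts
            assert np.all(c2 >= 2 * c1)


class TestBaselineAndFlags:
    def test_single_genome_baseline_is_its_own_frequencies(self):
        corpus = Corpus([_genome("g", "ACGTACGTAAATTTCCC")])
        base = corpus_baseline(corpus)
        kc = count_kmers(corpus[0].nt_sequence)
        assert np.allclose(base.frequencies, kc.counts / kc.total)

    def test_all_a_corpus_degenerate_baseline(self):
        corpus = Corpus([_genome("g1", "A" * 30), _genome("g2", "A" * 10)])
        base = corpus_baseline(corpus)
        assert base.frequencies[KMERS.index("AAAA")] == 1.0
        assert base.frequencies.sum() == 1.0

    def test_pooled_counts_are_sum_of_per_genome_counts(self, rng):
        genomes = [_genome(f"g{i}", "".join(rng.choice(list("ACGT"), size=200)))
                   for i in range(5)]
        corpus = Corpus(genomes)
        base = corpus_baseline(corpus)
        pooled = sum(count_kmers(g.nt_sequence).counts for g in genomes)
        assert np.allclose(base.frequencies, pooled / pooled.sum())

    def test_genome_identical_to_corpus_has_no_overrepresentation(self):
        corpus = Corpus([_genome("g", "ACGTACGTAAATTTCCCGGG")])
        base = corpus_baseline(corpus)
        rep = representation_flags(count_kmers(corpus[0].nt_sequence, genome_id="g"), base)
        assert not rep.flags.any()  # exact ties count as under-represented
        assert rep.p_over == 0.0

    def test_pure_repeat_vs_mixed_baseline(self):
        corpus = Corpus([_genome("g1", "A" * 40), _genome("g2", "ACGT" * 10)])
        base = corpus_baseline(corpus)
        rep = representation_flags(count_kmers("A" * 40, genome_id="g1"), base)
        assert rep.flags.sum() == 1
        assert rep.flags[KMERS.index("AAAA")]
        assert rep.p_over == pytest.approx(1 / 256)

    def test_flags_match_bruteforce_recomputation(self, rng):
        genomes = [_genome(f"g{i}", "".join(rng.choice(list("ACGT"), size=300,
                                                       p=[0.4, 0.1, 0.1, 0.4])))
                   for i in range(4)]
        corpus = Corpus(genomes)
        base = corpus_baseline(corpus)
        for g in corpus:
            kc = count_kmers(g.nt_sequence, genome_id=g.id)
            rep = representation_flags(kc, base)
            brute = brute_counts(g.nt_sequence)
            total = sum(brute.values())
            for m, name in enumerate(KMERS):
                assert rep.flags[m] == (brute.get(name, 0) / total > base.frequencies[m])

    def test_empty_genome_errors(self):
        base = CorpusBaseline(np.full(256, 1 / 256))
        with pytest.raises(ValueError, match="k-mer"):
            representation_flags(count_kmers("ACG", genome_id="tiny"), base)


class TestMutualInformation:
    def test_identical_balanced_representation_gives_one_bit(self):
        flags = np.zeros(256, dtype=bool)
        flags[:128] = True
        assert kmer_mutual_information(_rep(flags), _rep(flags.copy())) == pytest.approx(1.0)

    def test_independent_flags_give_zero(self):
        a = np.zeros(256, dtype=bool)
        b = np.zeros(256, dtype=bool)
        a[:128] = True  # joint over-over = 64 = 128/256 * 128/256 * 256
        b[64:192] = True
        assert kmer_mutual_information(_rep(a), _rep(b)) == pytest.approx(0.0, abs=1e-12)

    def test_frozen_four_term_value(self):
        # marginals 128/256 each, joint over-over 96/256
        a = np.zeros(256, dtype=bool)
        b = np.zeros(256, dtype=bool)
        a[:128] = True
        b[32:160] = True  # overlap with a = 96
        got = kmer_mutual_information(_rep(a), _rep(b))
        assert got == pytest.approx(0.1887218755408671, abs=1e-9)
        vi = kmer_vi(_rep(a), _rep(b))
        assert vi == pytest.approx(2.0 - 2 * 0.1887218755408671, abs=1e-9)

    def test_matches_bruteforce_on_random_flags(self, rng):
        for _ in range(25):
            a = rng.random(256) < rng.uniform(0.2, 0.8)
            b = rng.random(256) < rng.uniform(0.2, 0.8)
            assert kmer_mutual_information(_rep(a), _rep(b)) == pytest.approx(
                brute_mi(a, b), abs=1e-9)

    def test_bounded_by_marginal_entropies(self, rng):
        for _ in range(25):
            a = rng.random(256) < 0.5
            b = rng.random(256) < 0.5
            i = kmer_mutual_information(_rep(a), _rep(b))
            ha = binary_entropy(float(a.mean()))
            hb = binary_entropy(float(b.mean()))
            assert -1e-12 <= i <= min(ha, hb) + 1e-12


class TestViMatrix:
    def test_identical_representations_have_zero_vi(self):
        flags = np.zeros(256, dtype=bool)
        flags[:100] = True
        assert kmer_vi(_rep(flags), _rep(flags.copy())) == pytest.approx(0.0, abs=1e-12)

    def test_matrix_entries_finite_in_0_2(self, rng):
        genomes = [_genome(f"g{i}", "".join(rng.choice(
            list("ACGT"), size=500, p=np.roll([0.4, 0.3, 0.2, 0.1], i % 4))))
            for i in range(8)]
        m = kmer_vi_matrix(Corpus(genomes))
        assert np.isfinite(m.values).all()
        assert m.values.min() >= 0.0
        assert m.values.max() <= 2.0
        assert np.array_equal(m.values, m.values.T)

    def test_matrix_agrees_with_pairwise_function(self, rng):
        genomes = [_genome(f"g{i}", "".join(rng.choice(list("ACGT"), size=400)))
                   for i in range(5)]
        corpus = Corpus(genomes)
        m = kmer_vi_matrix(corpus)
        base = corpus_baseline(corpus)
        reps = [representation_flags(count_kmers(g.nt_sequence, genome_id=g.id), base)
                for g in corpus]
        for i in range(5):
            for j in range(5):
                assert m.values[i, j] == pytest.approx(kmer_vi(reps[i], reps[j]), abs=1e-9)

    def test_token_weighting_variant_differs_but_is_valid(self, rng):
        genomes = [_genome(f"g{i}", "".join(rng.choice(
            list("ACGT"), size=400, p=[0.4, 0.1, 0.2, 0.3])))
            for i in range(4)]
        corpus = Corpus(genomes)
        m_type = kmer_vi_matrix(corpus, weighting="type")
        m_token = kmer_vi_matrix(corpus, weighting="token")
        assert np.isfinite(m_token.values).all()
        assert m_token.values.min() >= 0.0
        assert not np.allclose(m_type.values, m_token.values)
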