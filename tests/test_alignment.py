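"""Six-frame translation and the exact translated local aligner.

The internal aligner is checked against an independent quadratic-space
Gotoh (affine-gap Smith-Waterman) oracle written here from the recurrence,
sharing nothing with the implementation but the scoring constants.
"""

import math
import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from viratax.alignment import (
    AlignerParams,
    GeneMatch,
    InternalAligner,
    TabularScorer,
    best_hit_table,
    parse_tabular_hits,
    translate_six_frames,
)
from viratax.genomes import Corpus, Gene, Genome, reverse_complement

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(a: str, b: str, open_cost: float = 12.0, extend_cost: float = 1.0) -> float:
    """Naive full-matrix affine-gap local alignment score (oracle).

    A gap of length L costs open_cost + (L - 1) * extend_cost.
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -np.inf)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), -np.inf)  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - open_cost, E[i, j - 1] - extend_cost)
            F[i, j] = max(H[i - 1, j] - open_cost, F[i - 1, j] - extend_cost)
            H[i, j] = max(0.0, H[i - 1, j - 1] + BLOSUM62[a[i - 1], b[j - 1]],
                          E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def oracle_best_raw(nt_a: str, nt_b: str) -> float:
    """Best oracle score over all 36 frame pairs, frames via Biopython."""
    def frames(nt):
        out = []
        for s in (nt, str(Seq(nt).reverse_complement())):
            for off in range(3):
                sub = s[off: off + (len(s) - off) // 3 * 3]
                if sub:
                    out.append(str(Seq(sub).translate()))
        return out

    return max(gotoh_local_score(fa, fb)
               for fa in frames(nt_a) for fb in frames(nt_b))


def random_gene(rng: random.Random, n_codons: int, gid: str) -> Gene:
    nt = "".join(rng.choice("ACGT") for _ in range(3 * n_codons))
    return Gene(id=gid, genome_id=f"genome_{gid}", nt_sequence=nt,
                start=0, end=len(nt))


class TestTranslateSixFrames:
    def test_standard_code_frame1(self):
        assert translate_six_frames("ATGAAA")[0] == "MK"

    def test_partial_codons_dropped(self):
        frames = translate_six_frames("ATGAAAC")  # length 7
        assert len(frames[0]) == 2  # frame +1
        assert len(frames[2]) == 1  # frame +3

    def test_stop_codons_as_star(self):
        assert translate_six_frames("TAA")[0] == "*"

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            translate_six_frames("AT")

    def test_revcomp_swaps_frame_blocks(self):
        rng = random.Random(7)
        for _ in range(10):
            s = "".join(rng.choice("ACGT") for _ in range(30))
            fwd = translate_six_frames(s)
            rev = translate_six_frames(reverse_complement(s))
            assert rev == fwd[3:] + fwd[:3]


class TestInternalAligner:
    def test_identical_genes_score_the_self_score(self, aligner):
        rng = random.Random(3)
        g = random_gene(rng, 100, "a")
        h = Gene(id="b", genome_id="gb", nt_sequence=g.nt_sequence,
                 start=0, end=len(g.nt_sequence))
        bits = aligner.bitscore(g, h)
        assert bits is not None and bits > 0
        assert bits == pytest.approx(aligner.self_bitscore(g), abs=1e-9)

    def test_self_score_is_maximal(self, aligner):
        rng = random.Random(5)
        genes = [random_gene(rng, 30, f"g{i}") for i in range(6)]
        for g in genes:
            self_bits = aligner.self_bitscore(g)
            for h in genes:
                if h.id == g.id:
                    continue
                bits = aligner.params.raw_to_bits(aligner.raw_score(g, h))
                assert bits <= self_bits + 1e-9

    def test_unrelated_random_genes_are_no_match(self, aligner):
        rng = random.Random(9)
        a, b = random_gene(rng, 40, "x"), random_gene(rng, 40, "y")
        assert aligner.bitscore(a, b) is None

    def test_sub_codon_gene_is_no_match(self, aligner):
        a = Gene(id="t", genome_id="g", nt_sequence="AC", start=0, end=2)
        b = random_gene(random.Random(0), 30, "z")
        assert aligner.bitscore(a, b) is None

    def test_matches_gotoh_oracle_on_random_gene_pairs(self, aligner):
        rng = random.Random(42)
        genes = [random_gene(rng, rng.randint(8, 14), f"o{i}") for i in range(20)]
        for i in range(len(genes)):
            for j in range(i, len(genes)):
                got = aligner.raw_score(genes[i], genes[j])
                want = oracle_best_raw(genes[i].nt_sequence, genes[j].nt_sequence)
                assert got == pytest.approx(want, abs=1e-9), (i, j)

    def test_bits_conversion_matches_oracle_formula(self, aligner):
        rng = random.Random(8)
        g = random_gene(rng, 12, "p")
        raw = oracle_best_raw(g.nt_sequence, g.nt_sequence)
        p = aligner.params
        want = (p.lam * raw - math.log(p.K)) / math.log(2.0)
        assert aligner.self_bitscore(g) == pytest.approx(want, abs=1e-9)


@pytest.fixture
def tiny_corpus():
    def mk(gid, genes):
        gs = []
        pos = 0
        for name, nt in genes:
            gs.append(Gene(id=name, genome_id=gid, nt_sequence=nt,
                           start=pos, end=pos + len(nt)))
            pos += len(nt)
        return Genome(id=gid, name=gid, nt_sequence="".join(nt for _, nt in genes), genes=gs)

    rng = random.Random(1)
    seqs = {f"s{i}": "".join(rng.choice("ACGT") for _ in range(30)) for i in range(4)}
    return Corpus([
        mk("G1", [("a1", seqs["s0"]), ("a2", seqs["s1"])]),
        mk("G2", [("b1", seqs["s2"]), ("b2", seqs["s3"])]),
    ])


class TestParseTabularHits:
    def _write(self, path, rows):
        lines = []
        for q, s, bits in rows:
            lines.append("\t".join([q, s, "90.0", "30", "3", "0", "1", "30",
                                    "1", "30", "1e-10", str(bits)]))
        path.write_text("\n".join(lines) + "\n")

    def test_self_hits_separated_and_intra_genome_discarded(self, tmp_path, tiny_corpus):
        p = tmp_path / "hits.tsv"
        self._write(p, [("a1", "b1", 50.0), ("a1", "b2", 45.0), ("a2", "b2", 40.0),
                        ("b1", "a2", 30.0), ("a1", "a1", 60.0)])
        matches, self_scores = parse_tabular_hits(p, tiny_corpus)
        assert len(matches) == 4
        assert self_scores == {"a1": 60.0}

    def test_duplicate_ordered_pair_keeps_max(self, tmp_path, tiny_corpus):
        p = tmp_path / "hits.tsv"
        self._write(p, [("a1", "b1", 50.0), ("a1", "b1", 46.0)])
        matches, _ = parse_tabular_hits(p, tiny_corpus)
        assert len(matches) == 1
        assert matches[0].bitscore == 50.0

    def test_empty_file_gives_empty_list(self, tmp_path, tiny_corpus):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        matches, self_scores = parse_tabular_hits(p, tiny_corpus)
        assert matches == [] and self_scores == {}

    def test_malformed_line_errors_with_line_number(self, tmp_path, tiny_corpus):
        p = tmp_path / "hits.tsv"
        p.write_text("a1\tb1\tnot-enough-columns\n")
        with pytest.raises(ValueError, match=":1"):
            parse_tabular_hits(p, tiny_corpus)

    def test_unknown_gene_skipped_with_warning(self, tmp_path, tiny_corpus, caplog):
        p = tmp_path / "hits.tsv"
        self._write(p, [("a1", "nosuch", 50.0), ("a1", "b1", 44.0)])
        with caplog.at_level("WARNING"):
            matches, _ = parse_tabular_hits(p, tiny_corpus)
        assert len(matches) == 1
        assert "nosuch" in caplog.text

    def test_prefixed_gene_ids_resolve(self, tmp_path, tiny_corpus):
        p = tmp_path / "hits.tsv"
        self._write(p, [("G1|a1", "G2|b1", 50.0)])
        matches, _ = parse_tabular_hits(p, tiny_corpus)
        assert len(matches) == 1

    def test_missing_self_score_names_gene(self, tmp_path, tiny_corpus):
        p = tmp_path / "hits.tsv"
        self._write(p, [("a1", "b1", 50.0)])
        scorer = TabularScorer.from_file(p, tiny_corpus)
        with pytest.raises(ValueError, match="a1"):
            scorer.self_bitscore(tiny_corpus["G1"].genes[0])


class TestBestHitTable:
    def test_max_over_orderings(self):
        table = best_hit_table([GeneMatch("a", "b", 50.0), GeneMatch("b", "a", 46.0)])
        assert table == {frozenset(("a", "b")): 50.0}

    def test_single_ordering_passes_through(self):
        table = best_hit_table([GeneMatch("a", "b", 33.0)])
        assert table[frozenset(("a", "b"))] == 33.0

    def test_invariant_under_permutation(self):
        rng = random.Random(0)
        matches = [GeneMatch(rng.choice("abcd"), rng.choice("efgh"), rng.uniform(20, 80))
                   for _ in range(50)]
        ref = best_hit_table(matches)
        for _ in range(5):
            rng.shuffle(matches)
            assert best_hit_table(matches) == ref
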