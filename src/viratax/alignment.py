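"""Alignment bit scores between gene pairs.

Two backends produce the bit scores that feed the variation-of-information
distance: an exact six-frame translated Smith-Waterman aligner for
desk-scale corpora (:class:`InternalAligner`), and a parser for external
translated-search output in the common 12-column tabular dialect
(:class:`TabularScorer`), which lets full-scale runs reuse precomputed
TBLASTX-style hits.

Raw local-alignment scores ``S`` are converted to bits with the
Karlin-Altschul relation ``S' = (lambda * S - ln K) / ln 2``. The bit score
is interpretable as the log2 size of a database in which an equally good
match would occur once by chance; the model treats it as (proportional to)
the mutual information between the two genes, with the proportionality
constant absorbed by the downstream rescaling of the k-mer distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Protocol

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from viratax.genomes import Corpus, Gene, Genome, reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class GeneMatch:
    """An ordered gene pair with its alignment bit score (bits)."""

    gene_a: str
    gene_b: str
    bitscore: float

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError(f"negative bitscore for ({self.gene_a},{self.gene_b})")


@dataclass
class AlignerParams:
    """Scoring parameters for the internal translated aligner.

    Defaults are the standard gapped BLOSUM62 values (gap open 11, extend
    1, lambda = 0.267 nats per score unit, K = 0.041). Any fixed choice of
    constants only changes the overall bit scale, which is absorbed when
    the k-mer distance is rescaled against the gene distance; they are
    exposed so tabular and internal runs can be made commensurate.
    ``min_bitscore`` is the reporting threshold below which an alignment is
    treated as no match (an open circuit). Its default of 35 bits plays the
    role of a search tool's expect-value cutoff: the expected number of
    chance local alignments in an all-vs-all translated search is about
    K * M * N * exp(-lambda * S) over M x N aligned residues, and with the
    six-frame translations of a desk-scale corpus (M, N ~ 1e5 residues)
    that expectation falls below one only for scores above ~33 bits. A
    materially lower floor floods the parallel sum with chance matches
    between unrelated genomes, which stack into spuriously small distances.
    Scale the threshold up (log2 of the search space) for larger corpora.
    """

    substitution_matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    K: float = 0.041
    min_bitscore: float = 35.0

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.min_bitscore < 0:
            raise ValueError("min_bitscore must be non-negative")

    def raw_to_bits(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.K)) / math.log(2.0)


def translate_six_frames(nt_sequence: str) -> list[str]:
    """Translate a nucleotide sequence in all six frames.

    Returns frames +1, +2, +3 of the sequence followed by +1, +2, +3 of its
    reverse complement; stop codons are ``*``, trailing partial codons are
    dropped, and codons containing ``N`` translate to ``X``.
    """
    if len(nt_sequence) < 3:
        raise ValueError("sequence shorter than one codon")
    frames = []
    for strand_seq in (nt_sequence, reverse_complement(nt_sequence)):
        for off in range(3):
            sub = strand_seq[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames.append(str(Seq(sub).translate(table=1)) if sub else "")
    return frames


class GeneScorer(Protocol):
    """Backend protocol: self bit scores (entropies) and inter-genome matches."""

    def self_bitscore(self, gene: Gene) -> float: ...

    def iter_matches(self, genome_a: Genome, genome_b: Genome) -> Iterator[tuple[Gene, Gene, float]]:
        """Yield (gene_a, gene_b, bitscore) for matched gene pairs."""
        ...


class InternalAligner:
    """Exact six-frame translated local aligner.

    For each gene pair, the best Smith-Waterman raw score over all 36 frame
    pairs is converted to bits; scores below ``min_bitscore`` are no-match.
    This is exact local dynamic programming (no seeding heuristics), meant
    for desk-scale corpora; full-scale runs should feed tabular hits from
    an external search tool instead.
    """

    def __init__(self, params: AlignerParams | None = None):
        self.params = params or AlignerParams()
        matrix = substitution_matrices.load(self.params.substitution_matrix_name)
        aln = PairwiseAligner()
        aln.mode = "local"
        aln.substitution_matrix = matrix
        # BLAST-style affine gaps: a gap of length L costs open + L * extend
        aln.open_gap_score = -(self.params.gap_open + self.params.gap_extend)
        aln.extend_gap_score = -self.params.gap_extend
        self._aligner = aln
        self._alphabet = set(str(matrix.alphabet))
        self._frames: dict[str, list[str]] = {}

    def _gene_frames(self, gene: Gene) -> list[str]:
        # cache keyed by sequence, not gene id: ids are only unique within
        # one corpus and an aligner may be reused across corpora
        cached = self._frames.get(gene.nt_sequence)
        if cached is None:
            frames = translate_six_frames(gene.nt_sequence)
            cached = [
                "".join(c if c in self._alphabet else "X" for c in f)
                for f in frames if f
            ]
            self._frames[gene.nt_sequence] = cached
        return cached

    def raw_score(self, gene_a: Gene, gene_b: Gene) -> float:
        """Best Smith-Waterman raw score over all 36 frame pairs."""
        best = 0.0
        for fa in self._gene_frames(gene_a):
            for fb in self._gene_frames(gene_b):
                s = self._aligner.score(fa, fb)
                if s > best:
                    best = s
        return best

    def bitscore(self, gene_a: Gene, gene_b: Gene) -> Optional[float]:
        """Bit score of the best frame-pair alignment, or None for no match."""
        if len(gene_a.nt_sequence) < 3 or len(gene_b.nt_sequence) < 3:
            return None
        bits = self.params.raw_to_bits(self.raw_score(gene_a, gene_b))
        if bits < self.params.min_bitscore:
            return None
        return bits

    def self_bitscore(self, gene: Gene) -> float:
        # The entropy H(gene) is the gene-vs-itself bit score; it is not a
        # reported "match", so the min_bitscore floor does not apply.
        if len(gene.nt_sequence) < 3:
            raise ValueError(f"gene {gene.id}: shorter than one codon")
        return self.params.raw_to_bits(self.raw_score(gene, gene))

    def iter_matches(self, genome_a: Genome, genome_b: Genome) -> Iterator[tuple[Gene, Gene, float]]:
        for ga in genome_a.genes:
            for gb in genome_b.genes:
                bits = self.bitscore(ga, gb)
                if bits is not None:
                    yield ga, gb, bits


def parse_tabular_hits(
    path: str | Path, corpus: Corpus
) -> tuple[list[GeneMatch], dict[str, float]]:
    """Parse 12-column tabular search output into gene matches + self scores.

    Columns: query id, subject id, %identity, length, mismatches, gap
    opens, q.start, q.end, s.start, s.end, e-value, bitscore. Ids may be
    bare gene ids or the ``genomeid|geneid`` form written by
    :func:`viratax.genomes.write_gene_fasta`. Self-hits are collected
    separately (they supply the gene entropies); hits between genes of the
    same genome are discarded; duplicate hits for one ordered pair keep the
    maximum bit score; unknown gene ids are skipped with a warning.
    """
    genes = corpus.gene_lookup()

    def resolve(token: str) -> Optional[Gene]:
        if token in genes:
            return genes[token]
        if "|" in token:
            tail = token.split("|", 1)[1]
            if tail in genes:
                return genes[tail]
        return None

    best: dict[tuple[str, str], float] = {}
    self_scores: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            try:
                bits = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad bitscore {fields[11]!r}") from exc
            ga, gb = resolve(fields[0]), resolve(fields[1])
            if ga is None or gb is None:
                missing = fields[0] if ga is None else fields[1]
                logger.warning("%s:%d: unknown gene id %r; hit skipped", path, lineno, missing)
                continue
            if ga.id == gb.id:
                self_scores[ga.id] = max(self_scores.get(ga.id, 0.0), bits)
                continue
            if ga.genome_id == gb.genome_id:
                continue  # intra-genome hits never enter the genome distance
            key = (ga.id, gb.id)
            if bits > best.get(key, -1.0):
                best[key] = bits
    matches = [GeneMatch(a, b, s) for (a, b), s in best.items()]
    return matches, self_scores


def best_hit_table(matches: Iterable[GeneMatch]) -> dict[frozenset, float]:
    """Symmetrize: max bit score per unordered gene pair over both orderings."""
    table: dict[frozenset, float] = {}
    for m in matches:
        key = frozenset((m.gene_a, m.gene_b))
        if m.bitscore > table.get(key, -1.0):
            table[key] = m.bitscore
    return table


class TabularScorer:
    """Gene scorer backed by parsed tabular hits from an external search."""

    def __init__(self, matches: Iterable[GeneMatch], self_scores: dict[str, float],
                 corpus: Corpus, min_bitscore: float = 0.0):
        self._table = {k: v for k, v in best_hit_table(matches).items()
                       if v >= min_bitscore}
        self._self = dict(self_scores)
        self._genes = corpus.gene_lookup()

    @classmethod
    def from_file(cls, path: str | Path, corpus: Corpus,
                  min_bitscore: float = 0.0) -> "TabularScorer":
        matches, self_scores = parse_tabular_hits(path, corpus)
        return cls(matches, self_scores, corpus, min_bitscore=min_bitscore)

    def self_bitscore(self, gene: Gene) -> float:
        try:
            return self._self[gene.id]
        except KeyError:
            raise ValueError(
                f"gene {gene.id}: no self-hit in tabular input; the entropy "
                "H(gene) requires the gene-vs-itself bit score"
            ) from None

    def iter_matches(self, genome_a: Genome, genome_b: Genome) -> Iterator[tuple[Gene, Gene, float]]:
        for ga in genome_a.genes:
            for gb in genome_b.genes:
                bits = self._table.get(frozenset((ga.id, gb.id)))
                if bits is not None:
                    yield ga, gb, bits
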