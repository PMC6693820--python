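"""4-mer over/under-representation and its variation of information.

Every genome is reduced to 256 binary flags: is each of the 256 possible
4-mers more prevalent in this genome than in the pooled corpus? Treating
the flag as a binary random variable over the 256 4-mer types, the mutual
information between two genomes is the four-term sum

    I(A, B) = sum_{a,b in {over, under}} p(a,b) log2( p(a,b) / (p(a) p(b)) )

and the distance is the variation of information VI = H(A) + H(B) - 2 I,
which for binary variables lies in [0, 2] bits and is finite for every
genome pair — the fallback when no gene alignment exists.

4-mers are counted in every sliding-window position ("all reading
frames"), so a genome of length L contributes about L tokens; windows
containing N are excluded. Counting is on the given strand only (no
reverse-complement canonicalization).

Probabilities are, by default, fractions of the 256 4-mer *types* (uniform
weight per type); a token-weighted variant, where each type is weighted by
its pooled corpus frequency, is available via ``weighting="token"``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from viratax.genomes import Corpus
from viratax.matrix import DistanceMatrix

N_KMERS = 256  # 4^4 types over {A, C, G, T}

#: All 4-mers in lexicographic order; index i corresponds to counts[i].
KMERS = ["".join(p) for p in itertools.product("ACGT", repeat=4)]

_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class KmerCounts:
    genome_id: str
    counts: np.ndarray  # (256,) ints, lexicographic 4-mer order
    total: int


@dataclass
class CorpusBaseline:
    """Pooled 4-mer token frequencies across all genomes of a corpus."""

    frequencies: np.ndarray  # (256,) reals summing to 1


@dataclass
class KmerRepresentation:
    """Per-genome over-representation flags relative to the corpus baseline."""

    genome_id: str
    flags: np.ndarray  # (256,) bool, True = over-represented
    p_over: float

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)


def count_kmers(sequence: str, k: int = 4, genome_id: str = "") -> KmerCounts:
    """Count k-mers in all sliding-window positions.

    Windows containing N (or any non-ACGT character) are excluded. A
    sequence shorter than k has all-zero counts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_types = 4 ** k
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if codes.size < k:
        return KmerCounts(genome_id, np.zeros(n_types, dtype=np.int64), 0)
    idx = np.zeros(codes.size - k + 1, dtype=np.int64)
    valid = np.ones(codes.size - k + 1, dtype=bool)
    for off in range(k):
        window = codes[off: codes.size - k + 1 + off]
        valid &= window < 4
        idx = idx * 4 + window
    counts = np.bincount(idx[valid], minlength=n_types)
    return KmerCounts(genome_id, counts, int(valid.sum()))


def corpus_counts(corpus: Corpus, k: int = 4) -> list[KmerCounts]:
    return [count_kmers(g.nt_sequence, k=k, genome_id=g.id) for g in corpus]


def corpus_baseline(corpus: Corpus, k: int = 4) -> CorpusBaseline:
    """Token-weighted pooled 4-mer frequencies over the whole corpus."""
    pooled = np.zeros(4 ** k, dtype=np.int64)
    for kc in corpus_counts(corpus, k=k):
        pooled += kc.counts
    total = pooled.sum()
    if total == 0:
        raise ValueError("corpus contains no countable k-mers")
    return CorpusBaseline(frequencies=pooled / total)


def representation_flags(counts: KmerCounts, baseline: CorpusBaseline) -> KmerRepresentation:
    """Over-representation flags: genome frequency strictly above baseline.

    Exact ties count as under-represented (over-representation means
    strictly more prevalent).
    """
    if counts.total == 0:
        raise ValueError(
            f"genome {counts.genome_id or '?'}: no countable k-mers "
            "(sequence too short for the k-mer metric)"
        )
    freqs = counts.counts / counts.total
    flags = freqs > baseline.frequencies
    return KmerRepresentation(counts.genome_id, flags, float(flags.mean()))


def _weights(weighting: str, baseline: CorpusBaseline | None, n_types: int) -> np.ndarray:
    if weighting == "type":
        return np.full(n_types, 1.0 / n_types)
    if weighting == "token":
        if baseline is None:
            raise ValueError("token weighting requires the corpus baseline")
        return baseline.frequencies
    raise ValueError(f"unknown weighting {weighting!r}")


def _mi_terms(p11: np.ndarray, pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Four-term binary mutual information from joint over-over and marginals."""
    cells = [
        (p11, pa, pb),
        (pa - p11, pa, 1.0 - pb),
        (pb - p11, 1.0 - pa, pb),
        (1.0 - pa - pb + p11, 1.0 - pa, 1.0 - pb),
    ]
    mi = np.zeros(np.broadcast(p11, pa, pb).shape)
    for pab, pma, pmb in cells:
        pab = np.clip(pab, 0.0, 1.0)
        denom = pma * pmb
        with np.errstate(divide="ignore", invalid="ignore"):
            term = pab * np.log2(np.where(pab > 0, pab, 1.0) / np.where(denom > 0, denom, 1.0))
        mi += np.where(pab > 0, term, 0.0)
    return mi


def kmer_mutual_information(
    rep_a: KmerRepresentation,
    rep_b: KmerRepresentation,
    weighting: str = "type",
    baseline: CorpusBaseline | None = None,
) -> float:
    """Mutual information (bits) between two genomes' representation flags."""
    w = _weights(weighting, baseline, rep_a.flags.size)
    pa = float(w[rep_a.flags].sum())
    pb = float(w[rep_b.flags].sum())
    p11 = float(w[rep_a.flags & rep_b.flags].sum())
    return float(_mi_terms(np.array(p11), np.array(pa), np.array(pb)))


def binary_entropy(p: np.ndarray | float) -> np.ndarray | float:
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0) \
            - np.where(p < 1, (1 - p) * np.log2(np.where(p < 1, 1 - p, 1.0)), 0.0)
    return h if h.shape else float(h)


def kmer_vi(
    rep_a: KmerRepresentation,
    rep_b: KmerRepresentation,
    weighting: str = "type",
    baseline: CorpusBaseline | None = None,
) -> float:
    """Variation of information between two representations, in [0, 2] bits."""
    w = _weights(weighting, baseline, rep_a.flags.size)
    pa = float(w[rep_a.flags].sum())
    pb = float(w[rep_b.flags].sum())
    i = kmer_mutual_information(rep_a, rep_b, weighting=weighting, baseline=baseline)
    return max(float(binary_entropy(pa)) + float(binary_entropy(pb)) - 2.0 * i, 0.0)


def corpus_representations(
    corpus: Corpus, k: int = 4, baseline: CorpusBaseline | None = None
) -> tuple[list[KmerRepresentation], CorpusBaseline]:
    if baseline is None:
        baseline = corpus_baseline(corpus, k=k)
    reps = [representation_flags(kc, baseline) for kc in corpus_counts(corpus, k=k)]
    return reps, baseline


def vi_matrix_from_flags(
    flags: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Pairwise VI matrix from an (n, 256) boolean flag matrix (vectorized)."""
    f = flags.astype(float)
    pa = f @ weights  # (n,) marginal p(over)
    p11 = (f * weights) @ f.T  # (n, n) joint over-over
    mi = _mi_terms(p11, pa[:, None], pa[None, :])
    h = np.asarray(binary_entropy(pa))
    vi = h[:, None] + h[None, :] - 2.0 * mi
    vi = np.maximum(vi, 0.0)  # floating-point dust on near-identical pairs
    vi = 0.5 * (vi + vi.T)
    np.fill_diagonal(vi, 0.0)
    return vi


def kmer_vi_matrix(corpus: Corpus, k: int = 4, weighting: str = "type") -> DistanceMatrix:
    """Pairwise 4-mer VI over a corpus: symmetric, zero diagonal, finite,
    every entry in [0, 2] bits."""
    reps, baseline = corpus_representations(corpus, k=k)
    flags = np.stack([r.flags for r in reps])
    weights = _weights(weighting, baseline, flags.shape[1])
    vi = vi_matrix_from_flags(flags, weights)
    return DistanceMatrix(ids=corpus.ids, values=vi, sentinel_allowed=False)
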