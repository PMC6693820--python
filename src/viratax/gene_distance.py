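"""Per-gene variation of information and the parallel-resistor genome distance.

The dissimilarity between two genes is the variation of information

    D(A_i, B_j) = H(A_i) + H(B_j) - 2 I(A_i, B_j)

with the mutual information I taken as the alignment bit score and each
entropy as the gene's self-alignment bit score. Gene dissimilarities for a
genome pair combine like resistors in parallel,

    D_eq = 1 / sum_matches (1 / D_i),

so every additional matching gene pair can only lower the genome distance,
and a pair of genomes with no matching genes is an open circuit (infinite
distance, recorded as a sentinel). Search heuristics can underestimate a
gene's entropy and drive D negative; negative values are clamped to a
small positive epsilon so the parallel sum stays defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from viratax.alignment import GeneScorer
from viratax.genomes import Corpus, Gene
from viratax.matrix import DistanceMatrix

logger = logging.getLogger(__name__)

#: Clamp for non-positive variations of information, in bits. Far below any
#: real gene VI so ordering is preserved, while keeping 1/D finite.
DEFAULT_EPSILON = 1e-6

#: Sentinel for "no gene pair matched" (an open circuit).
NO_MATCH = np.inf


@dataclass
class GenePairVI:
    """One matched gene pair with entropies, mutual information, and VI (bits)."""

    gene_a: str
    gene_b: str
    H_a: float
    H_b: float
    I: float
    D: float


@dataclass
class GenomePairGeneDistance:
    genome_a: str
    genome_b: str
    D_eq: float  # bits; NO_MATCH (inf) when n_matches == 0
    n_matches: int


def gene_entropy(gene: Gene, scorer: GeneScorer) -> float:
    """Entropy of a gene: the bit score of the gene aligned against itself."""
    return scorer.self_bitscore(gene)


def gene_variation_of_information(
    H_a: float, H_b: float, I: float, epsilon: float = DEFAULT_EPSILON
) -> float:
    """VI = H_a + H_b - 2 I, clamped below at ``epsilon``.

    The clamp covers both identical genes (VI exactly 0) and unphysical
    negative values arising when a heuristic search reports a pair score
    exceeding a self score.
    """
    return max(H_a + H_b - 2.0 * I, epsilon)


def genome_pair_distance(gene_vis: list[GenePairVI]) -> float:
    """Parallel-resistor combination of per-gene VIs; inf when no matches.

    A single match leaves the distance equal to that gene pair's VI; each
    additional match strictly decreases it.
    """
    if not gene_vis:
        return NO_MATCH
    return 1.0 / sum(1.0 / v.D for v in gene_vis)


def genome_pair_vis(
    genome_a, genome_b, scorer: GeneScorer,
    entropy_cache: dict[str, float] | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[list[GenePairVI], int]:
    """All matched gene-pair VIs for one genome pair.

    Returns the list and the number of clamped (non-positive) VIs. Matches
    are deduplicated to one score per unordered gene pair (the maximum), so
    overlapping alignments are not double-counted in the parallel sum.
    """
    cache = entropy_cache if entropy_cache is not None else {}

    def H(gene: Gene) -> float:
        h = cache.get(gene.id)
        if h is None:
            h = gene_entropy(gene, scorer)
            cache[gene.id] = h
        return h

    best: dict[tuple[str, str], tuple[Gene, Gene, float]] = {}
    for ga, gb, bits in scorer.iter_matches(genome_a, genome_b):
        key = (ga.id, gb.id)
        if key not in best or bits > best[key][2]:
            best[key] = (ga, gb, bits)

    vis: list[GenePairVI] = []
    n_clamped = 0
    for ga, gb, bits in best.values():
        h_a, h_b = H(ga), H(gb)
        raw = h_a + h_b - 2.0 * bits
        if raw <= 0:
            n_clamped += 1
        vis.append(GenePairVI(ga.id, gb.id, h_a, h_b, bits,
                              gene_variation_of_information(h_a, h_b, bits, epsilon)))
    return vis, n_clamped


def gene_distance_matrix(
    corpus: Corpus, scorer: GeneScorer, epsilon: float = DEFAULT_EPSILON
) -> DistanceMatrix:
    """Pairwise gene-alignment genome distances over a corpus.

    Symmetric with a zero diagonal (self-distance is definitionally zero,
    not computed through the parallel sum); genome pairs with no matching
    genes carry the infinite sentinel. Matches between genes of the same
    genome never contribute.
    """
    n = len(corpus)
    values = np.zeros((n, n), dtype=float)
    entropy_cache: dict[str, float] = {}
    total_clamped = 0
    for i in range(n):
        for j in range(i + 1, n):
            vis, n_clamped = genome_pair_vis(
                corpus[i], corpus[j], scorer,
                entropy_cache=entropy_cache, epsilon=epsilon,
            )
            total_clamped += n_clamped
            d = genome_pair_distance(vis)
            values[i, j] = values[j, i] = d
    if total_clamped:
        logger.info("clamped %d non-positive gene VIs to epsilon=%g",
                    total_clamped, epsilon)
    n_pairs = n * (n - 1) // 2
    n_finite = int(np.isfinite(values[np.triu_indices(n, k=1)]).sum())
    logger.info("gene distances: %d/%d genome pairs have at least one match",
                n_finite, n_pairs)
    return DistanceMatrix(ids=corpus.ids, values=values, sentinel_allowed=True)
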