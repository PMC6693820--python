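"""Combine the gene-alignment and k-mer distances into one finite matrix.

The two distances live on very different scales: finite gene-alignment
distances run from near zero up to tens of thousands of bits, while the
4-mer VI is bounded by 2 bits. Left unscaled, the k-mer resistor would
short-circuit every parallel combination, so the k-mer VI is first rescaled
so that its maximum equals the maximum finite gene-alignment distance.
The rescaled k-mer distance is then treated as one more resistor in
parallel with the gene distance:

    D = 1 / (1/D_gene + 1/(s * D_kmer)),

with the open-circuit convention that a sentinel (no-match) gene distance
leaves D = s * D_kmer.
"""

from __future__ import annotations

import numpy as np

from viratax.matrix import DistanceMatrix


def rescale_factor(gene_matrix: DistanceMatrix, kmer_matrix: DistanceMatrix) -> float:
    """s = (max finite off-diagonal gene distance) / (max off-diagonal k-mer VI)."""
    try:
        gene_max = gene_matrix.max_finite_off_diagonal()
    except ValueError:
        raise ValueError(
            "gene distance matrix has no finite entries; no scale can be set "
            "— run in k-mer-only mode instead"
        ) from None
    kmer_off = kmer_matrix.off_diagonal()
    kmer_max = float(kmer_off.max()) if kmer_off.size else 0.0
    if kmer_max <= 0:
        raise ValueError("k-mer matrix has no positive off-diagonal entry")
    return gene_max / kmer_max


def combine_distances(
    gene_matrix: DistanceMatrix, kmer_matrix: DistanceMatrix, s: float
) -> DistanceMatrix:
    """Parallel combination of the gene matrix with the rescaled k-mer matrix."""
    if gene_matrix.ids != kmer_matrix.ids:
        raise ValueError("matrices cover different genome sets or orders")
    if s <= 0:
        raise ValueError("scale factor must be positive")
    dg = gene_matrix.values
    dk = s * kmer_matrix.values
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dg) & (dg > 0), 1.0 / np.where(dg > 0, dg, 1.0), 0.0)
        inv = inv + np.where(dk > 0, 1.0 / np.where(dk > 0, dk, 1.0), 0.0)
        combined = np.where(inv > 0, 1.0 / np.where(inv > 0, inv, 1.0), 0.0)
    # a zero in either matrix is a zero-resistance wire: combined distance 0
    combined[dk == 0] = 0.0
    combined[np.isfinite(dg) & (dg == 0)] = 0.0
    combined = 0.5 * (combined + combined.T)
    np.fill_diagonal(combined, 0.0)
    return DistanceMatrix(ids=gene_matrix.ids, values=combined, sentinel_allowed=False)
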