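"""Place new genomes into an existing clustering by weighted k-NN.

Once the taxonomy has been built, a new genome can be placed without
computing any gene alignments: its 4-mer representation flags are computed
against the *frozen* reference baseline, its k-mer VI to every reference
genome is evaluated, and the cluster shared by the (weighted) plurality of
its k nearest reference neighbors wins. Neighbor counts are weighted to
favor smaller clusters — with unweighted counts a cluster of fewer than
k/2 members could never reach a plurality against a large cluster — and
the default weight is w(size) = 1/size. The winning cluster's share of the
total weighted neighbor count is reported as a confidence in (0, 1];
ranking assignments by this confidence identifies the placements the model
is most certain about, and an optional threshold leaves low-confidence
genomes unassigned.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from viratax.embed import Clustering
from viratax.genomes import Corpus
from viratax.kmer import (
    CorpusBaseline,
    _mi_terms,
    _weights,
    binary_entropy,
    corpus_baseline,
    count_kmers,
    representation_flags,
)

logger = logging.getLogger(__name__)


def inverse_size_weight(size: int) -> float:
    """Default neighbor weight: w(size) = 1/size, favoring small clusters."""
    return 1.0 / size


@dataclass
class ReferenceModel:
    """Frozen reference for k-NN placement.

    Holds the reference corpus baseline (immutable after fit), one flag
    vector per non-noise reference genome, its cluster label, and cluster
    sizes. New genomes are flagged against this baseline; they never update
    it, since a handful of additions would not change it measurably.
    """

    ids: list[str]
    flags: np.ndarray  # (n_ref, 256) bool
    labels: np.ndarray  # (n_ref,) int cluster ids, all >= 0
    baseline: CorpusBaseline
    k: int = 4
    cluster_sizes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cluster_sizes:
            uniq, counts = np.unique(self.labels, return_counts=True)
            self.cluster_sizes = {int(c): int(n) for c, n in zip(uniq, counts)}
        if sum(self.cluster_sizes.values()) != len(self.ids):
            raise ValueError("cluster sizes inconsistent with labels")

    def __len__(self) -> int:
        return len(self.ids)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "k": self.k,
            "ids": self.ids,
            "labels": [int(x) for x in self.labels],
            "flags": ["".join("1" if b else "0" for b in row) for row in self.flags],
            "baseline": [float(x) for x in self.baseline.frequencies],
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceModel":
        doc = json.loads(Path(path).read_text())
        flags = np.array([[c == "1" for c in row] for row in doc["flags"]], dtype=bool)
        return cls(
            ids=list(doc["ids"]),
            flags=flags,
            labels=np.array(doc["labels"], dtype=int),
            baseline=CorpusBaseline(np.array(doc["baseline"], dtype=float)),
            k=int(doc.get("k", 4)),
        )


@dataclass
class Assignment:
    genome_id: str
    cluster: int  # -1 when below the confidence threshold
    confidence: float  # winning cluster's share of total weighted count
    neighbor_ids: list[str]


def fit_reference(corpus: Corpus, clustering: Clustering, k: int = 4) -> ReferenceModel:
    """Freeze a reference model from a clustered corpus.

    Noise-labeled genomes (label -1) are excluded from the model, but the
    baseline is the full corpus baseline the clustering was built from.
    """
    if len(clustering.labels) != len(corpus):
        raise ValueError("clustering does not cover the corpus")
    baseline = corpus_baseline(corpus, k=k)
    keep = np.where(np.asarray(clustering.labels) >= 0)[0]
    if keep.size == 0:
        raise ValueError("all genomes are noise; nothing to fit")
    ids, rows = [], []
    for i in keep:
        g = corpus[int(i)]
        rep = representation_flags(count_kmers(g.nt_sequence, k=k, genome_id=g.id), baseline)
        ids.append(g.id)
        rows.append(rep.flags)
    return ReferenceModel(
        ids=ids,
        flags=np.stack(rows),
        labels=np.asarray(clustering.labels)[keep].astype(int),
        baseline=baseline,
        k=k,
    )


def _cross_vi(new_flags: np.ndarray, ref_flags: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """(n_new, n_ref) k-mer VI between two flag matrices."""
    fn = new_flags.astype(float)
    fr = ref_flags.astype(float)
    pa = fn @ weights
    pb = fr @ weights
    p11 = (fn * weights) @ fr.T
    mi = _mi_terms(p11, pa[:, None], pb[None, :])
    ha = np.asarray(binary_entropy(pa))
    hb = np.asarray(binary_entropy(pb))
    return np.maximum(ha[:, None] + hb[None, :] - 2.0 * mi, 0.0)


def knn_classify(
    new_genomes: Corpus,
    model: ReferenceModel,
    k: int = 30,
    weighting: Callable[[int], float] = inverse_size_weight,
    confidence_threshold: float | None = None,
    exclude_self: bool = False,
) -> list[Assignment]:
    """Assign each new genome to the cluster of the weighted plurality of
    its k nearest reference neighbors (k-mer VI distance).

    ``exclude_self`` drops a reference neighbor with the same genome id as
    the query — used when re-classifying the reference set against itself.
    Ties in the weighted plurality go to the lower cluster id (logged).
    """
    n_ref = len(model)
    if k > n_ref - (1 if exclude_self else 0):
        raise ValueError(f"k={k} exceeds usable reference size {n_ref}")
    w_type = _weights("type", None, model.flags.shape[1])
    new_flags = []
    for g in new_genomes:
        rep = representation_flags(
            count_kmers(g.nt_sequence, k=model.k, genome_id=g.id), model.baseline
        )
        new_flags.append(rep.flags)
    vi = _cross_vi(np.stack(new_flags), model.flags, w_type)

    cluster_w = {c: weighting(s) for c, s in model.cluster_sizes.items()}
    n_clusters = max(model.cluster_sizes) + 1
    assignments: list[Assignment] = []
    ref_ids = np.array(model.ids)
    for i, g in enumerate(new_genomes):
        row = vi[i].copy()
        if exclude_self and g.id in model.ids:
            row[model.ids.index(g.id)] = np.inf
        # stable nearest-k: sort by (distance, reference order)
        nearest = np.lexsort((np.arange(n_ref), row))[:k]
        scores = np.zeros(n_clusters)
        for j in nearest:
            c = int(model.labels[j])
            scores[c] += cluster_w[c]
        winner = int(np.argmax(scores))  # lowest cluster id wins ties
        if (scores == scores[winner]).sum() > 1:
            logger.info("genome %s: tied plurality; chose cluster %d", g.id, winner)
        confidence = float(scores[winner] / scores.sum())
        cluster = winner
        if confidence_threshold is not None and confidence < confidence_threshold:
            cluster = -1
        assignments.append(Assignment(
            genome_id=g.id,
            cluster=cluster,
            confidence=confidence,
            neighbor_ids=[str(x) for x in ref_ids[nearest]],
        ))
    return assignments


def assignments_to_tsv(assignments: list[Assignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tcluster\tconfidence\tneighbors\n")
        for a in assignments:
            fh.write(f"{a.genome_id}\t{a.cluster}\t{a.confidence:.6g}\t"
                     f"{','.join(a.neighbor_ids)}\n")
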