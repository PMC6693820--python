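"""End-to-end orchestration: genomes in, taxonomy out.

Stages: extract genes -> align -> gene distance -> k-mer distance ->
combine -> classical MDS -> t-SNE -> OPTICS -> dendrogram (+ optional
reference model for k-NN placement). Every stage writes its output to the
run directory together with a small manifest keyed by a content hash of
its inputs and parameters; re-running with unchanged inputs skips the
stage, so incremental work (e.g. classifying new genomes against a built
taxonomy) never recomputes the expensive alignment steps. The resolved
configuration and package version are written alongside every run for
provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

import viratax
from viratax.alignment import AlignerParams, InternalAligner, TabularScorer
from viratax.classify import fit_reference
from viratax.combine import combine_distances, rescale_factor
from viratax.embed import (
    Clustering,
    classical_mds,
    cluster_dendrogram,
    dendrogram_to_newick,
    optics_clusters,
    tsne_embed,
)
from viratax.gene_distance import gene_distance_matrix
from viratax.genomes import Corpus, read_fasta, read_genbank, write_gene_fasta
from viratax.kmer import kmer_vi_matrix
from viratax.matrix import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs for one run, serialized alongside the outputs."""

    input_path: str = ""
    input_format: str = "genbank"  # genbank | fasta
    merge_segments: bool = False
    aligner: str = "internal"  # internal | tabular:<path>
    k: int = 4
    kmer_weighting: str = "type"
    min_bitscore: float = 35.0
    epsilon: float = 1e-6
    mds_dims: int = 50
    perplexity: float = 30.0
    theta: float = 0.5
    n_restarts: int = 20
    min_samples: int = 5
    cluster_method: str = "cut"
    xi: float = 0.05
    cluster_eps: float | None = None
    knn_k: int = 30
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _hash(*parts: str | bytes) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p.encode() if isinstance(p, str) else p)
        h.update(b"\x00")
    return h.hexdigest()


class _Stage:
    """Content-addressed caching for one pipeline stage."""

    def __init__(self, outdir: Path, name: str, input_hash: str, outputs: list[Path]):
        self.name = name
        self.manifest = outdir / f".{name}.manifest.json"
        self.input_hash = input_hash
        self.outputs = outputs

    def is_current(self) -> bool:
        if not self.manifest.exists():
            return False
        if not all(o.exists() for o in self.outputs):
            return False
        try:
            doc = json.loads(self.manifest.read_text())
        except json.JSONDecodeError:
            return False
        return doc.get("input_hash") == self.input_hash

    def mark_done(self) -> None:
        self.manifest.write_text(json.dumps(
            {"stage": self.name, "input_hash": self.input_hash,
             "outputs": [str(o) for o in self.outputs]}))


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run all stages into ``outdir``; cached stages are skipped.

    Any stage failure aborts with the stage name and the offending input
    in the exception message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    (outdir / "VERSION").write_text(viratax.__version__ + "\n")

    input_path = Path(config.input_path)
    if not input_path.exists():
        raise FileNotFoundError(f"stage load: input {input_path} not found")
    in_hash = _file_hash(input_path)

    def stage(name: str, outputs: list[str], params: str, deps: list[Path]) -> _Stage:
        dep_hash = _hash(*[_file_hash(d) for d in deps]) if deps else in_hash
        return _Stage(outdir, name, _hash(dep_hash, params),
                      [outdir / o for o in outputs])

    try:
        corpus = (read_genbank(input_path, merge_segments=config.merge_segments)
                  if config.input_format == "genbank" else read_fasta(input_path))
    except Exception as exc:
        raise RuntimeError(f"stage load failed on {input_path}: {exc}") from exc

    # --- genes + gene distance -------------------------------------------
    genes_fa = outdir / "genes.fasta"
    gene_tsv = outdir / "gene_dist.tsv"
    st = stage("gene_dist", ["genes.fasta", "gene_dist.tsv"],
               f"{config.aligner}|{config.min_bitscore}|{config.epsilon}|"
               f"{config.merge_segments}", [])
    if st.is_current():
        logger.info("stage gene_dist: cached, skipping")
        gene_m = DistanceMatrix.from_tsv(gene_tsv, sentinel_allowed=True)
    else:
        try:
            write_gene_fasta(corpus, genes_fa)
            params = AlignerParams(min_bitscore=config.min_bitscore)
            if config.aligner == "internal":
                scorer = InternalAligner(params)
            elif config.aligner.startswith("tabular:"):
                scorer = TabularScorer.from_file(
                    config.aligner.split(":", 1)[1], corpus,
                    min_bitscore=config.min_bitscore)
            else:
                raise ValueError(f"unknown aligner {config.aligner!r}")
            gene_m = gene_distance_matrix(corpus, scorer, epsilon=config.epsilon)
            gene_m.to_tsv(gene_tsv)
            st.mark_done()
        except Exception as exc:
            raise RuntimeError(f"stage gene_dist failed on {input_path}: {exc}") from exc

    # --- k-mer distance ---------------------------------------------------
    kmer_tsv = outdir / "kmer_vi.tsv"
    st = stage("kmer_dist", ["kmer_vi.tsv"],
               f"{config.k}|{config.kmer_weighting}|{config.merge_segments}", [])
    if st.is_current():
        logger.info("stage kmer_dist: cached, skipping")
        kmer_m = DistanceMatrix.from_tsv(kmer_tsv, sentinel_allowed=False)
    else:
        try:
            kmer_m = kmer_vi_matrix(corpus, k=config.k, weighting=config.kmer_weighting)
            kmer_m.to_tsv(kmer_tsv)
            st.mark_done()
        except Exception as exc:
            raise RuntimeError(f"stage kmer_dist failed on {input_path}: {exc}") from exc

    # --- combine ----------------------------------------------------------
    combined_tsv = outdir / "combined.tsv"
    st = stage("combine", ["combined.tsv"], "", [gene_tsv, kmer_tsv])
    if st.is_current():
        logger.info("stage combine: cached, skipping")
        combined = DistanceMatrix.from_tsv(combined_tsv, sentinel_allowed=False)
    else:
        try:
            s = rescale_factor(gene_m, kmer_m)
            logger.info("k-mer rescale factor s = %.6g", s)
            combined = combine_distances(gene_m, kmer_m, s)
            combined.to_tsv(combined_tsv)
            st.mark_done()
        except Exception as exc:
            raise RuntimeError(f"stage combine failed: {exc}") from exc

    # --- embed ------------------------------------------------------------
    emb_tsv = outdir / "embedding.tsv"
    st = stage("embed", ["embedding.tsv"],
               f"{config.mds_dims}|{config.perplexity}|{config.theta}|"
               f"{config.n_restarts}|{config.seed}", [combined_tsv])
    if st.is_current():
        logger.info("stage embed: cached, skipping")
        coords3, ids = _read_embedding(emb_tsv)
    else:
        try:
            mds_coords, n_clipped = classical_mds(combined, dims=config.mds_dims)
            logger.info("MDS: %d negative eigenvalues clipped", n_clipped)
            emb = tsne_embed(mds_coords, combined.ids,
                             perplexity=config.perplexity, theta=config.theta,
                             n_restarts=config.n_restarts, seed=config.seed)
            _write_embedding(emb_tsv, combined.ids, emb.mds_coords, emb.tsne_coords)
            coords3, ids = emb.tsne_coords, combined.ids
            logger.info("t-SNE: best KL divergence %.4f over %d restarts",
                        emb.kl_divergence, config.n_restarts)
            st.mark_done()
        except Exception as exc:
            raise RuntimeError(f"stage embed failed: {exc}") from exc

    # --- cluster ----------------------------------------------------------
    clusters_tsv = outdir / "clusters.tsv"
    st = stage("cluster", ["clusters.tsv"],
               f"{config.min_samples}|{config.cluster_method}|{config.xi}|"
               f"{config.cluster_eps}", [emb_tsv])
    if st.is_current():
        logger.info("stage cluster: cached, skipping")
        clustering = _read_clusters(clusters_tsv)
    else:
        try:
            clustering = optics_clusters(coords3, min_samples=config.min_samples,
                                         method=config.cluster_method,
                                         xi=config.xi, eps=config.cluster_eps)
            _write_clusters(clusters_tsv, ids, clustering)
            logger.info("OPTICS: %d clusters, %d noise points",
                        clustering.n_clusters, int((clustering.labels < 0).sum()))
            st.mark_done()
        except Exception as exc:
            raise RuntimeError(f"stage cluster failed: {exc}") from exc

    # --- dendrogram + reference model ------------------------------------
    nwk = outdir / "dendrogram.nwk"
    st = stage("dendrogram", ["dendrogram.nwk"], "", [clusters_tsv, emb_tsv])
    if not st.is_current():
        try:
            if clustering.n_clusters >= 2:
                dend = cluster_dendrogram(coords3, clustering)
                nwk.write_text(dendrogram_to_newick(dend) + "\n")
            else:
                nwk.write_text(";\n")
                logger.warning("fewer than 2 clusters; empty dendrogram written")
            st.mark_done()
        except Exception as exc:
            raise RuntimeError(f"stage dendrogram failed: {exc}") from exc
    else:
        logger.info("stage dendrogram: cached, skipping")

    model_json = outdir / "model.json"
    st = stage("model", ["model.json"], f"{config.k}", [clusters_tsv])
    if not st.is_current():
        try:
            if clustering.n_clusters >= 1:
                fit_reference(corpus, clustering, k=config.k).to_json(model_json)
                st.mark_done()
        except Exception as exc:
            raise RuntimeError(f"stage model failed: {exc}") from exc
    else:
        logger.info("stage model: cached, skipping")

    return outdir


def _write_embedding(path: Path, ids: list[str], mds: np.ndarray, tsne: np.ndarray) -> None:
    with open(path, "w") as fh:
        mds_cols = "\t".join(f"mds{i}" for i in range(mds.shape[1]))
        tsne_cols = "\t".join(f"tsne{i}" for i in range(tsne.shape[1]))
        fh.write(f"id\t{mds_cols}\t{tsne_cols}\n")
        for i, gid in enumerate(ids):
            row = np.concatenate([mds[i], tsne[i]])
            fh.write(gid + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def _read_embedding(path: Path) -> tuple[np.ndarray, list[str]]:
    ids, rows = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        tsne_idx = [i for i, c in enumerate(header) if c.startswith("tsne")]
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            ids.append(fields[0])
            rows.append([float(fields[i]) for i in tsne_idx])
    return np.array(rows), ids


def _write_clusters(path: Path, ids: list[str], clustering: Clustering) -> None:
    with open(path, "w") as fh:
        fh.write("id\tcluster\treachability\tordering\n")
        for i, gid in enumerate(ids):
            fh.write(f"{gid}\t{int(clustering.labels[i])}\t"
                     f"{clustering.reachability[i]:.10g}\t"
                     f"{int(np.where(clustering.ordering == i)[0][0])}\n")


def _read_clusters(path: Path) -> Clustering:
    labels, reach, order_pos = [], [], []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            labels.append(int(fields[1]))
            reach.append(float(fields[2]))
            order_pos.append(int(fields[3]))
    ordering = np.empty(len(order_pos), dtype=int)
    for i, pos in enumerate(order_pos):
        ordering[pos] = i
    return Clustering(labels=np.array(labels), reachability=np.array(reach),
                      ordering=ordering)
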