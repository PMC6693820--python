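"""Synthetic viral corpora with known family structure.

The generator emulates the signal structure the distance model relies on:
each family descends from a single ancestor genome of a few genes separated
by intergenic spacers, and descendants diverge by per-site nucleotide
substitution plus whole-gene loss and gain. Within a family, genes are
recognizable homologs, so the translated aligner finds matches and the
gene-alignment distance is finite; between families, genes are unrelated
random sequences, so only the 4-mer signal (driven by each family's GC
bias) carries information — exactly the regime in which the k-mer fallback
must do the work.

Gene gain draws novel random genes rather than transferring genes between
families, which keeps families separable; an optional ``gene_transfer``
switch instead copies a gene from another genome of the same family's pool,
creating the chimeric structure where no one descendant need share a gene
with every other. There is no indel or recombination model: divergence is
substitution plus gene turnover only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from viratax.genomes import Corpus, Gene, Genome, reverse_complement

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic corpus.

    Defaults describe a small, clearly structured corpus: 3 families of 10
    genomes, ancestors of 4-6 genes of 60-120 codons with 20-50 nt
    intergenic spacers, 5% per-site substitution per descendant, 10%
    per-gene loss and gain, and family GC contents spread over
    [0.35, 0.65] so the 4-mer profile separates families.
    """

    n_families: int = 3
    genomes_per_family: int = 10
    genes_per_ancestor: tuple[int, int] = (4, 6)
    gene_length: tuple[int, int] = (60, 120)  # codons
    intergenic_length: tuple[int, int] = (20, 50)  # nt
    substitution_rate: float = 0.05
    gene_loss_prob: float = 0.1
    gene_gain_prob: float = 0.1
    gc_bias: list[float] | None = None  # per family; evenly spaced if None
    minus_strand_prob: float = 0.3
    gene_transfer: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.substitution_rate, self.gene_loss_prob,
                  self.gene_gain_prob, self.minus_strand_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for lo, hi in (self.genes_per_ancestor, self.gene_length,
                       self.intergenic_length):
            if lo > hi or lo < 1:
                raise ValueError(f"empty or invalid range ({lo},{hi})")
        if self.gc_bias is not None:
            if len(self.gc_bias) != self.n_families:
                raise ValueError("gc_bias must have one value per family")
            if any(not 0.0 < g < 1.0 for g in self.gc_bias):
                raise ValueError("gc_bias values must lie in (0, 1)")

    def family_gc(self) -> list[float]:
        if self.gc_bias is not None:
            return list(self.gc_bias)
        if self.n_families == 1:
            return [0.5]
        return list(np.linspace(0.35, 0.65, self.n_families))


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length, p=_base_probs(gc)))


def random_gene_sequence(n_codons: int, gc: float, rng: np.random.Generator) -> str:
    """Random coding sequence of ``n_codons`` with no in-frame stop codons."""
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(_BASES, size=3, p=_base_probs(gc)))
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


def mutate_sequence(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``rate`` to a
    uniformly chosen *different* base. N sites are left untouched."""
    if rate == 0.0 or not sequence:
        return sequence
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    idx = code[arr]
    hit = (rng.random(arr.size) < rate) & (idx >= 0)
    shift = rng.integers(1, 4, size=int(hit.sum()))
    new_idx = (idx[hit] + shift) % 4
    arr[hit] = np.frombuffer(b"ACGT", dtype=np.uint8)[new_idx]
    return arr.tobytes().decode("ascii")


@dataclass
class _ProtoGene:
    name: str
    nt: str  # coding orientation
    strand: str


def _assemble(genome_id: str, name: str, proto: list[_ProtoGene],
              spacers: list[str], family: str) -> Genome:
    """Lay genes and spacers alternately onto a forward-strand sequence."""
    parts: list[str] = []
    genes: list[Gene] = []
    pos = 0
    for i, pg in enumerate(proto):
        spacer = spacers[i]
        parts.append(spacer)
        pos += len(spacer)
        embedded = pg.nt if pg.strand == "+" else reverse_complement(pg.nt)
        parts.append(embedded)
        genes.append(Gene(
            id=f"{genome_id}_{pg.name}",
            genome_id=genome_id,
            nt_sequence=pg.nt,
            start=pos,
            end=pos + len(pg.nt),
            strand=pg.strand,
        ))
        pos += len(pg.nt)
    parts.append(spacers[len(proto)])
    return Genome(id=genome_id, name=name, nt_sequence="".join(parts),
                  genes=genes, metadata={"family": family})


def simulate_corpus(config: SimulationConfig) -> tuple[Corpus, dict[str, int]]:
    """Generate a corpus of families plus the true family label per genome.

    Deterministic given ``config.seed``. Returns the corpus and a map
    genome id -> family index.
    """
    rng = np.random.default_rng(config.seed)
    gcs = config.family_gc()
    genomes: list[Genome] = []
    labels: dict[str, int] = {}
    for f in range(config.n_families):
        gc = gcs[f]
        family = f"F{f}"
        n_genes = int(rng.integers(config.genes_per_ancestor[0],
                                   config.genes_per_ancestor[1] + 1))
        ancestor = [
            _ProtoGene(
                name=f"g{i}",
                nt=random_gene_sequence(
                    int(rng.integers(config.gene_length[0], config.gene_length[1] + 1)),
                    gc, rng),
                strand="-" if rng.random() < config.minus_strand_prob else "+",
            )
            for i in range(n_genes)
        ]
        family_pool = [pg.nt for pg in ancestor]
        for d in range(config.genomes_per_family):
            gid = f"{family}G{d}"
            proto: list[_ProtoGene] = []
            for pg in ancestor:
                if rng.random() < config.gene_loss_prob:
                    continue
                proto.append(_ProtoGene(
                    name=pg.name,
                    nt=mutate_sequence(pg.nt, config.substitution_rate, rng),
                    strand=pg.strand,
                ))
            if rng.random() < config.gene_gain_prob:
                if config.gene_transfer and family_pool:
                    src = family_pool[int(rng.integers(len(family_pool)))]
                    gained = mutate_sequence(src, config.substitution_rate, rng)
                else:
                    gained = random_gene_sequence(
                        int(rng.integers(config.gene_length[0],
                                         config.gene_length[1] + 1)),
                        gc, rng)
                proto.append(_ProtoGene(
                    name=f"novel{d}",
                    nt=gained,
                    strand="-" if rng.random() < config.minus_strand_prob else "+",
                ))
            if not proto:  # a genome must keep at least one gene
                proto.append(_ProtoGene(
                    name=ancestor[0].name,
                    nt=mutate_sequence(ancestor[0].nt, config.substitution_rate, rng),
                    strand=ancestor[0].strand,
                ))
            spacers = [
                mutate_sequence(
                    random_sequence(
                        int(rng.integers(config.intergenic_length[0],
                                         config.intergenic_length[1] + 1)),
                        gc, rng),
                    config.substitution_rate, rng)
                for _ in range(len(proto) + 1)
            ]
            genome = _assemble(gid, f"{family} descendant {d}", proto, spacers, family)
            genomes.append(genome)
            labels[gid] = f
    return Corpus(genomes), labels


def labels_to_tsv(labels: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tfamily\n")
        for gid, fam in labels.items():
            fh.write(f"{gid}\t{fam}\n")
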