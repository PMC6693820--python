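"""Data model and I/O for genomes, genes, and corpora.

A :class:`Genome` is a nucleotide sequence plus the coding sequences (genes)
annotated on it; a :class:`Corpus` is an ordered collection of genomes whose
order fixes the row/column order of every distance matrix downstream.
Sequences are normalized to uppercase over the alphabet ``{A, C, G, T, N}``;
any other ambiguity code is mapped to ``N`` on load, because the 4-mer
metric lives on the 4-letter alphabet and windows containing ``N`` are
excluded from counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_sequence(seq: str) -> str:
    """Uppercase and map any character outside {A,C,G,T,N} to N."""
    seq = seq.upper()
    if set(seq) - _VALID:
        n_bad = sum(c not in _VALID for c in seq)
        logger.warning("mapped %d non-ACGTN characters to N", n_bad)
        seq = "".join(c if c in _VALID else "N" for c in seq)
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Gene:
    """A coding sequence extracted from a genome.

    ``nt_sequence`` is stored in coding orientation (reverse-complemented
    for minus-strand features). ``start``/``end`` are 0-based half-open on
    the genome's forward strand. For single-interval genes the sequence
    length equals ``end - start``; spliced (compound-location) features may
    be shorter than their genomic span.
    """

    id: str
    genome_id: str
    nt_sequence: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.nt_sequence:
            raise ValueError(f"gene {self.id}: empty sequence")
        if self.end <= self.start:
            raise ValueError(f"gene {self.id}: end {self.end} <= start {self.start}")
        if len(self.nt_sequence) > self.end - self.start:
            raise ValueError(
                f"gene {self.id}: sequence longer than genomic span "
                f"({len(self.nt_sequence)} > {self.end - self.start})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return len(self.nt_sequence)


@dataclass
class Genome:
    """A viral genome: sequence, annotated genes, optional metadata labels.

    ``metadata`` (host kingdom, Baltimore class, ICTV family, ...) is carried
    for reporting only and never enters any computation.
    """

    id: str
    name: str
    nt_sequence: str
    genes: list[Gene] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise ValueError(f"genome {self.id}: duplicate gene id {g.id}")
            seen.add(g.id)
            if g.start < 0 or g.end > len(self.nt_sequence):
                raise ValueError(
                    f"genome {self.id}: gene {g.id} at ({g.start},{g.end}) "
                    f"outside sequence of length {len(self.nt_sequence)}"
                )

    def __len__(self) -> int:
        return len(self.nt_sequence)


class Corpus:
    """Ordered collection of genomes; order defines matrix row order."""

    def __init__(self, genomes: list[Genome]):
        self.genomes: list[Genome] = list(genomes)
        self.index: dict[str, int] = {}
        for i, g in enumerate(self.genomes):
            if g.id in self.index:
                raise ValueError(f"duplicate genome id {g.id}")
            self.index[g.id] = i

    def __len__(self) -> int:
        return len(self.genomes)

    def __iter__(self) -> Iterator[Genome]:
        return iter(self.genomes)

    def __getitem__(self, key) -> Genome:
        if isinstance(key, str):
            return self.genomes[self.index[key]]
        return self.genomes[key]

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.index

    @property
    def ids(self) -> list[str]:
        return [g.id for g in self.genomes]

    def genes(self) -> Iterator[Gene]:
        for g in self.genomes:
            yield from g.genes

    def gene_lookup(self) -> dict[str, Gene]:
        return {gene.id: gene for gene in self.genes()}


def _extract_cds(record: SeqRecord, feature: SeqFeature, idx: int) -> Optional[Gene]:
    start = int(feature.location.start)
    end = int(feature.location.end)
    if start < 0 or end > len(record.seq):
        logger.warning(
            "record %s: CDS %d at (%d,%d) exceeds sequence bounds; skipped",
            record.id, idx, start, end,
        )
        return None
    quals = feature.qualifiers
    gene_id = (
        quals.get("protein_id", [None])[0]
        or quals.get("locus_tag", [None])[0]
        or f"{record.id}_cds{idx}"
    )
    nt = normalize_sequence(str(feature.extract(record.seq)))
    strand = "-" if feature.location.strand == -1 else "+"
    return Gene(id=gene_id, genome_id=record.id, nt_sequence=nt,
                start=start, end=end, strand=strand)


def _record_to_genome(record: SeqRecord) -> Genome:
    genes = []
    seen: set[str] = set()
    for i, feat in enumerate(f for f in record.features if f.type == "CDS"):
        gene = _extract_cds(record, feat, i)
        if gene is None:
            continue
        if gene.id in seen:  # e.g. repeated protein_id on a join
            gene.id = f"{gene.id}.{i}"
        seen.add(gene.id)
        genes.append(gene)
    meta = {}
    organism = record.annotations.get("organism")
    if organism:
        meta["organism"] = organism
    return Genome(
        id=record.id,
        name=record.description or record.id,
        nt_sequence=normalize_sequence(str(record.seq)),
        genes=genes,
        metadata=meta,
    )


def read_genbank(path: str | Path, merge_segments: bool = False) -> Corpus:
    """Read a GenBank flat file into a Corpus, one Genome per record.

    Each CDS feature becomes one Gene, with its sequence extracted in
    coding orientation. Records without CDS features still yield genomes
    (usable by the k-mer metric). With ``merge_segments``, records sharing
    an organism name are concatenated into a single genome (sequences
    joined, genes pooled with shifted coordinates) — useful for
    multi-segment viruses whose segments would otherwise be treated as
    unrelated genomes.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"failed to parse GenBank file {path}: {exc}") from exc
    if not records:
        raise ValueError(f"no GenBank records in {path}")
    genomes = [_record_to_genome(r) for r in records]
    if merge_segments:
        genomes = _merge_by_organism(genomes)
    return Corpus(genomes)


def _merge_by_organism(genomes: list[Genome]) -> list[Genome]:
    groups: dict[str, list[Genome]] = {}
    order: list[str] = []
    for g in genomes:
        key = g.metadata.get("organism") or g.id
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(g)
    merged = []
    for key in order:
        members = groups[key]
        if len(members) == 1:
            merged.append(members[0])
            continue
        seq_parts: list[str] = []
        genes: list[Gene] = []
        offset = 0
        for m in members:
            for gene in m.genes:
                genes.append(Gene(
                    id=f"{m.id}|{gene.id}" if len(members) > 1 else gene.id,
                    genome_id=members[0].id,
                    nt_sequence=gene.nt_sequence,
                    start=gene.start + offset,
                    end=gene.end + offset,
                    strand=gene.strand,
                ))
            seq_parts.append(m.nt_sequence)
            offset += len(m.nt_sequence)
        merged.append(Genome(
            id=members[0].id,
            name=key,
            nt_sequence="".join(seq_parts),
            genes=genes,
            metadata={"organism": key, "n_segments": len(members)},
        ))
        logger.info("merged %d segments of %r", len(members), key)
    return merged


def read_fasta(path: str | Path) -> Corpus:
    """Read nucleotide FASTA into a Corpus of gene-less genomes.

    The header token before the first whitespace becomes the genome id.
    Duplicate ids and empty files are errors.
    """
    path = Path(path)
    genomes = []
    for record in SeqIO.parse(str(path), "fasta"):
        genomes.append(Genome(
            id=record.id,
            name=record.description or record.id,
            nt_sequence=normalize_sequence(str(record.seq)),
        ))
    if not genomes:
        raise ValueError(f"no FASTA records in {path}")
    return Corpus(genomes)


def write_fasta(corpus: Corpus, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.nt_sequence), id=g.id, description=g.name if g.name != g.id else "")
        for g in corpus
    ]
    SeqIO.write(records, str(path), "fasta")


def write_gene_fasta(corpus: Corpus, path: str | Path) -> None:
    """Write every extracted gene as ``genomeid|geneid`` for external search tools."""
    records = [
        SeqRecord(Seq(gene.nt_sequence), id=f"{gene.genome_id}|{gene.id}", description="")
        for gene in corpus.genes()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_genbank(corpus: Corpus, path: str | Path) -> None:
    """Write a Corpus as a GenBank flat file with CDS features."""
    records = []
    for g in corpus:
        rec = SeqRecord(Seq(g.nt_sequence), id=g.id, name=g.id[:16],
                        description=g.name,
                        annotations={"molecule_type": "DNA",
                                     "organism": g.metadata.get("organism", g.name)})
        for gene in g.genes:
            loc = FeatureLocation(gene.start, gene.end,
                                  strand=-1 if gene.strand == "-" else 1)
            feat = SeqFeature(loc, type="CDS",
                              qualifiers={"locus_tag": [gene.id]})
            rec.features.append(feat)
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")
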