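"""Genome and gene-model data structures with FASTA/GFF3 readers and writers.

Coordinates are 0-based, half-open internally; GFF3 I/O converts to and
from the format's 1-based inclusive convention.  Gene models are
single-transcript: CDS features may parent an mRNA or the gene directly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "Genome",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "extract_cds",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: genomic interval, strand, and ordered CDS parts.

    ``cds_parts`` are sub-intervals in genomic order (ascending start),
    non-overlapping and contained in ``[start, end)`` regardless of strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_parts: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        object.__setattr__(self, "cds_parts", tuple(tuple(p) for p in self.cds_parts))
        prev_end = None
        for s, e in self.cds_parts:
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"gene {self.gene_id}: CDS part [{s}, {e}) outside gene interval"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: CDS parts overlap or are unsorted"
                )
            prev_end = e

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_parts)

    def with_(self, **kwargs) -> "GeneModel":
        return dataclasses.replace(self, **kwargs)


@dataclass
class Genome:
    """A set of chromosome sequences plus per-chromosome sorted gene lists."""

    sequences: dict[str, str] = field(default_factory=dict)
    genes: dict[str, list[GeneModel]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in self.genes:
            self.genes[chrom] = sorted(self.genes[chrom], key=lambda g: g.start)
        self.validate()

    def validate(self) -> None:
        for chrom, models in self.genes.items():
            if chrom not in self.sequences:
                raise ValueError(f"genes reference unknown chromosome {chrom!r}")
            length = len(self.sequences[chrom])
            for g in models:
                if g.end > length:
                    raise ValueError(
                        f"gene {g.gene_id} extends past end of {chrom} "
                        f"({g.end} > {length})"
                    )

    def all_genes(self) -> list[GeneModel]:
        """Genes over all chromosomes, sorted by (chrom, start)."""
        out: list[GeneModel] = []
        for chrom in sorted(self.genes):
            out.extend(self.genes[chrom])
        return out

    def gene(self, gene_id: str) -> GeneModel:
        for models in self.genes.values():
            for g in models:
                if g.gene_id == gene_id:
                    return g
        raise KeyError(gene_id)

    def add_gene(self, gene: GeneModel) -> None:
        self.genes.setdefault(gene.chrom, []).append(gene)
        self.genes[gene.chrom].sort(key=lambda g: g.start)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> uppercase-sequence map."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"no records in FASTA file {path}")
    return sequences


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences as multi-record FASTA, wrapped at ``width`` columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"malformed GFF3 attribute {part!r}")
        key, value = part.split("=", 1)
        attrs[key] = value
    return attrs


def read_gff(path: str | Path, genome_sequences: dict[str, str]) -> list[GeneModel]:
    """Parse GFF3 gene models (gene / optional mRNA / CDS with ID & Parent).

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Returned genes are sorted by (chrom, start); CDS parts are grouped under
    their parent gene, resolving through an mRNA level when present.
    """
    gene_rows: dict[str, tuple[str, int, int, str]] = {}
    mrna_parent: dict[str, str] = {}
    cds_by_gene: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start1, end1, _score, strand, _frame, attr_text = fields
            start, end = int(start1) - 1, int(end1)
            attrs = _parse_attributes(attr_text)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ValueError(f"{path}:{lineno}: gene without ID")
                gene_rows[gid] = (chrom, start, end, strand)
                order.append(gid)
            elif ftype == "mRNA":
                mid, parent = attrs.get("ID"), attrs.get("Parent")
                if mid is None or parent is None:
                    raise ValueError(f"{path}:{lineno}: mRNA needs ID and Parent")
                mrna_parent[mid] = parent
            elif ftype == "CDS":
                parent = attrs.get("Parent")
                if parent is None:
                    raise ValueError(f"{path}:{lineno}: CDS without Parent")
                gid = mrna_parent.get(parent, parent)
                if chrom not in genome_sequences:
                    raise ValueError(
                        f"{path}:{lineno}: CDS on unknown chromosome {chrom!r}"
                    )
                if end > len(genome_sequences[chrom]):
                    raise ValueError(
                        f"{path}:{lineno}: CDS [{start}, {end}) outside "
                        f"chromosome {chrom} of length {len(genome_sequences[chrom])}"
                    )
                cds_by_gene.setdefault(gid, []).append((start, end))
            # other feature types ignored

    for gid in cds_by_gene:
        if gid not in gene_rows:
            raise ValueError(f"CDS features reference unknown parent gene {gid!r}")

    genes: list[GeneModel] = []
    for gid in order:
        chrom, start, end, strand = gene_rows[gid]
        parts = tuple(sorted(cds_by_gene.get(gid, [])))
        genes.append(GeneModel(gid, chrom, start, end, strand, parts))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gff(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene + CDS; 1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tectoconv\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.cds_parts, 1):
                fh.write(
                    f"{g.chrom}\tectoconv\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t0\tID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


def extract_cds(gene: GeneModel, genome: Genome | dict[str, str]) -> str:
    """Spliced CDS of a gene in transcriptional orientation, uppercase.

    Parts are concatenated in genomic order; on the minus strand the
    concatenation is reverse-complemented.
    """
    sequences = genome.sequences if isinstance(genome, Genome) else genome
    if gene.chrom not in sequences:
        raise ValueError(f"gene {gene.gene_id}: unknown chromosome {gene.chrom!r}")
    chrom_seq = sequences[gene.chrom]
    pieces = []
    for s, e in gene.cds_parts:
        if e > len(chrom_seq):
            raise ValueError(f"gene {gene.gene_id}: CDS part [{s}, {e}) out of bounds")
        pieces.append(chrom_seq[s:e])
    cds = "".join(pieces).upper()
    return reverse_complement(cds) if gene.strand == "-" else cds
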