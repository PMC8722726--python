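"""Sequence and annotation I/O, coordinate conventions, strand-aware extraction.

Coordinates are 0-based half-open everywhere inside the package; user-facing
reports convert to 1-based inclusive at the serialization boundary.  Gene-local
("sense") coordinates index the gene's own sense strand: position 0 is the
first base of exon 1 regardless of genomic strand.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AnnotationError, FastaParseError, RangeError

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One contig: an uppercase A/C/G/T/N string."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaParseError(f"contig {self.contig_id!r}: empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise FastaParseError(
                f"contig {self.contig_id!r}: invalid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Interval:
    """Genomic interval, 0-based half-open, with strand."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise RangeError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id}"
            )
        if self.strand not in ("+", "-"):
            raise RangeError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "Interval") -> int:
        if self.contig_id != other.contig_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def to_1based(self) -> tuple[int, int]:
        """(start, end) in 1-based inclusive report coordinates."""
        return self.start + 1, self.end

    def to_bed_fields(self, name: str = ".") -> list[str]:
        return [self.contig_id, str(self.start), str(self.end), name, "0", self.strand]


@dataclass
class GeneModel:
    """Strand-aware exon architecture of one gene on one contig.

    ``exons`` are ordered 5'→3' in gene orientation, so for minus-strand genes
    exon 1 has the highest genomic coordinate.  Exon numbers are the 1-based
    indices into that list.
    """

    gene_id: str
    contig_id: str
    strand: str
    exons: list[Interval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id!r}: no exons")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise AnnotationError(f"gene {self.gene_id!r}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise AnnotationError(
                f"gene {self.gene_id!r}: exons not sorted 5'→3' in gene orientation"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> Interval:
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        return Interval(self.contig_id, start, end, self.strand)

    @property
    def sense_length(self) -> int:
        return self.span.length

    def sense_sequence(self, genome: GenomeSequence) -> str:
        """Sense-strand sequence of the full gene span (exon 1 first)."""
        return sense_sequence(self.span, genome)

    # -- gene-local sense coordinate helpers ---------------------------------

    def local_to_genomic_pos(self, pos: int) -> int:
        span = self.span
        if not 0 <= pos < span.length:
            raise RangeError(f"local position {pos} outside gene {self.gene_id!r}")
        if self.strand == "+":
            return span.start + pos
        return span.end - 1 - pos

    def local_to_genomic(self, start: int, end: int) -> Interval:
        span = self.span
        if not (0 <= start < end <= span.length):
            raise RangeError(
                f"local window [{start}, {end}) outside gene {self.gene_id!r}"
            )
        if self.strand == "+":
            return Interval(self.contig_id, span.start + start, span.start + end, "+")
        return Interval(self.contig_id, span.end - end, span.end - start, "-")

    def genomic_to_local(self, iv: Interval) -> tuple[int, int]:
        span = self.span
        if iv.contig_id != self.contig_id or iv.start < span.start or iv.end > span.end:
            raise RangeError(f"interval {iv} outside gene {self.gene_id!r}")
        if self.strand == "+":
            return iv.start - span.start, iv.end - span.start
        return span.end - iv.end, span.end - iv.start

    def exon_local_intervals(self) -> list[tuple[int, int]]:
        """Exon windows in gene-local sense coordinates, exon 1 first."""
        return [self.genomic_to_local(e) for e in self.exons]

    def intron_local_intervals(self) -> list[tuple[int, int]]:
        locals_ = self.exon_local_intervals()
        return [(a_end, b_start) for (_, a_end), (b_start, _) in zip(locals_, locals_[1:])]


def introns_of(gene: GeneModel) -> list[Interval]:
    """Genomic intron intervals, ordered 5'→3' in gene orientation.

    Intron k (1-based) lies between exon k and exon k+1; a single-exon gene
    has none.
    """
    introns = []
    for a, b in zip(gene.exons, gene.exons[1:]):
        if gene.strand == "+":
            introns.append(Interval(gene.contig_id, a.end, b.start, "+"))
        else:
            introns.append(Interval(gene.contig_id, b.end, a.start, "-"))
    return introns


def sense_sequence(region: Interval, genome: GenomeSequence) -> str:
    """Sequence of ``region`` read 5'→3' along its own strand."""
    if region.contig_id != genome.contig_id:
        raise RangeError(
            f"region contig {region.contig_id!r} != genome contig {genome.contig_id!r}"
        )
    if region.end > len(genome):
        raise RangeError(
            f"interval [{region.start}, {region.end}) outside contig "
            f"{genome.contig_id!r} of length {len(genome)}"
        )
    sub = genome.sequence[region.start : region.end]
    return sub if region.strand == "+" else revcomp(sub)


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Load all records of a FASTA file, normalizing to uppercase."""
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"no such file: {path}")
    # pre-scan for structural problems so errors can name a line
    with open(path) as fh:
        seen_header = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                seen_header = True
            elif not seen_header:
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before any '>' header"
                )
            else:
                bad = set(line.upper()) - VALID_ALPHABET
                if bad:
                    raise FastaParseError(
                        f"{path}:{lineno}: invalid sequence characters {sorted(bad)!r}"
                    )
    result: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in result:
            raise FastaParseError(f"{path}: duplicate contig id {rec.id!r}")
        result[rec.id] = GenomeSequence(rec.id, str(rec.seq).upper())
    return result


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    seqrecs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 / GTF I/O


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (or GTF) into :class:`GeneModel` objects.

    Exons are grouped per gene through their Parent/gene_id attributes; an
    exon with no gene ancestor is an annotation error.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"no such file: {path}")
    is_gtf = path.suffix.lower() in (".gtf", ".gff2")
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=not is_gtf,
            disable_infer_transcripts=not is_gtf,
        )
    except Exception as exc:  # pragma: no cover - gffutils error text varies
        raise AnnotationError(f"failed to parse {path}: {exc}") from exc

    genes: list[GeneModel] = []
    claimed_exons: set[str] = set()
    for gene in db.features_of_type("gene"):
        exon_ivs = []
        for exon in db.children(gene, featuretype="exon"):
            claimed_exons.add(exon.id)
            # gffutils keeps 1-based inclusive; convert to 0-based half-open
            exon_ivs.append(
                Interval(exon.seqid, exon.start - 1, exon.end, gene.strand)
            )
        if not exon_ivs:
            raise AnnotationError(f"gene {gene.id!r} has no exons")
        exon_ivs = sorted(set(exon_ivs), key=lambda e: e.start)
        if gene.strand == "-":
            exon_ivs = exon_ivs[::-1]
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, exon_ivs))

    for exon in db.features_of_type("exon"):
        if exon.id not in claimed_exons:
            raise AnnotationError(
                f"exon {exon.id!r} at {exon.seqid}:{exon.start}-{exon.end} "
                "has no parent gene"
            )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as a minimal gene→exon GFF3 file (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            span = gene.span
            fh.write(
                "\t".join(
                    [
                        gene.contig_id,
                        "stemfuse",
                        "gene",
                        str(span.start + 1),
                        str(span.end),
                        ".",
                        gene.strand,
                        ".",
                        f"ID={gene.gene_id}",
                    ]
                )
                + "\n"
            )
            for num, exon in enumerate(gene.exons, start=1):
                fh.write(
                    "\t".join(
                        [
                            gene.contig_id,
                            "stemfuse",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            gene.strand,
                            ".",
                            f"ID={gene.gene_id}.exon{num};Parent={gene.gene_id}",
                        ]
                    )
                    + "\n"
                )


def gene_by_id(genes: Iterable[GeneModel], gene_id: str) -> GeneModel:
    for g in genes:
        if g.gene_id == gene_id:
            return g
    raise AnnotationError(f"gene {gene_id!r} not found in annotation")
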