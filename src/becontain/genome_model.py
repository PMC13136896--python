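"""Sequence and annotation data model for the start-codon editing screen.

Internal coordinates are 0-based half-open on the forward strand everywhere.
All GFF3 input/output uses the standard 1-based inclusive convention; the
documented TSV gene-table dialect is also 1-based inclusive.

A :class:`Genome` is a single contig over the alphabet ``{A, C, G, T, N}``
with linear or circular topology; circular genomes allow wrap-around
subsequence extraction (the *E. coli* chromosome is circular, but wrapping
must be requested explicitly to avoid silent origin-spanning bugs).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ILLEGAL = re.compile(r"[^ACGTN]")

STRANDS = ("+", "-")


class SequenceError(ValueError):
    """Raised for malformed sequences or out-of-range coordinate access."""


class AnnotationError(ValueError):
    """Raised for malformed or out-of-bounds gene annotations."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over ``{A,C,G,T,N}``.

    Involution: ``revcomp(revcomp(s)) == s``. ``N`` complements to ``N``.
    """
    m = _ILLEGAL.search(seq)
    if m:
        raise SequenceError(
            f"illegal base {m.group(0)!r} at position {m.start()}"
        )
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Genome:
    """A single-contig genome sequence with explicit topology."""

    id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise SequenceError(f"unknown topology {self.topology!r}")
        if len(self.sequence) < 1:
            raise SequenceError("genome sequence must be non-empty")
        seq = self.sequence.upper()
        m = _ILLEGAL.search(seq)
        if m:
            raise SequenceError(
                f"illegal base {m.group(0)!r} at position {m.start()} "
                f"of genome {self.id!r}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def circular(self) -> bool:
        return self.topology == "circular"

    def fetch(self, start: int, end: int) -> str:
        """Forward-strand subsequence ``[start, end)``.

        On circular genomes coordinates may run off either end (wrap-around);
        on linear genomes out-of-range access raises :class:`SequenceError`.
        """
        if end < start:
            raise SequenceError(f"inverted interval [{start}, {end})")
        n = len(self.sequence)
        if not self.circular:
            if start < 0 or end > n:
                raise SequenceError(
                    f"interval [{start}, {end}) outside linear genome of "
                    f"length {n}"
                )
            return self.sequence[start:end]
        if end - start > n:
            raise SequenceError(
                f"interval [{start}, {end}) longer than circular genome"
            )
        i = start % n
        return (self.sequence + self.sequence)[i : i + (end - start)]

    def base(self, pos: int) -> str:
        return self.fetch(pos, pos + 1)


def start_codon_of(start: int, end: int, strand: str, genome: Genome) -> str:
    """First codon of a CDS ``[start, end)`` read 5'->3' on ``strand``."""
    if strand == "+":
        return genome.fetch(start, start + 3)
    if strand == "-":
        return revcomp(genome.fetch(end - 3, end))
    raise AnnotationError(f"unknown strand {strand!r}")


@dataclass(frozen=True)
class GeneRecord:
    """A strand-aware CDS with pathway tag and essentiality flag.

    ``start_codon`` is derived from the genome at construction time via
    :meth:`from_interval`; it is the first 3 nt of the CDS read in gene
    orientation.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    pathway: str = ""
    essential: bool = True
    start_codon: str = ""

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise AnnotationError(
                f"unknown strand {self.strand!r} for gene {self.gene_id!r}"
            )
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"bad CDS interval [{self.start}, {self.end}) for gene "
                f"{self.gene_id!r}"
            )
        if self.end - self.start < 3:
            raise AnnotationError(
                f"CDS of gene {self.gene_id!r} shorter than one codon"
            )

    @classmethod
    def from_interval(
        cls,
        gene_id: str,
        start: int,
        end: int,
        strand: str,
        genome: Genome,
        pathway: str = "",
        essential: bool = True,
    ) -> "GeneRecord":
        if end > len(genome):
            raise AnnotationError(
                f"CDS [{start}, {end}) of gene {gene_id!r} exceeds genome "
                f"length {len(genome)}"
            )
        return cls(
            gene_id=gene_id,
            start=start,
            end=end,
            strand=strand,
            pathway=pathway,
            essential=essential,
            start_codon=start_codon_of(start, end, strand, genome),
        )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class StartContext:
    """Sequence around a start codon, in gene orientation.

    Position ``upstream_len`` of :attr:`sequence` is the A of the start
    codon.  :meth:`forward_coord` maps a context index invertibly back to the
    forward-strand genome coordinate (modulo genome length on circular
    genomes).
    """

    gene_id: str
    upstream_len: int
    downstream_len: int
    sequence: str
    strand: str
    #: forward-strand coordinate of context position 0 before orientation;
    #: for "-" genes this is the *highest* coordinate of the span.
    origin: int

    def __post_init__(self) -> None:
        if len(self.sequence) != self.upstream_len + self.downstream_len:
            raise SequenceError(
                "context sequence length does not match upstream + downstream"
            )

    def forward_coord(self, i: int) -> int:
        if not 0 <= i < len(self.sequence):
            raise SequenceError(f"context index {i} out of range")
        return self.origin + i if self.strand == "+" else self.origin - i

    def context_index(self, forward: int) -> int:
        i = forward - self.origin if self.strand == "+" else self.origin - forward
        if not 0 <= i < len(self.sequence):
            raise SequenceError(
                f"forward coordinate {forward} outside context span"
            )
        return i

    @property
    def start_codon(self) -> str:
        return self.sequence[self.upstream_len : self.upstream_len + 3]


def extract_start_context(
    gene: GeneRecord, genome: Genome, upstream: int, downstream: int
) -> StartContext:
    """Extract ``upstream`` nt of 5' context plus ``downstream`` nt of CDS-side
    sequence around the start codon, read in gene orientation.

    ``upstream=0, downstream=3`` returns exactly the start codon.  Circular
    genomes wrap across the origin; linear genomes raise if the span runs out
    of bounds.
    """
    if upstream < 0 or downstream < 0:
        raise SequenceError("context lengths must be non-negative")
    n = len(genome)
    if gene.strand == "+":
        lo, hi = gene.start - upstream, gene.start + downstream
        seq = genome.fetch(lo, hi)
        origin = lo % n if genome.circular else lo
    else:
        lo, hi = gene.end - downstream, gene.end + upstream
        seq = revcomp(genome.fetch(lo, hi))
        origin = (hi - 1) % n if genome.circular else hi - 1
    return StartContext(
        gene_id=gene.gene_id,
        upstream_len=upstream,
        downstream_len=downstream,
        sequence=seq,
        strand=gene.strand,
        origin=origin,
    )


# ---------------------------------------------------------------------------
# readers / writers


def read_genome(
    path: str | Path,
    record_id: str | None = None,
    topology: str = "linear",
) -> Genome:
    """Read a genome from a FASTA file.

    Multi-record files are rejected unless ``record_id`` selects one record.
    Sequences are uppercased and validated against ``{A,C,G,T,N}``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    if record_id is not None:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise SequenceError(f"record {record_id!r} not found in {path}")
        rec = matches[0]
    elif len(records) > 1:
        raise SequenceError(
            f"{path} holds {len(records)} records; pass record_id to choose one"
        )
    else:
        rec = records[0]
    return Genome(id=rec.id, sequence=str(rec.seq), topology=topology)


def write_genome_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.sequence), width):
            fh.write(genome.sequence[i : i + width] + "\n")


_GENE_TABLE_COLUMNS = ["gene_id", "start", "end", "strand", "pathway", "essential"]


def read_gene_table(path: str | Path, genome: Genome) -> list[GeneRecord]:
    """Read the documented TSV gene-table dialect.

    Tab-separated columns ``gene_id, start(1-based), end(inclusive),
    strand(+/-), pathway, essential(0/1)``; lines starting with ``#`` are
    comments.
    """
    frame = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=_GENE_TABLE_COLUMNS,
        dtype={"gene_id": str, "pathway": str},
        keep_default_na=False,
    )
    records = []
    for row in frame.itertuples(index=False):
        start1, end1 = int(row.start), int(row.end)
        if start1 < 1 or end1 < start1:
            raise AnnotationError(
                f"bad 1-based interval {start1}..{end1} for gene {row.gene_id!r}"
            )
        records.append(
            GeneRecord.from_interval(
                gene_id=str(row.gene_id),
                start=start1 - 1,
                end=end1,
                strand=str(row.strand),
                genome=genome,
                pathway=str(row.pathway),
                essential=bool(int(row.essential)),
            )
        )
    return records


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(_GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.start + 1}\t{g.end}\t{g.strand}\t"
                f"{g.pathway}\t{int(g.essential)}\n"
            )


def read_gff3(path: str | Path, genome: Genome) -> list[GeneRecord]:
    """Read CDS features from a GFF3 file (1-based inclusive coordinates)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    records = []
    for feat in db.features_of_type("CDS", order_by="start"):
        attrs = feat.attributes
        gene_id = None
        for key in ("ID", "gene", "locus_tag", "Name"):
            if key in attrs:
                gene_id = attrs[key][0]
                break
        if gene_id is None:
            raise AnnotationError(f"CDS at {feat.start}..{feat.end} has no id")
        pathway = attrs["pathway"][0] if "pathway" in attrs else ""
        essential = True
        if "essential" in attrs:
            essential = attrs["essential"][0] not in ("0", "false", "False")
        if feat.strand not in STRANDS:
            raise AnnotationError(
                f"unknown strand {feat.strand!r} for CDS {gene_id!r}"
            )
        records.append(
            GeneRecord.from_interval(
                gene_id=gene_id,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                genome=genome,
                pathway=pathway,
                essential=essential,
            )
        )
    return records


def write_gff3(
    genes: Iterable[GeneRecord], genome: Genome, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for g in genes:
            attrs = f"ID={g.gene_id};pathway={g.pathway};essential={int(g.essential)}"
            fh.write(
                f"{genome.id}\tbecontain\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t0\t{attrs}\n"
            )


def read_annotation(
    path: str | Path, genome: Genome, fmt: str | None = None
) -> list[GeneRecord]:
    """Read gene annotations from GFF3 or the TSV gene-table dialect.

    Format is sniffed from the file suffix unless ``fmt`` ("gff3" or "tsv")
    is given.
    """
    if fmt is None:
        suffix = Path(path).suffix.lower()
        fmt = "gff3" if suffix in (".gff", ".gff3") else "tsv"
    if fmt == "gff3":
        return read_gff3(path, genome)
    if fmt == "tsv":
        return read_gene_table(path, genome)
    raise AnnotationError(f"unknown annotation format {fmt!r}")
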