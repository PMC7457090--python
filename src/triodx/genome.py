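"""Toy genomes and gene models.

A :class:`ToyGenome` is a single synthetic chromosome carrying an ordered set of
protein-coding :class:`GeneModel` entries. It stands in for a contiguous
multi-gene region of a real chromosome arm so that every downstream stage
(variant filtering, copy-number ratios, splice-consequence modelling) can be
exercised with fully known truth.

All coordinates are 1-based inclusive throughout (VCF/HGVS convention).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

STOP_CODONS = ("TAA", "TAG", "TGA")
#: every codon that does not terminate translation, in fixed lexicographic order
NONSTOP_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
)

MIN_INTRON_LENGTH = 20


class GenomeError(ValueError):
    """Raised when a genome or gene model violates its invariants."""


@dataclass
class GeneModel:
    """One protein-coding gene: exon structure, CDS bounds, panel membership.

    Exons are 1-based inclusive genomic intervals, sorted and non-overlapping.
    ``panel`` flags membership in the clinically relevant disease-gene panel.
    """

    gene_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    panel: bool = False

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def introns(self) -> list[tuple[int, int]]:
        """Intervals between consecutive exons (genomic order)."""
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    def exon_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.exons]

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def exon_of(self, pos: int) -> int | None:
        """1-based exon ordinal containing ``pos``, or None."""
        for i, (s, e) in enumerate(self.exons, start=1):
            if s <= pos <= e:
                return i
        return None

    def intron_of(self, pos: int) -> int | None:
        """1-based intron ordinal (genomic order) containing ``pos``, or None."""
        for i, (s, e) in enumerate(self.introns(), start=1):
            if s <= pos <= e:
                return i
        return None

    def cds_position(self, pos: int) -> int | None:
        """1-based position within the spliced CDS for an exonic genomic ``pos``.

        Only implemented for '+'-strand genes whose CDS spans all exons (the
        toy-genome convention); returns None for intronic positions.
        """
        if self.strand != "+":
            raise NotImplementedError("cds_position is defined for '+' strand genes")
        offset = 0
        for s, e in self.exons:
            if s <= pos <= e:
                return offset + (pos - s) + 1
            offset += e - s + 1
        return None

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise GenomeError(f"{self.gene_id}: no exons")
        for s, e in self.exons:
            if s > e:
                raise GenomeError(f"{self.gene_id}: inverted exon ({s}, {e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise GenomeError(f"{self.gene_id}: exons unsorted or overlapping")
            if s2 - e1 - 1 < MIN_INTRON_LENGTH:
                raise GenomeError(f"{self.gene_id}: intron shorter than {MIN_INTRON_LENGTH}")
        if not (self.start <= self.cds_start <= self.cds_end <= self.end):
            raise GenomeError(f"{self.gene_id}: CDS outside gene span")


@dataclass
class ToyGenome:
    """A synthetic chromosome with an ordered, non-overlapping gene set."""

    chrom: str
    sequence: str
    genes: list[GeneModel] = field(default_factory=list)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of the 1-based inclusive interval [start, end]."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise GenomeError(f"interval ({start}, {end}) outside chromosome")
        return self.sequence[start - 1 : end]

    def base(self, pos: int) -> str:
        return self.fetch(pos, pos)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def gene_by_number(self, number: int) -> GeneModel:
        """Gene by 1-based positional number along the chromosome."""
        return self.genes[number - 1]

    def spliced_cds(self, gene: GeneModel) -> str:
        """Concatenated exon sequence in transcript orientation."""
        seq = "".join(self.fetch(s, e) for s, e in gene.exons)
        if gene.strand == "-":
            seq = reverse_complement(seq)
        return seq

    def validate(self) -> None:
        for g in self.genes:
            g.validate()
            if g.end > len(self.sequence):
                raise GenomeError(f"{g.gene_id}: extends past chromosome end")
            if len(self.spliced_cds(g)) % 3 != 0:
                raise GenomeError(f"{g.gene_id}: CDS length not a multiple of 3")
        for a, b in zip(self.genes, self.genes[1:]):
            if b.start <= a.end:
                raise GenomeError(f"genes {a.gene_id}/{b.gene_id} overlap or unsorted")

    # ---------------------------------------------------------------- file IO

    def write_fasta(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i : i + 70] + "\n")

    def write_gene_table(self, path: str | Path) -> None:
        """Tab-delimited gene/exon table. Coordinates are 1-based inclusive."""
        cols = ["gene_id", "chrom", "strand", "exon_starts", "exon_ends",
                "cds_start", "cds_end", "panel"]
        with Path(path).open("w") as fh:
            fh.write("\t".join(cols) + "\n")
            for g in self.genes:
                fh.write(
                    "\t".join([
                        g.gene_id,
                        self.chrom,
                        g.strand,
                        ",".join(str(s) for s, _ in g.exons),
                        ",".join(str(e) for _, e in g.exons),
                        str(g.cds_start),
                        str(g.cds_end),
                        "1" if g.panel else "0",
                    ]) + "\n"
                )

    @classmethod
    def read(cls, fasta_path: str | Path, gene_table_path: str | Path) -> "ToyGenome":
        record = next(SeqIO.parse(str(fasta_path), "fasta"))
        genes: list[GeneModel] = []
        with Path(gene_table_path).open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                starts = [int(x) for x in row["exon_starts"].split(",")]
                ends = [int(x) for x in row["exon_ends"].split(",")]
                genes.append(
                    GeneModel(
                        gene_id=row["gene_id"],
                        strand=row["strand"],
                        exons=list(zip(starts, ends)),
                        cds_start=int(row["cds_start"]),
                        cds_end=int(row["cds_end"]),
                        panel=row["panel"] == "1",
                    )
                )
        return cls(chrom=record.id, sequence=str(record.seq).upper(), genes=genes)


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
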