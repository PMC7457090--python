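"""Splice-acceptor disruption modelled as intron retention, PTC, and NMD.

A variant in the splice-acceptor region (here, offsets -1..-8 upstream of an
exon; -1..-2 are the canonical AG) is modelled as causing full retention of
the affected intron in the mature transcript. The retained-intron mRNA is
translated from the CDS start; the first in-frame stop at or after the
disrupted exon-intron junction is the premature termination codon (PTC), and
the number of complete codons strictly between the junction and the stop is
the count of additional amino acids appended before termination. The
transcript is predicted to undergo nonsense-mediated decay (NMD) when the PTC
lies at least 50 nt upstream of the last remaining exon-exon junction (the
operational 50-nt rule).

Negative-strand genes are handled by reverse-complementing once at model
construction; everything downstream works in transcript orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .genome import GeneModel, ToyGenome, reverse_complement

STOP_CODONS = {"TAA", "TAG", "TGA"}

CANONICAL_ACCEPTOR = (-2, -1)
ACCEPTOR_REGION = (-8, -3)
CANONICAL_DONOR = (1, 2)
DONOR_REGION = (3, 6)


class MappingError(ValueError):
    """Variant position outside the gene, or invalid intron ordinal."""


@dataclass
class TranscriptModel:
    """Exon and intron sequences of one gene, in transcript orientation."""

    gene_id: str
    strand: str
    exon_seqs: list[str]
    intron_seqs: list[str]
    cds_start: int = 0  # 0-based offset of the CDS within the spliced transcript
    # genomic intervals in genomic order, used to map variant positions
    exon_intervals: list[tuple[int, int]] = field(default_factory=list)
    intron_intervals: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def from_gene(cls, genome: ToyGenome, gene: GeneModel) -> "TranscriptModel":
        exon_seqs = [genome.fetch(s, e) for s, e in gene.exons]
        intron_seqs = [genome.fetch(s, e) for s, e in gene.introns()]
        if gene.strand == "-":
            exon_seqs = [reverse_complement(s) for s in reversed(exon_seqs)]
            intron_seqs = [reverse_complement(s) for s in reversed(intron_seqs)]
        return cls(
            gene_id=gene.gene_id,
            strand=gene.strand,
            exon_seqs=exon_seqs,
            intron_seqs=intron_seqs,
            cds_start=0,
            exon_intervals=list(gene.exons),
            intron_intervals=list(gene.introns()),
        )

    @property
    def n_introns(self) -> int:
        return len(self.intron_seqs)

    def spliced(self) -> str:
        return "".join(self.exon_seqs)

    def spliced_junctions(self) -> list[int]:
        """Exon-exon junction offsets in the fully spliced transcript."""
        out, acc = [], 0
        for seq in self.exon_seqs[:-1]:
            acc += len(seq)
            out.append(acc)
        return out


def classify_splice_position(
    pos: int, genome_gene: GeneModel
) -> tuple[str, int | None, int | None]:
    """Splice classification of a genomic position within a gene.

    Returns (class, intron ordinal, offset) with class in {"canonical-splice",
    "splice-region", "none"}. The ordinal and offset are in transcript
    orientation: donor offsets are positive from the intron's 5' end,
    acceptor offsets negative from its 3' end (acceptor -1 is the intron's
    last base). Offsets -1..-2 / +1..+2 are canonical; -3..-8 / +3..+6 are
    splice region.
    """
    if not genome_gene.contains(pos):
        raise MappingError(f"position {pos} outside gene {genome_gene.gene_id}")
    introns = genome_gene.introns()
    n = len(introns)
    for gi, (s, e) in enumerate(introns, start=1):
        if not (s <= pos <= e):
            continue
        if genome_gene.strand == "+":
            ordinal = gi
            donor_off = pos - s + 1
            acceptor_off = pos - e - 1  # e -> -1
        else:
            ordinal = n - gi + 1
            donor_off = e - pos + 1
            acceptor_off = -(pos - s + 1)  # s -> -1
        if CANONICAL_DONOR[0] <= donor_off <= CANONICAL_DONOR[1]:
            return "canonical-splice", ordinal, donor_off
        if CANONICAL_ACCEPTOR[0] <= acceptor_off <= CANONICAL_ACCEPTOR[1]:
            return "canonical-splice", ordinal, acceptor_off
        if DONOR_REGION[0] <= donor_off <= DONOR_REGION[1]:
            return "splice-region", ordinal, donor_off
        if ACCEPTOR_REGION[0] <= acceptor_off <= ACCEPTOR_REGION[1]:
            return "splice-region", ordinal, acceptor_off
        return "none", ordinal, None
    return "none", None, None


def retained_intron_transcript(
    model: TranscriptModel, intron_ordinal: int
) -> tuple[str, list[int], int]:
    """mRNA with one intron retained, its exon-exon junctions, and the
    disrupted junction position.

    ``intron_ordinal`` is 1-based in transcript orientation; 0 means retain
    nothing (control), returning the spliced transcript with all junctions
    and -1 for the disrupted junction. Junction positions are 0-based offsets
    of the boundary (number of nucleotides before it).
    """
    if intron_ordinal == 0:
        return model.spliced(), model.spliced_junctions(), -1
    if not (1 <= intron_ordinal <= model.n_introns):
        raise MappingError(
            f"intron ordinal {intron_ordinal} invalid for {model.gene_id} "
            f"({model.n_introns} introns)"
        )
    k = intron_ordinal
    parts = model.exon_seqs[:k] + [model.intron_seqs[k - 1]] + model.exon_seqs[k:]
    seq = "".join(parts)

    junctions, acc = [], 0
    for j, exon in enumerate(model.exon_seqs[:-1], start=1):
        acc += len(exon)
        if j == k:
            acc += len(model.intron_seqs[k - 1])
            continue  # this boundary is exon-intron now, not exon-exon
        junctions.append(acc)
    disrupted = sum(len(e) for e in model.exon_seqs[:k])
    return seq, junctions, disrupted


@dataclass
class SpliceConsequence:
    """Outcome of one retained-intron event."""

    retained_intron: int
    ptc_present: bool
    ptc_position: int | None  # 0-based offset of the stop codon's first base
    additional_aa: int | None  # complete codons strictly between junction and stop
    ptc_in_retained_intron: bool | None
    nmd_predicted: bool
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "retained_intron": self.retained_intron,
            "ptc_present": self.ptc_present,
            "ptc_position": self.ptc_position,
            "additional_aa": self.additional_aa,
            "ptc_in_retained_intron": self.ptc_in_retained_intron,
            "nmd_predicted": self.nmd_predicted,
            "flags": self.flags,
        }


def find_ptc(
    mrna: str, cds_start: int, junction: int
) -> tuple[bool, int | None, int | None, list[str]]:
    """Locate the premature stop created downstream of a disrupted junction.

    Translates codon-by-codon from ``cds_start``; the PTC is the first stop
    codon ending after the junction. Returns (ptc_present, ptc_position,
    additional_aa, flags). A transcript with no stop at all is flagged
    "no PTC (read-through)" rather than raising.
    """
    if junction < cds_start:
        raise MappingError("junction upstream of CDS start")
    flags: list[str] = []
    ptc_pos = None
    for i in range(cds_start, len(mrna) - 2, 3):
        codon = mrna[i : i + 3].upper()
        if codon in STOP_CODONS and i + 3 > junction:
            ptc_pos = i
            break
    if ptc_pos is None:
        return False, None, None, ["no PTC (read-through)"]
    # first codon boundary at or after the junction
    first_after = cds_start + 3 * -(-(junction - cds_start) // 3)
    additional = max(0, (ptc_pos - first_after) // 3)
    return True, ptc_pos, additional, flags


def predict_nmd(
    ptc_position: int, junctions: list[int], min_distance: int = 50
) -> bool:
    """The 50-nt rule: NMD iff the PTC starts >= ``min_distance`` nt upstream
    of the last exon-exon junction. A PTC in the final exon never triggers."""
    if not junctions:
        return False
    return (max(junctions) - ptc_position) >= min_distance


def splice_consequence(
    model: TranscriptModel, intron_ordinal: int, nmd_min_distance: int = 50
) -> SpliceConsequence:
    """Full chain: retain the intron, locate the PTC, predict NMD."""
    mrna, junctions, junction = retained_intron_transcript(model, intron_ordinal)
    present, ptc_pos, additional, flags = find_ptc(mrna, model.cds_start, junction)
    in_intron = None
    if present:
        intron_len = len(model.intron_seqs[intron_ordinal - 1])
        in_intron = junction <= ptc_pos < junction + intron_len
        if not in_intron:
            flags.append("PTC beyond retained intron")
    nmd = predict_nmd(ptc_pos, junctions, nmd_min_distance) if present else False
    return SpliceConsequence(
        retained_intron=intron_ordinal,
        ptc_present=present,
        ptc_position=ptc_pos,
        additional_aa=additional,
        ptc_in_retained_intron=in_intron,
        nmd_predicted=nmd,
        flags=flags,
    )


def translate_cds(seq: str) -> str:
    """Translate a CDS (utility for model checking)."""
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate())
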