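"""Synthetic trio-exome scenes with planted, fully serialized truth.

The generator emulates the study design the pipeline is built for: a family
trio (father, mother, proband) where the proband carries a compound
heterozygote in one disease-panel gene — a splice-acceptor SNV on the paternal
chromosome in trans with a multi-gene heterozygous deletion inherited from the
mother. Because a diploid-assuming caller cannot see the deleted allele, the
proband's (and, within the deletion, the mother's) genotypes are emitted as a
caller would report them: hemizygous sites appear homozygous for the remaining
allele. That artifact — not an error to be cleaned away — is precisely the
signal the downstream Mendelian-inconsistency stage must detect.

Planted alongside are a benign missense surviving the cascade as a classic
autosomal-recessive homozygote (both parents het, proband hom-alt), and
background variants engineered to be removed at specific cascade stages
(non-panel gene, synonymous/deep-intronic consequence, common allele,
non-recessive transmission, weak in-silico support). Exon read counts follow a
negative binomial with mean proportional to exon length x depth x copy/2.

Every planted event is recoverable from the serialized :class:`TrioTruth`
without re-reading the generated files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

from .cnv import ReadCountMatrix
from .genome import NONSTOP_CODONS, STOP_CODONS, GeneModel, GenomeError, ToyGenome
from .variant_io import AnnotatedVariant, Genotype, TrioGenotype

BASES = "ACGT"
SCORE_TOOLS = ("sift", "polyphen2", "provean", "fathmm", "mutationtaster",
               "dbscsnv_ada", "dbscsnv_rf")


class ScenarioError(ValueError):
    """Planted scenario inconsistent with the genome (bad span/target)."""


# --------------------------------------------------------------------- genome


def build_toy_genome(
    n_genes: int = 22,
    seed: int = 7,
    exon_codons: tuple[int, int] = (20, 60),
    exons_per_gene: tuple[int, int] = (3, 8),
    intron_length: tuple[int, int] = (60, 140),
    intergenic_length: tuple[int, int] = (200, 400),
    panel_fraction: float = 0.5,
    chrom: str = "chr_sim",
) -> ToyGenome:
    """Deterministically generate a multi-gene chromosome.

    Exon lengths are drawn as whole codons (so every exon boundary falls on a
    codon boundary), each CDS starts with ATG, ends with TAA and contains no
    internal stop; introns are canonical GT...AG with a C at acceptor -3 and
    length >= 60. All genes are generated on the '+' strand.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for lo, hi in (exon_codons, exons_per_gene, intron_length, intergenic_length):
        if lo <= 0 or hi < lo:
            raise ValueError("length parameters must be positive with lo <= hi")
    if intron_length[0] < 30:
        raise ValueError("introns must be at least 30 bp to hold splice signals")

    rng = np.random.default_rng(seed)
    pieces: list[str] = []
    genes: list[GeneModel] = []
    cursor = 0  # 0-based length emitted so far

    def rand_seq(n: int) -> str:
        return "".join(rng.choice(list(BASES), size=n))

    for gi in range(n_genes):
        pieces.append(rand_seq(int(rng.integers(intergenic_length[0], intergenic_length[1] + 1))))
        cursor = sum(len(p) for p in pieces)

        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        exon_lens = [3 * int(rng.integers(exon_codons[0], exon_codons[1] + 1))
                     for _ in range(n_ex)]
        n_codons = sum(exon_lens) // 3
        cds = "ATG" + "".join(rng.choice(NONSTOP_CODONS, size=n_codons - 2)) + "TAA"

        exons: list[tuple[int, int]] = []
        cds_cursor = 0
        for ei, elen in enumerate(exon_lens):
            start = cursor + 1  # 1-based
            pieces.append(cds[cds_cursor : cds_cursor + elen])
            cds_cursor += elen
            cursor += elen
            exons.append((start, cursor))
            if ei < n_ex - 1:
                ilen = int(rng.integers(intron_length[0], intron_length[1] + 1))
                pieces.append("GT" + rand_seq(ilen - 5) + "CAG")
                cursor += ilen
        genes.append(
            GeneModel(
                gene_id=f"GENE{gi + 1:02d}",
                strand="+",
                exons=exons,
                cds_start=exons[0][0],
                cds_end=exons[-1][1],
                panel=bool(rng.random() < panel_fraction),
            )
        )
    pieces.append(rand_seq(int(rng.integers(intergenic_length[0], intergenic_length[1] + 1))))
    genome = ToyGenome(chrom=chrom, sequence="".join(pieces), genes=genes)
    genome.validate()
    return genome


# ---------------------------------------------------------------- truth model


@dataclass
class SimVariant:
    """One simulated variant with its annotations and parental haplotypes.

    ``father_hap``/``mother_hap`` give the alt-allele dose on each parental
    haplotype; ``transmission`` records which haplotype each parent passed to
    the proband. Observed (caller-visible) genotypes are derived from these
    together with the deletion geometry.
    """

    pos: int
    ref: str
    alt: str
    gene_id: str
    category: str
    consequence: str
    hgvs_c: str
    maf_taiwanese: float
    maf_eas: float
    father_hap: tuple[int, int]
    mother_hap: tuple[int, int]
    transmission: tuple[int, int]
    scores: dict[str, float] = field(default_factory=dict)
    conservation: float | None = None
    intron_ordinal: int | None = None
    acceptor_offset: int | None = None


@dataclass
class PlantedDeletion:
    start: int
    end: int
    carrier: str
    gene_span: tuple[int, int]  # 1-based gene numbers, inclusive
    gene_ids: list[str]


@dataclass
class TrioTruth:
    """Full serialized truth for one simulated family scenario."""

    seed: int
    chrom: str
    snv: SimVariant
    deletion: PlantedDeletion | None
    benign: SimVariant
    background: list[SimVariant]
    snv_carrier: str = "father"
    mother_deleted_hap: int = 1
    deletion_in_counts: bool = True

    def __post_init__(self) -> None:
        if self.deletion is not None and self.deletion.carrier == self.snv_carrier:
            raise ScenarioError("SNV carrier and deletion carrier must differ")

    def all_variants(self) -> list[SimVariant]:
        return sorted([self.snv, self.benign, *self.background], key=lambda v: v.pos)

    def in_deletion(self, pos: int) -> bool:
        return self.deletion is not None and self.deletion.start <= pos <= self.deletion.end

    def observed_alleles(self, v: SimVariant) -> dict[str, tuple[int, int]]:
        """Caller-visible allele pairs per sample (0=ref, 1=alt).

        Inside the heterozygous deletion the mother and proband each have one
        haplotype, which a diploid caller reports as homozygous.
        """
        in_del = self.in_deletion(v.pos)
        father = tuple(sorted(v.father_hap))
        if in_del:
            m = v.mother_hap[1 - self.mother_deleted_hap]
            mother = (m, m)
        else:
            mother = tuple(sorted(v.mother_hap))
        paternal = v.father_hap[v.transmission[0]]
        if in_del:
            proband = (paternal, paternal)
        else:
            maternal = v.mother_hap[v.transmission[1]]
            proband = tuple(sorted((paternal, maternal)))
        return {"father": father, "mother": mother, "proband": proband}

    def copy_states(self, genome: ToyGenome) -> dict[str, dict[str, int]]:
        """Per-sample, per-gene copy numbers implied by the planted deletion."""
        states = {s: {g.gene_id: 2 for g in genome.genes} for s in ("father", "mother", "proband")}
        if self.deletion is not None and self.deletion_in_counts:
            for gid in self.deletion.gene_ids:
                states["mother"][gid] = 1
                states["proband"][gid] = 1
        return states

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TrioTruth":
        raw = json.loads(Path(path).read_text())

        def mkvar(d: dict) -> SimVariant:
            d = dict(d)
            for k in ("father_hap", "mother_hap", "transmission"):
                d[k] = tuple(d[k])
            return SimVariant(**d)

        deletion = raw["deletion"]
        if deletion is not None:
            deletion["gene_span"] = tuple(deletion["gene_span"])
            deletion = PlantedDeletion(**deletion)
        return cls(
            seed=raw["seed"],
            chrom=raw["chrom"],
            snv=mkvar(raw["snv"]),
            deletion=deletion,
            benign=mkvar(raw["benign"]),
            background=[mkvar(d) for d in raw["background"]],
            snv_carrier=raw["snv_carrier"],
            mother_deleted_hap=raw["mother_deleted_hap"],
            deletion_in_counts=raw["deletion_in_counts"],
        )


# ------------------------------------------------------------------- planting


def _rewrite_target_intron(genome: ToyGenome, gene: GeneModel, ordinal: int,
                           rng: np.random.Generator) -> None:
    """Rewrite one intron so retention yields a PTC after 5 extra codons.

    Layout (junction falls on a codon boundary by construction): GT + 1 random
    base (first retained codon, never a stop), 4 non-stop codons, TAA, random
    filler, CAG acceptor. Total length is preserved.
    """
    s, e = gene.introns()[ordinal - 1]
    length = e - s + 1
    if length < 24:
        raise ScenarioError("target intron too short to host the planted stop")
    body = (
        "GT"
        + rng.choice(list(BASES))
        + "".join(rng.choice(NONSTOP_CODONS, size=4))
        + "TAA"
    )
    filler = "".join(rng.choice(list(BASES), size=length - len(body) - 3))
    new_intron = body + filler + "CAG"
    assert len(new_intron) == length
    seq = genome.sequence
    genome.sequence = seq[: s - 1] + new_intron + seq[e:]


def _nonsynonymous_middle_base(codon: str, rng: np.random.Generator) -> str:
    """Alt for the codon's middle base giving a non-stop amino-acid change."""
    aa = str(Seq(codon).translate())
    options = []
    for b in BASES:
        if b == codon[1]:
            continue
        new = codon[0] + b + codon[2]
        if new in STOP_CODONS:
            continue
        if str(Seq(new).translate()) != aa:
            options.append(b)
    if not options:
        raise ScenarioError(f"no nonsynonymous middle-base change for codon {codon}")
    return str(rng.choice(options))


def _benign_scores() -> dict[str, float]:
    # split missense evidence: SIFT and FATHMM deleterious,
    # PolyPhen-2 and PROVEAN tolerated, MutationTaster disease-causing
    return {"sift": 0.02, "polyphen2": 0.33, "provean": -1.83, "fathmm": -2.17,
            "mutationtaster": 0.8}


def _weak_scores(rng: np.random.Generator) -> dict[str, float]:
    # at most one damaging call (MutationTaster occasionally), below any quorum of 2
    return {
        "sift": round(float(rng.uniform(0.2, 1.0)), 3),
        "polyphen2": round(float(rng.uniform(0.0, 0.5)), 3),
        "provean": round(float(rng.uniform(-1.5, 1.0)), 2),
        "fathmm": round(float(rng.uniform(-1.0, 2.0)), 2),
        "mutationtaster": round(float(rng.uniform(0.0, 0.8)), 3),
    }


_BACKGROUND_CATEGORIES = ("nonpanel", "synonymous", "common", "nonAR", "weak", "intronic")


def plant_compound_het_scenario(
    genome: ToyGenome,
    target_gene: int = 13,
    deletion_genes: tuple[int, int] = (8, 15),
    seed: int = 0,
    n_background: int = 40,
    target_intron: int | None = None,
    plant_deletion: bool = True,
    deletion_in_counts: bool = True,
) -> TrioTruth:
    """Plant the compound-het scenario and background variants into ``genome``.

    The father receives a heterozygous acceptor-region SNV at offset -3 of the
    target gene's chosen intron; the mother a heterozygous deletion spanning
    ``deletion_genes`` (1-based gene numbers, inclusive); the proband inherits
    both. The target gene's intron sequence is rewritten in place so intron
    retention produces a premature stop after exactly 5 additional codons.

    ``plant_deletion=False`` keeps the pseudo-homozygous genotype pattern (as
    from a genotyping artifact) but removes the deletion itself;
    ``deletion_in_counts=False`` keeps the deletion in the genotype model but
    simulates read counts at copy 2, so CNV support is absent.
    """
    lo, hi = deletion_genes
    if not (1 <= lo <= hi <= len(genome.genes)):
        raise ScenarioError(f"deletion gene span {deletion_genes} outside genome")
    if not (lo <= target_gene <= hi):
        raise ScenarioError(f"target gene {target_gene} outside deletion span {deletion_genes}")
    gene = genome.gene_by_number(target_gene)
    if len(gene.exons) < 2:
        raise ScenarioError(f"target gene {gene.gene_id} has no intron")

    rng = np.random.default_rng(seed)
    ordinal = target_intron if target_intron is not None else max(1, len(gene.introns()) // 2)
    if not (1 <= ordinal <= len(gene.introns())):
        raise ScenarioError(f"intron ordinal {ordinal} invalid for {gene.gene_id}")
    _rewrite_target_intron(genome, gene, ordinal, rng)

    # make sure the diagnostic genes are on the disease panel
    gene.panel = True

    # --- splice-acceptor SNV at offset -3 (the C of the CAG acceptor)
    i_start, i_end = gene.introns()[ordinal - 1]
    snv_pos = i_end - 2
    assert genome.base(snv_pos) == "C"
    next_exon_cds = sum(gene.exon_lengths()[:ordinal]) + 1
    snv = SimVariant(
        pos=snv_pos, ref="C", alt="G", gene_id=gene.gene_id,
        category="planted_splice_snv", consequence="splice-region",
        hgvs_c=f"c.{next_exon_cds}-3C>G",
        maf_taiwanese=0.001, maf_eas=0.0001,
        father_hap=(1, 0), mother_hap=(0, 0), transmission=(0, 1),
        scores={"mutationtaster": 0.95, "dbscsnv_ada": 0.999, "dbscsnv_rf": 0.932},
        conservation=0.911,
        intron_ordinal=ordinal, acceptor_offset=-3,
    )

    # --- heterozygous multi-gene deletion carried by the mother
    deletion = None
    if plant_deletion:
        g_lo, g_hi = genome.gene_by_number(lo), genome.gene_by_number(hi)
        if lo > 1:
            start = (genome.gene_by_number(lo - 1).end + g_lo.start) // 2
        else:
            start = max(1, g_lo.start - 50)
        if hi < len(genome.genes):
            end = (g_hi.end + genome.gene_by_number(hi + 1).start) // 2
        else:
            end = min(len(genome.sequence), g_hi.end + 50)
        deletion = PlantedDeletion(
            start=start, end=end, carrier="mother",
            gene_span=(lo, hi),
            gene_ids=[genome.gene_by_number(i).gene_id for i in range(lo, hi + 1)],
        )

    used: set[int] = {snv_pos}

    # --- benign missense: classic AR homozygote in a panel gene off the deletion
    candidates = [i for i in list(range(hi + 1, len(genome.genes) + 1)) + list(range(1, lo))
                  if i != target_gene]
    if not candidates:
        raise ScenarioError("no gene available outside the deletion for the benign missense")
    benign_gene = genome.gene_by_number(candidates[0])
    benign_gene.panel = True
    cds = genome.spliced_cds(benign_gene)
    codon_index = len(cds) // 6  # roughly the middle of the protein
    codon = cds[3 * codon_index : 3 * codon_index + 3]
    cds_pos = 3 * codon_index + 2  # middle base, 1-based
    benign_pos = _cds_to_genomic(benign_gene, cds_pos)
    alt = _nonsynonymous_middle_base(codon, rng)
    aa_from = str(Seq(codon).translate())
    aa_to = str(Seq(codon[0] + alt + codon[2]).translate())
    benign = SimVariant(
        pos=benign_pos, ref=codon[1], alt=alt, gene_id=benign_gene.gene_id,
        category="planted_benign_missense", consequence="missense",
        hgvs_c=f"c.{cds_pos}{codon[1]}>{alt} (p.{aa_from}{codon_index + 1}{aa_to})",
        maf_taiwanese=0.034, maf_eas=0.020,
        father_hap=(1, 0), mother_hap=(0, 1), transmission=(0, 1),
        scores=_benign_scores(), conservation=0.841,
    )
    used.add(benign_pos)

    # --- stage-targeted background variants
    nonpanel_genes = [g for g in genome.genes if not g.panel]
    panel_genes = [g for g in genome.genes
                   if g.panel and g.gene_id != gene.gene_id]
    background: list[SimVariant] = []
    for i in range(n_background):
        category = _BACKGROUND_CATEGORIES[i % len(_BACKGROUND_CATEGORIES)]
        if category == "nonpanel" and not nonpanel_genes:
            category = "weak"
        bg_gene = _pick_gene(rng, nonpanel_genes if category == "nonpanel" else panel_genes)
        if category == "intronic" and len(bg_gene.exons) < 2:
            category = "synonymous"
        pos = _pick_position(rng, bg_gene, category, used)
        ref = genome.base(pos)
        alt = str(rng.choice([b for b in BASES if b != ref]))
        if category == "common":
            maf = round(float(rng.uniform(0.06, 0.40)), 3)
        else:
            maf = round(float(rng.uniform(0.0002, 0.045)), 4)
        maf_eas = round(min(1.0, maf * float(rng.uniform(0.5, 1.5))), 4)
        consequence = {"nonpanel": "missense", "synonymous": "synonymous",
                       "common": "missense", "nonAR": "missense",
                       "weak": "missense", "intronic": "intronic"}[category]
        father_hap, mother_hap, trans = _draw_genotypes(rng, category, pos, deletion)
        background.append(
            SimVariant(
                pos=pos, ref=ref, alt=alt, gene_id=bg_gene.gene_id,
                category=category, consequence=consequence,
                hgvs_c="", maf_taiwanese=maf, maf_eas=maf_eas,
                father_hap=father_hap, mother_hap=mother_hap, transmission=trans,
                scores=_weak_scores(rng),
                conservation=round(float(rng.uniform(0.0, 0.95)), 3),
            )
        )

    return TrioTruth(
        seed=seed, chrom=genome.chrom, snv=snv, deletion=deletion,
        benign=benign, background=background,
        deletion_in_counts=deletion_in_counts,
    )


def _cds_to_genomic(gene: GeneModel, cds_pos: int) -> int:
    """Genomic position of a 1-based CDS position ('+' strand toy genes)."""
    remaining = cds_pos
    for s, e in gene.exons:
        elen = e - s + 1
        if remaining <= elen:
            return s + remaining - 1
        remaining -= elen
    raise GenomeError(f"CDS position {cds_pos} beyond {gene.gene_id}")


def _pick_gene(rng: np.random.Generator, pool: list[GeneModel]) -> GeneModel:
    if not pool:
        raise ScenarioError("no gene available for background variant placement")
    return pool[int(rng.integers(len(pool)))]


def _pick_position(rng: np.random.Generator, gene: GeneModel, category: str,
                   used: set[int]) -> int:
    for _ in range(200):
        if category == "intronic":
            s, e = gene.introns()[int(rng.integers(len(gene.introns())))]
            # stay clear of donor +1..+6 and acceptor -1..-8 windows
            pos = int(rng.integers(s + 9, e - 9))
        else:
            s, e = gene.exons[int(rng.integers(len(gene.exons)))]
            pos = int(rng.integers(s, e + 1))
        if pos not in used:
            used.add(pos)
            return pos
    raise ScenarioError("could not place background variant without collision")


def _draw_genotypes(
    rng: np.random.Generator, category: str, pos: int,
    deletion: PlantedDeletion | None,
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
    in_del = deletion is not None and deletion.start <= pos <= deletion.end
    mat_trans = 1 if in_del else int(rng.integers(2))
    if category == "weak":
        # classic AR homozygote: both parents het, both alt alleles transmitted
        return (1, 0), (1, 0), (0, 0 if not in_del else 1)
    if category == "nonAR":
        # father carries the allele but transmits his reference haplotype
        return (1, 0), (0, 0), (1, mat_trans)
    for _ in range(50):
        father = (int(rng.random() < 0.35), int(rng.random() < 0.35))
        mother = (int(rng.random() < 0.35), int(rng.random() < 0.35))
        trans = (int(rng.integers(2)), mat_trans)
        if _visible(father, mother, trans, in_del):
            return father, mother, trans
    return (1, 0), (0, 0), (0, mat_trans)


def _visible(father, mother, trans, in_del) -> bool:
    """Would a caller emit this site at all (some observed alt allele)?"""
    if sum(father) > 0:
        return True
    if (mother[0] if in_del else sum(mother)) > 0:
        return True
    return False


# ------------------------------------------------------------------- emitters

_SAMPLES = ("father", "mother", "proband")


def emit_trio_vcf(truth: TrioTruth, genome: ToyGenome, path: str | Path) -> None:
    """Write the trio VCF exactly as a diploid-assuming caller would report it."""
    header = pysam.VariantHeader()
    header.contigs.add(genome.chrom, length=len(genome.sequence))
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in _SAMPLES:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in truth.all_variants():
            obs = truth.observed_alleles(v)
            rec = out.new_record(
                contig=genome.chrom, start=v.pos - 1, stop=v.pos,
                alleles=(v.ref, v.alt),
            )
            for s in _SAMPLES:
                rec.samples[s]["GT"] = obs[s]
                rec.samples[s].phased = False
            out.write(rec)


def emit_annotation_table(truth: TrioTruth, genome: ToyGenome, path: str | Path) -> None:
    """Tab-delimited annotation table keyed by (chrom, pos, ref, alt)."""
    rows = []
    for v in truth.all_variants():
        gene_number = next(i for i, g in enumerate(genome.genes, 1) if g.gene_id == v.gene_id)
        row = {
            "chrom": truth.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene": v.gene_id, "transcript": f"NM_{9000 + gene_number}.1",
            "hgvs_c": v.hgvs_c, "consequence": v.consequence,
            "maf_taiwanese": v.maf_taiwanese, "maf_eas": v.maf_eas,
        }
        for tool in SCORE_TOOLS:
            row[f"score_{tool}"] = v.scores.get(tool, np.nan)
        row["conservation"] = v.conservation
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_GT_ENUM = {(0, 0): Genotype.HOM_REF, (0, 1): Genotype.HET, (1, 1): Genotype.HOM_ALT}


def truth_to_variants(truth: TrioTruth, genome: ToyGenome) -> list[AnnotatedVariant]:
    """Build the in-memory AnnotatedVariant list directly from truth.

    Equivalent to emitting the VCF + annotation table and reading them back;
    used for fast many-seed simulation runs.
    """
    out = []
    for v in truth.all_variants():
        obs = truth.observed_alleles(v)
        gene_number = next(i for i, g in enumerate(genome.genes, 1) if g.gene_id == v.gene_id)
        out.append(
            AnnotatedVariant(
                chrom=truth.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                gene=v.gene_id, transcript=f"NM_{9000 + gene_number}.1",
                hgvs_c=v.hgvs_c, consequence=v.consequence,
                maf={"taiwanese": v.maf_taiwanese, "eas": v.maf_eas},
                scores=dict(v.scores), conservation=v.conservation,
                genotypes=TrioGenotype(*(_GT_ENUM[obs[s]] for s in _SAMPLES)),
            )
        )
    return out


# --------------------------------------------------------------- read counts


def simulate_exon_counts(
    genome: ToyGenome,
    copy_states: dict[str, dict[str, int]],
    depth: float = 100.0,
    dispersion: float = 0.05,
    seed: int = 0,
    read_length: int = 150,
    on_target_rate: float = 0.828,
    sample_factors: dict[str, float] | None = None,
) -> ReadCountMatrix:
    """Negative-binomial per-exon read counts proportional to copy number.

    Mean count for an exon = depth x sample factor x (exon length / read
    length) x copy/2; variance = mean + dispersion x mean^2 (Poisson when
    dispersion is 0). Per-sample library-size factors default to U(0.8, 1.2)
    so that total-mapped-read normalization is actually exercised.

    Total mapped reads per sample derive from the expected *diploid* on-target
    yield divided by the on-target rate. This emulates a whole-exome library in
    which the simulated region is a negligible fraction of the capture: a
    regional deletion must not shift the library size, otherwise normalization
    would bias every ratio of the carrier sample.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    samples = list(copy_states)
    for s in samples:
        for gid, copy in copy_states[s].items():
            if copy not in (0, 1, 2, 3, 4):
                raise ValueError(f"copy state {copy} for {s}/{gid} outside 0..4")
    rng = np.random.default_rng(seed)
    if sample_factors is None:
        sample_factors = {s: float(rng.uniform(0.8, 1.2)) for s in samples}

    rows = []
    for g in genome.genes:
        for ei, (s_, e_) in enumerate(g.exons, start=1):
            rows.append({"gene_id": g.gene_id, "exon": ei, "start": s_, "end": e_})
    df = pd.DataFrame(rows)
    lengths = (df["end"] - df["start"] + 1).to_numpy(dtype=float)
    gene_ids = df["gene_id"].to_numpy()

    for s in samples:
        copies = np.array([copy_states[s].get(g, 2) for g in gene_ids], dtype=float)
        mu = depth * sample_factors[s] * lengths / read_length * copies / 2.0
        counts = np.zeros(len(mu), dtype=np.int64)
        positive = mu > 0
        if dispersion == 0:
            counts[positive] = rng.poisson(mu[positive])
        else:
            n = 1.0 / dispersion
            p = n / (n + mu[positive])
            counts[positive] = rng.negative_binomial(n, p)
        df[s] = counts

    expected_diploid = depth * lengths.sum() / read_length
    totals = {
        s: max(1, int(round(expected_diploid * sample_factors[s] / on_target_rate)))
        for s in samples
    }
    return ReadCountMatrix(exons=df, totals=totals)


# -------------------------------------------------------------------- scenes


@dataclass
class Scene:
    """A fully materialized synthetic trio dataset on disk."""

    directory: Path
    genome: ToyGenome
    truth: TrioTruth
    paths: dict[str, Path]


def make_default_scene(
    outdir: str | Path,
    seed: int = 7,
    n_genes: int = 22,
    deletion_genes: tuple[int, int] = (8, 15),
    target_gene: int = 13,
    depth: float = 100.0,
    dispersion: float = 0.05,
    n_background: int = 40,
    plant_deletion: bool = True,
    deletion_in_counts: bool = True,
) -> Scene:
    """Generate and write a complete scene: genome, VCF, annotations, counts,
    panel list, truth JSON and a ready-to-run pipeline config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    g_seed, p_seed, c_seed = (int(x) & 0x7FFFFFFF for x in ss.generate_state(3))

    genome = build_toy_genome(n_genes=n_genes, seed=g_seed)
    truth = plant_compound_het_scenario(
        genome, target_gene=target_gene, deletion_genes=deletion_genes,
        seed=p_seed, n_background=n_background,
        plant_deletion=plant_deletion, deletion_in_counts=deletion_in_counts,
    )
    counts = simulate_exon_counts(
        genome, truth.copy_states(genome), depth=depth, dispersion=dispersion,
        seed=c_seed,
    )

    paths = {name: outdir / fname for name, fname in [
        ("fasta", "genome.fa"), ("genes", "genes.tsv"), ("vcf", "trio.vcf"),
        ("annotation", "annotation.tsv"), ("counts", "counts.tsv"),
        ("panel", "panel.txt"), ("truth", "truth.json"), ("config", "config.json"),
    ]}
    genome.write_fasta(paths["fasta"])
    genome.write_gene_table(paths["genes"])
    emit_trio_vcf(truth, genome, paths["vcf"])
    emit_annotation_table(truth, genome, paths["annotation"])
    counts.to_tsv(paths["counts"])
    paths["panel"].write_text("".join(g.gene_id + "\n" for g in genome.genes if g.panel))
    truth.to_json(paths["truth"])

    config = {
        "inputs": {
            "vcf": "trio.vcf", "annotation": "annotation.tsv",
            "genome_fasta": "genome.fa", "gene_table": "genes.tsv",
            "counts": "counts.tsv", "panel": "panel.txt",
        },
        "samples": {"father": "father", "mother": "mother", "proband": "proband"},
        "cascade": {
            "maf_threshold": 0.05, "maf_population": "taiwanese",
            "damaging_quorum": 2, "conservation_threshold": 0.8,
        },
        "cnv": {"reference": "father", "loss_threshold": 0.7, "min_bins": 2},
        "evidence": {
            "pm2_max_maf": 0.005,
            "bs1_min_maf": 0.01,
            "functional_evidence": [f"{truth.chrom}:{truth.snv.pos}:{truth.snv.ref}:{truth.snv.alt}"],
            "declared_codes": {
                f"{truth.chrom}:{truth.benign.pos}:{truth.benign.ref}:{truth.benign.alt}":
                    ["PM1", "BS2", "BP6"],
            },
        },
        "seed": seed,
        "output_dir": "out",
    }
    paths["config"].write_text(json.dumps(config, indent=2) + "\n")
    return Scene(directory=outdir, genome=genome, truth=truth, paths=paths)
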