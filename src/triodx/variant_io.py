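"""Unified variant data model and trio VCF / annotation-table IO.

A trio callset arrives as a three-sample VCF plus a sidecar tab-delimited
annotation table (gene, transcript consequence, population minor-allele
frequencies, in-silico prediction scores, conservation), the shape a typical
exome annotation run produces. Both are joined here into
:class:`AnnotatedVariant` records, the common currency of every downstream
stage. Multi-allelic VCF sites are decomposed into one record per alt allele,
because all filters operate per allele.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

VariantKey = tuple[str, int, str, str]


class ConfigurationError(ValueError):
    """Bad sample map, population key, or missing input."""


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


class Genotype(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


#: consequence classes recognised by the prioritization cascade
CONSEQUENCE_CLASSES = (
    "missense",
    "nonsense",
    "frameshift",
    "inframe-indel",
    "canonical-splice",
    "splice-region",
    "synonymous",
    "intronic",
    "other",
)


@dataclass
class TrioGenotype:
    """Father/mother/proband genotype triple for one alt allele."""

    father: Genotype
    mother: Genotype
    proband: Genotype

    def as_tuple(self) -> tuple[Genotype, Genotype, Genotype]:
        return (self.father, self.mother, self.proband)

    def has_missing(self) -> bool:
        return Genotype.MISSING in self.as_tuple()


@dataclass
class AnnotatedVariant:
    """One called alt allele joined to its annotations and trio genotypes."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str = ""
    hgvs_c: str = ""
    consequence: str = "other"
    maf: dict[str, float] = field(default_factory=dict)
    scores: dict[str, float] = field(default_factory=dict)
    conservation: float | None = None
    genotypes: TrioGenotype | None = None
    # filled in as the variant moves through the pipeline
    tags: list[str] = field(default_factory=list)
    stage_reached: str = ""
    acmg_tier: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"position {self.pos} < 1")
        if self.ref == self.alt:
            raise FormatError(f"ref == alt at {self.chrom}:{self.pos}")
        for pop, f in self.maf.items():
            if not (0.0 <= f <= 1.0):
                raise FormatError(f"MAF {f} for {pop} outside [0, 1]")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def key_str(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def maf_for(self, population: str) -> float:
        """MAF used at filter time; an absent population record counts as 0.0.

        Absence of a frequency must not rescue a variant from scrutiny: a
        never-observed allele is treated as maximally rare.
        """
        value = self.maf.get(population)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return 0.0
        return value


def _classify_gt(allele_indices: tuple, alt_index: int) -> Genotype:
    if any(a is None for a in allele_indices) or len(allele_indices) == 0:
        return Genotype.MISSING
    n_alt = sum(1 for a in allele_indices if a == alt_index)
    if n_alt == 0:
        return Genotype.HOM_REF
    if n_alt == len(allele_indices):
        return Genotype.HOM_ALT
    return Genotype.HET


def read_annotated_trio(
    vcf_path: str | Path,
    annotation_path: str | Path,
    sample_map: dict[str, str],
) -> list[AnnotatedVariant]:
    """Join a trio VCF with its annotation table into AnnotatedVariant records.

    ``sample_map`` maps the roles {father, mother, proband} to VCF sample
    column names. One record is produced per alt allele. Annotation rows with
    no VCF mate are logged and dropped; duplicate annotation keys are an error.
    """
    vcf_path, annotation_path = Path(vcf_path), Path(annotation_path)
    for p in (vcf_path, annotation_path):
        if not p.exists():
            raise ConfigurationError(f"missing input file: {p}")
    for role in ("father", "mother", "proband"):
        if role not in sample_map:
            raise ConfigurationError(f"sample map lacks role {role!r}")

    ann = pd.read_csv(annotation_path, sep="\t", dtype={"chrom": str})
    ann_index: dict[VariantKey, dict] = {}
    for row in ann.to_dict("records"):
        key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        if key in ann_index:
            raise FormatError(f"duplicate annotation key {key}")
        ann_index[key] = row

    maf_cols = [c for c in ann.columns if c.startswith("maf_")]
    score_cols = [c for c in ann.columns if c.startswith("score_")]

    variants: list[AnnotatedVariant] = []
    seen: set[VariantKey] = set()
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for role in ("father", "mother", "proband"):
            if sample_map[role] not in list(vcf.header.samples):
                raise ConfigurationError(
                    f"sample column {sample_map[role]!r} (role {role}) not in VCF"
                )
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            for alt_ordinal, alt in enumerate(rec.alts or (), start=1):
                key = (rec.chrom, rec.pos, rec.ref, alt)
                if key in seen:
                    raise FormatError(f"duplicate VCF record {key}")
                seen.add(key)
                gts = {}
                for role in ("father", "mother", "proband"):
                    allele_indices = rec.samples[sample_map[role]].get("GT", ())
                    gts[role] = _classify_gt(tuple(allele_indices), alt_ordinal)
                row = ann_index.pop(key, None)
                if row is None:
                    logger.warning("VCF record %s has no annotation row", key)
                    row = {}
                maf = {
                    c[len("maf_"):]: float(row[c])
                    for c in maf_cols
                    if c in row and pd.notna(row[c])
                }
                scores = {
                    c[len("score_"):]: float(row[c])
                    for c in score_cols
                    if c in row and pd.notna(row[c])
                }
                cons = row.get("conservation")
                variants.append(
                    AnnotatedVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=str(row.get("gene", "")),
                        transcript=str(row.get("transcript", "")),
                        hgvs_c=str(row.get("hgvs_c", "")),
                        consequence=str(row.get("consequence", "other")),
                        maf=maf,
                        scores=scores,
                        conservation=float(cons) if pd.notna(cons) else None,
                        genotypes=TrioGenotype(gts["father"], gts["mother"], gts["proband"]),
                    )
                )
    for key in ann_index:
        logger.warning("annotation row %s has no VCF mate; dropped", key)
    return variants


_GT_TO_INDICES = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
    Genotype.MISSING: (None, None),
}


def write_candidates(
    variants: list[AnnotatedVariant],
    path: str | Path,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write candidate variants as a sorted three-sample VCF.

    INFO carries the cascade stage reached, inheritance tags and the ACMG tier.
    An empty candidate list yields a header-only VCF.
    """
    header = pysam.VariantHeader()
    if contigs is None:
        contigs = {}
        for v in variants:
            contigs[v.chrom] = max(contigs.get(v.chrom, 0), v.pos + len(v.ref))
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">')
    header.add_line('##INFO=<ID=STAGE,Number=1,Type=String,Description="Cascade stage reached">')
    header.add_line('##INFO=<ID=TAGS,Number=.,Type=String,Description="Inheritance tags">')
    header.add_line('##INFO=<ID=ACMG,Number=1,Type=String,Description="ACMG tier">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for sample in ("father", "mother", "proband"):
        header.add_sample(sample)
    try:
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
                rec = out.new_record(
                    contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                    alleles=(v.ref, v.alt),
                )
                if v.gene:
                    rec.info["GENE"] = v.gene
                if v.stage_reached:
                    rec.info["STAGE"] = v.stage_reached
                if v.tags:
                    rec.info["TAGS"] = tuple(t.replace(" ", "_") for t in v.tags)
                if v.acmg_tier:
                    rec.info["ACMG"] = v.acmg_tier.replace(" ", "_")
                if v.genotypes is not None:
                    for sample, gt in zip(
                        ("father", "mother", "proband"),
                        (v.genotypes.father, v.genotypes.mother, v.genotypes.proband),
                    ):
                        rec.samples[sample]["GT"] = _GT_TO_INDICES[gt]
                out.write(rec)
    except OSError as exc:
        raise FormatError(f"cannot write candidate VCF {path}: {exc}") from exc
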