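"""Mendelian consistency, hemizygosity hypotheses, compound-het resolution.

A diploid caller confronted with a heterozygous deletion reports the surviving
allele as homozygous. In a trio this surfaces as a Mendelian inconsistency:
the proband looks homozygous for an allele one parent does not carry. Rather
than discarding such sites, this module turns each one into an explicit
hemizygosity hypothesis — "the hom-ref parent may carry a deletion over this
gene" — and tests it against read-depth deletion calls. A hypothesis is
confirmed when a deletion call covers the gene and is carried by the suspect
parent and the proband but not by the SNV-carrier parent; confirmation yields
a compound-heterozygote call (SNV in trans with the deletion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .cnv import DeletionCall
from .genome import GeneModel
from .variant_io import AnnotatedVariant, Genotype, TrioGenotype

logger = logging.getLogger(__name__)

_ALLELES = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
}


def mendelian_consistent(trio: TrioGenotype) -> bool | None:
    """True iff the proband genotype can arise from one allele of each parent.

    Returns None ("unknown") when any genotype is missing.
    """
    if trio.has_missing():
        return None
    father, mother = _ALLELES[trio.father], _ALLELES[trio.mother]
    proband = sorted(_ALLELES[trio.proband])
    return any(
        sorted((f, m)) == proband for f in set(father) for m in set(mother)
    )


@dataclass
class HemizygosityHypothesis:
    """A proposed deletion explaining a pseudo-homozygous trio genotype."""

    variant_key: str
    gene: str
    suspect_parent: str  # the hom-ref parent, who may carry the deletion
    snv_carrier_parent: str  # the het parent contributing the observed allele
    required_region: tuple[int, int]
    status: str = "proposed"  # proposed | confirmed | refuted
    note: str = ""


def propose_hemizygosity(
    variant: AnnotatedVariant,
    trio: TrioGenotype,
    gene_model: GeneModel,
) -> HemizygosityHypothesis | None:
    """Emit a hypothesis for the pseudo-homozygous pattern, else None.

    Fires iff the proband is hom-alt with exactly one het parent and one
    hom-ref parent. The hom-ref parent is the suspect; the required deletion
    region is the variant's gene interval. De novo-looking patterns (both
    parents hom-ref) are logged, not pursued: the model here is recessive
    inheritance, not new mutation.
    """
    if trio.has_missing() or trio.proband != Genotype.HOM_ALT:
        return None
    parents = {"father": trio.father, "mother": trio.mother}
    het = [p for p, g in parents.items() if g == Genotype.HET]
    hom_ref = [p for p, g in parents.items() if g == Genotype.HOM_REF]
    if len(het) == 1 and len(hom_ref) == 1:
        return HemizygosityHypothesis(
            variant_key=variant.key_str,
            gene=variant.gene,
            suspect_parent=hom_ref[0],
            snv_carrier_parent=het[0],
            required_region=gene_model.interval,
        )
    if len(hom_ref) == 2:
        logger.info("de novo-like pattern at %s; not pursued under the recessive model",
                    variant.key_str)
    return None


@dataclass
class CompoundHetCall:
    """An SNV in trans with a deletion in one gene, one allele per parent."""

    gene: str
    snv_key: str
    snv_carrier: str
    deletion_carrier: str
    deletion: DeletionCall
    proband_zygosity: str = (
        "compound heterozygous: one SNV allele (paternal or maternal) in trans "
        "with one deleted allele from the other parent"
    )

    def __post_init__(self) -> None:
        if self.snv_carrier == self.deletion_carrier:
            raise ValueError("compound het requires different carrier parents")

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "snv": self.snv_key,
            "snv_carrier": self.snv_carrier,
            "deletion_carrier": self.deletion_carrier,
            "deletion": self.deletion.to_dict(),
            "proband_zygosity": self.proband_zygosity,
        }


def resolve_compound_het(
    hypothesis: HemizygosityHypothesis,
    deletion_calls: list[DeletionCall],
) -> CompoundHetCall | None:
    """Confirm or refute a hemizygosity hypothesis against deletion calls.

    Confirmation requires a call overlapping the gene interval whose carriers
    include the suspect parent and the proband but not the SNV-carrier parent
    (a deletion on the SNV side would mean biallelic loss, a different
    diagnosis). The hypothesis status is updated in place; a confirmed
    hypothesis also yields a CompoundHetCall.
    """
    lo, hi = hypothesis.required_region
    for call in deletion_calls:
        if call.end < lo or call.start > hi:
            continue
        carriers = set(call.carriers)
        if hypothesis.snv_carrier_parent in carriers:
            hypothesis.status = "refuted"
            hypothesis.note = (
                "overlapping deletion also carried by the SNV-carrier parent "
                "(would be biallelic loss)"
            )
            return None
        if {hypothesis.suspect_parent, "proband"} <= carriers:
            hypothesis.status = "confirmed"
            return CompoundHetCall(
                gene=hypothesis.gene,
                snv_key=hypothesis.variant_key,
                snv_carrier=hypothesis.snv_carrier_parent,
                deletion_carrier=hypothesis.suspect_parent,
                deletion=call,
            )
    hypothesis.status = "refuted"
    hypothesis.note = (
        "no supporting deletion call over the gene; alternatives such as "
        "uniparental disomy or a genotyping artifact are not excluded"
    )
    return None
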