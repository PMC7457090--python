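"""Staged variant-prioritization cascade with a per-stage count trace.

Five stages run in fixed order: disease-gene panel membership, protein/splice
consequence, population minor-allele frequency, autosomal-recessive
transmission, and in-silico prediction/conservation. Each stage only removes
variants, and the trace records (in, out) counts per stage — the numbers a
Sankey diagram of the run would show.

The transmission stage deliberately retains Mendelian-inconsistent
"pseudo-homozygous" genotypes (proband hom-alt, one parent het, other parent
hom-ref) with a hemizygosity tag instead of discarding them as errors: a
heterozygous deletion on the untransmitted-parent side produces exactly this
pattern, and dropping it would lose the diagnosis the pipeline exists to make.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .variant_io import (
    CONSEQUENCE_CLASSES,
    AnnotatedVariant,
    ConfigurationError,
    Genotype,
)

logger = logging.getLogger(__name__)

#: consequence classes kept at the consequence stage (amino-acid changing or
#: splice disrupting)
DAMAGING_CONSEQUENCES = frozenset(
    {"missense", "nonsense", "frameshift", "inframe-indel",
     "canonical-splice", "splice-region"}
)

#: loss-of-function / splice classes that bypass the missense-predictor quorum,
#: because positional evidence substitutes for protein-level predictions
PREDICTOR_BYPASS = frozenset(
    {"canonical-splice", "splice-region", "nonsense", "frameshift"}
)

#: per-tool rules deciding whether a score is a "damaging" call
DAMAGING_RULES = {
    "sift": lambda s: s < 0.05,
    "polyphen2": lambda s: s > 0.85,
    "provean": lambda s: s <= -2.5,
    "fathmm": lambda s: s <= -1.5,
    "mutationtaster": lambda s: s > 0.5,
    "dbscsnv_ada": lambda s: s > 0.6,
    "dbscsnv_rf": lambda s: s > 0.6,
}

TAG_HOM_AR = "hom-AR"
TAG_COMPHET = "comphet-candidate"
TAG_PSEUDO_HOM = "Mendelian-inconsistent: possible hemizygosity"
TAG_LOW_CONFIDENCE = "low-confidence"


@dataclass
class CascadeConfig:
    """Tunable thresholds of the cascade."""

    panel: frozenset[str] = frozenset()
    maf_threshold: float = 0.05
    maf_population: str = "taiwanese"
    damaging_quorum: int = 2
    conservation_threshold: float = 0.8
    donor_window: tuple[int, int] = (1, 6)
    acceptor_window: tuple[int, int] = (-8, -1)

    def __post_init__(self) -> None:
        if not (0 < self.maf_threshold <= 1):
            raise ConfigurationError("maf_threshold must lie in (0, 1]")
        if self.damaging_quorum < 1:
            raise ConfigurationError("damaging_quorum must be >= 1")


@dataclass
class StageRecord:
    stage: str
    n_in: int
    n_out: int


@dataclass
class FilterTrace:
    """Ordered per-stage (in, out) counts; the cascade's Sankey numbers."""

    stages: list[StageRecord] = field(default_factory=list)

    def add(self, record: StageRecord) -> None:
        if record.n_out > record.n_in:
            raise ValueError(f"stage {record.stage}: out > in")
        if self.stages and record.n_in != self.stages[-1].n_out:
            raise ValueError(
                f"stage {record.stage}: in-count {record.n_in} does not chain "
                f"to previous out-count {self.stages[-1].n_out}"
            )
        self.stages.append(record)

    def to_rows(self) -> list[tuple[str, int, int]]:
        return [(s.stage, s.n_in, s.n_out) for s in self.stages]

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("stage\tvariants_in\tvariants_out\n")
            for stage, n_in, n_out in self.to_rows():
                fh.write(f"{stage}\t{n_in}\t{n_out}\n")

    def to_sankey_json(self, path: str | Path) -> None:
        nodes = ["input"] + [s.stage for s in self.stages]
        links = [
            {"source": nodes[i], "target": s.stage, "value": s.n_out,
             "dropped": s.n_in - s.n_out}
            for i, s in enumerate(self.stages)
        ]
        Path(path).write_text(json.dumps({"nodes": nodes, "links": links}, indent=2) + "\n")


# ---------------------------------------------------------------- the stages


def filter_panel(
    variants: list[AnnotatedVariant], panel: frozenset[str] | set[str]
) -> tuple[list[AnnotatedVariant], StageRecord]:
    """Keep variants whose gene is on the clinically relevant panel."""
    if not panel:
        raise ConfigurationError("disease-gene panel is empty")
    kept = [v for v in variants if v.gene in panel]
    return kept, StageRecord("panel", len(variants), len(kept))


def filter_consequence(
    variants: list[AnnotatedVariant], config: CascadeConfig | None = None
) -> tuple[list[AnnotatedVariant], StageRecord]:
    """Keep variants that change the protein or disrupt splicing."""
    kept = []
    for v in variants:
        consequence = v.consequence
        if consequence not in CONSEQUENCE_CLASSES:
            logger.warning("unknown consequence %r at %s; classified as 'other'",
                           consequence, v.key_str)
            consequence = "other"
        if consequence in DAMAGING_CONSEQUENCES:
            kept.append(v)
    return kept, StageRecord("consequence", len(variants), len(kept))


def filter_maf(
    variants: list[AnnotatedVariant], threshold: float = 0.05,
    population: str = "taiwanese",
) -> tuple[list[AnnotatedVariant], StageRecord]:
    """Keep variants strictly rarer than ``threshold`` in ``population``.

    A variant with no frequency record for the population counts as 0.0
    (novel alleles must not escape scrutiny).
    """
    if not (0 < threshold <= 1):
        raise ConfigurationError("MAF threshold must lie in (0, 1]")
    known_pops = {p for v in variants for p in v.maf}
    if variants and known_pops and population not in known_pops:
        raise ConfigurationError(
            f"population {population!r} absent from all annotation records "
            f"(known: {sorted(known_pops)})"
        )
    kept = [v for v in variants if v.maf_for(population) < threshold]
    return kept, StageRecord("maf", len(variants), len(kept))


def _ar_tag(gt) -> str | None:
    """Transmission tag for one genotype triple under the recessive model.

    Returns hom-AR, pseudo-hom, comphet-candidate (pre-grouping) or None.
    """
    f, m, p = gt.father, gt.mother, gt.proband
    if p == Genotype.HOM_ALT and f == Genotype.HET and m == Genotype.HET:
        return TAG_HOM_AR
    if p == Genotype.HOM_ALT and {f, m} == {Genotype.HET, Genotype.HOM_REF}:
        return TAG_PSEUDO_HOM
    if p == Genotype.HET and {f, m} == {Genotype.HET, Genotype.HOM_REF}:
        return TAG_COMPHET
    return None


def filter_inheritance_ar(
    variants: list[AnnotatedVariant],
) -> tuple[list[AnnotatedVariant], StageRecord]:
    """Keep variants compatible with autosomal-recessive transmission.

    Three patterns survive: (a) hom-AR — proband hom-alt with both parents
    het; (b) comphet candidates — proband het with exactly one het parent,
    kept only when >= 2 such variants in the same gene descend from different
    parents; (c) pseudo-hom — proband hom-alt, one parent het, the other
    hom-ref, tagged for CNV follow-up rather than discarded as a Mendelian
    error. Genotype triples with missing calls are routed by the remaining
    data (missing treated as a wildcard) and flagged low-confidence.
    """
    tagged: list[tuple[AnnotatedVariant, str, str | None]] = []
    for v in variants:
        gt = v.genotypes
        if gt is None:
            continue
        if gt.has_missing():
            tag, origin = _wildcard_tag(gt)
            if tag is not None:
                tagged.append((v, tag, origin))
                v.tags.append(TAG_LOW_CONFIDENCE)
            continue
        tag = _ar_tag(gt)
        if tag is not None:
            origin = None
            if tag == TAG_COMPHET:
                origin = "father" if gt.father == Genotype.HET else "mother"
            tagged.append((v, tag, origin))

    # group compound-het candidates per gene; require both parental origins
    by_gene: dict[str, set[str]] = defaultdict(set)
    for v, tag, origin in tagged:
        if tag == TAG_COMPHET and origin is not None:
            by_gene[v.gene].add(origin)
    kept = []
    for v, tag, origin in tagged:
        if tag == TAG_COMPHET and by_gene[v.gene] != {"father", "mother"}:
            continue
        v.tags.append(tag)
        kept.append(v)
    return kept, StageRecord("inheritance", len(variants), len(kept))


def _wildcard_tag(gt) -> tuple[str | None, str | None]:
    """Best-supported AR tag when genotypes are missing (wildcard expansion)."""
    from itertools import product

    states = [
        [g] if g != Genotype.MISSING else
        [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT]
        for g in gt.as_tuple()
    ]
    for prefer in (TAG_HOM_AR, TAG_PSEUDO_HOM, TAG_COMPHET):
        for f, m, p in product(*states):
            probe = type(gt)(f, m, p)
            if _ar_tag(probe) == prefer:
                origin = None
                if prefer == TAG_COMPHET:
                    origin = "father" if f == Genotype.HET else "mother"
                return prefer, origin
    return None, None


def damaging_call_count(v: AnnotatedVariant) -> int:
    """Number of available prediction tools calling the variant damaging."""
    return sum(
        1 for tool, score in v.scores.items()
        if tool in DAMAGING_RULES and DAMAGING_RULES[tool](score)
    )


def prioritize(
    variants: list[AnnotatedVariant], config: CascadeConfig
) -> tuple[list[AnnotatedVariant], StageRecord]:
    """Final evidence stage: predictor quorum with a splice/LoF bypass.

    Keeps variants with >= quorum damaging calls among available tools, or
    with a positional (splice/LoF) consequence class. Survivors are ranked by
    conservation (descending), then damaging-call count, then position.
    """
    kept = [
        v for v in variants
        if v.consequence in PREDICTOR_BYPASS
        or damaging_call_count(v) >= config.damaging_quorum
    ]
    kept.sort(
        key=lambda v: (
            -(v.conservation if v.conservation is not None else -1.0),
            -damaging_call_count(v),
            v.key,
        )
    )
    return kept, StageRecord("prioritize", len(variants), len(kept))


def run_cascade(
    variants: list[AnnotatedVariant], config: CascadeConfig
) -> tuple[list[AnnotatedVariant], FilterTrace]:
    """Run all five stages in fixed order and record the trace."""
    trace = FilterTrace()
    current = list(variants)

    stages = [
        ("panel", lambda vs: filter_panel(vs, config.panel)),
        ("consequence", lambda vs: filter_consequence(vs, config)),
        ("maf", lambda vs: filter_maf(vs, config.maf_threshold, config.maf_population)),
        ("inheritance", filter_inheritance_ar),
        ("prioritize", lambda vs: prioritize(vs, config)),
    ]
    for name, stage in stages:
        current, record = stage(current)
        trace.add(record)
        for v in current:
            v.stage_reached = name
    return current, trace
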