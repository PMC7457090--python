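"""End-to-end trio diagnostic run and structured report.

Order of operations, fixed: read inputs -> prioritization cascade ->
hemizygosity hypotheses from pseudo-homozygous candidates -> read-ratio CNV
calls -> compound-het resolution -> splice-consequence modelling -> ACMG
evidence assignment and classification -> report. The report is written as
JSON (byte-stable for a fixed seed and config: no timestamps) and as a short
human-readable text, alongside a candidate VCF, the CNV call table and the
cascade trace.

Evidence assignment is rule-driven and logged: rarity below a bound gives
PM2, a confirmed in-trans deletion gives PM3, a splice consequence with a PTC
gives PM4, frequency above a bound gives BS1. PS3 (functional evidence) and
any other code are never inferred — they enter only as user-declared flags in
the config, because they encode wet-lab results outside this pipeline's reach.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import acmg, cascade, cnv, splice, trio, variant_io
from .genome import ToyGenome
from .variant_io import AnnotatedVariant, ConfigurationError, Genotype

logger = logging.getLogger(__name__)

SPLICE_CLASSES = {"canonical-splice", "splice-region"}


@dataclass
class PipelineReport:
    """Everything one run produced, with referential integrity.

    Every confirmed compound het references a deletion call by index; every
    candidate carries the cascade stage it reached.
    """

    metadata: dict
    trace: cascade.FilterTrace
    candidates: list[dict]
    deletion_calls: list[cnv.DeletionCall]
    hypotheses: list[trio.HemizygosityHypothesis]
    compound_hets: list[dict]

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "trace": [
                {"stage": s, "in": n_in, "out": n_out}
                for s, n_in, n_out in self.trace.to_rows()
            ],
            "candidates": self.candidates,
            "deletion_calls": [c.to_dict() for c in self.deletion_calls],
            "hypotheses": [
                {
                    "variant": h.variant_key, "gene": h.gene,
                    "suspect_parent": h.suspect_parent,
                    "snv_carrier_parent": h.snv_carrier_parent,
                    "required_region": list(h.required_region),
                    "status": h.status, "note": h.note,
                }
                for h in self.hypotheses
            ],
            "compound_hets": self.compound_hets,
        }

    def to_text(self) -> str:
        lines = ["== trio diagnostic report =="]
        lines.append("cascade trace:")
        for s, n_in, n_out in self.trace.to_rows():
            lines.append(f"  {s:<12} {n_in:>5} -> {n_out}")
        lines.append(f"deletion calls: {len(self.deletion_calls)}")
        for c in self.deletion_calls:
            bp, mb = cnv.deletion_span(c)
            lines.append(
                f"  {c.chrom}:{c.start}-{c.end} ({mb} Mb, copy {c.copy_state}, "
                f"carriers {','.join(c.carriers)}, {len(c.overlapped_genes)} genes)"
            )
        lines.append(f"confirmed compound heterozygotes: {len(self.compound_hets)}")
        for ch in self.compound_hets:
            lines.append(
                f"  {ch['gene']}: SNV {ch['snv']} ({ch['snv_carrier']}) in trans "
                f"with deletion ({ch['deletion_carrier']})"
            )
        lines.append("candidates:")
        for c in self.candidates:
            lines.append(
                f"  {c['key']} {c['gene']} {c['consequence']} "
                f"tags={','.join(c['tags']) or '-'} ACMG={c['acmg']['tier']} "
                f"[{','.join(sorted(c['evidence']))}]"
            )
        return "\n".join(lines) + "\n"


def load_config(config_path: str | Path) -> tuple[dict, Path]:
    config_path = Path(config_path)
    if not config_path.exists():
        raise ConfigurationError(f"missing config file: {config_path}")
    if config_path.suffix == ".toml":
        import tomllib

        config = tomllib.loads(config_path.read_text())
    else:
        config = json.loads(config_path.read_text())
    return config, config_path.parent


def assign_evidence(
    variant: AnnotatedVariant,
    rules: dict,
    population: str,
    comphet_confirmed: bool,
    splice_cons: splice.SpliceConsequence | None,
) -> tuple[acmg.AcmgEvidenceSet, list[str]]:
    """Deterministic, logged mapping from observations to ACMG codes."""
    codes: list[str] = []
    log: list[str] = []
    maf = variant.maf_for(population)
    if maf < rules.get("pm2_max_maf", 0.005):
        codes.append("PM2")
        log.append(f"PM2: MAF {maf} below very-rare bound {rules.get('pm2_max_maf', 0.005)}")
    if comphet_confirmed:
        codes.append("PM3")
        log.append("PM3: in trans with a deleterious allele (confirmed compound het)")
    if splice_cons is not None and splice_cons.ptc_present:
        codes.append("PM4")
        log.append(
            f"PM4: retained intron creates a PTC after {splice_cons.additional_aa} "
            "additional amino acids (gene-product length change)"
        )
    if maf > rules.get("bs1_min_maf", 0.01):
        codes.append("BS1")
        log.append(f"BS1: MAF {maf} above expected-for-disorder bound {rules.get('bs1_min_maf', 0.01)}")
    if variant.key_str in rules.get("functional_evidence", []):
        codes.append("PS3")
        log.append("PS3: user-declared functional evidence flag")
    for code in rules.get("declared_codes", {}).get(variant.key_str, []):
        if code not in codes:
            codes.append(code)
            log.append(f"{code}: user-declared")
    return acmg.AcmgEvidenceSet.parse(codes), log


def run_pipeline(config: str | Path | dict, base_dir: str | Path | None = None) -> PipelineReport:
    """Run the full analysis described by ``config`` and write all outputs.

    ``config`` may be a path to a JSON/TOML file or an equivalent dict (then
    ``base_dir`` anchors relative paths). Outputs land under
    ``config["output_dir"]``. Fail-fast: configuration errors raise before any
    output is written; partial reports are never produced.
    """
    if isinstance(config, (str, Path)):
        config, base_dir = load_config(config)
    if base_dir is None:
        base_dir = Path.cwd()
    base_dir = Path(base_dir)

    inputs = config.get("inputs", {})
    paths = {}
    for name in ("vcf", "annotation", "genome_fasta", "gene_table", "counts", "panel"):
        if name not in inputs:
            raise ConfigurationError(f"config lacks inputs.{name}")
        p = base_dir / inputs[name]
        if not p.exists():
            raise ConfigurationError(f"missing input file for inputs.{name}: {p}")
        paths[name] = p

    samples = config.get("samples", {"father": "father", "mother": "mother", "proband": "proband"})
    cas_cfg = config.get("cascade", {})
    cnv_cfg = config.get("cnv", {})
    rules = config.get("evidence", {})

    genome = ToyGenome.read(paths["genome_fasta"], paths["gene_table"])
    panel = frozenset(
        line.strip() for line in paths["panel"].read_text().splitlines() if line.strip()
    )
    variants = variant_io.read_annotated_trio(paths["vcf"], paths["annotation"], samples)

    config_obj = cascade.CascadeConfig(
        panel=panel,
        maf_threshold=cas_cfg.get("maf_threshold", 0.05),
        maf_population=cas_cfg.get("maf_population", "taiwanese"),
        damaging_quorum=cas_cfg.get("damaging_quorum", 2),
        conservation_threshold=cas_cfg.get("conservation_threshold", 0.8),
    )
    candidates, trace = cascade.run_cascade(variants, config_obj)

    # --- read-ratio CNV calls
    counts = cnv.ReadCountMatrix.from_tsv(paths["counts"])
    normalized = cnv.normalize_exon_counts(counts)
    gene_values = cnv.gene_level(normalized, genome.genes)
    reference = cnv_cfg.get("reference", "father")
    if reference == "median":
        gene_values = cnv.median_reference(gene_values, counts.samples)
    elif reference not in counts.samples:
        raise ConfigurationError(f"CNV reference sample {reference!r} not in count matrix")
    tracks = {
        s: cnv.ratio_track(gene_values, s, reference)
        for s in counts.samples
        if s != reference
    }
    calls = cnv.call_deletions(
        tracks, chrom=genome.chrom, genes=genome.genes,
        loss_threshold=cnv_cfg.get("loss_threshold", 0.7),
        min_bins=cnv_cfg.get("min_bins", 2),
    )

    # --- hemizygosity hypotheses and compound-het resolution
    hypotheses: list[trio.HemizygosityHypothesis] = []
    comphets: list[dict] = []
    comphet_genes: set[str] = set()
    for v in candidates:
        if cascade.TAG_PSEUDO_HOM not in v.tags or v.genotypes is None:
            continue
        hyp = trio.propose_hemizygosity(v, v.genotypes, genome.gene(v.gene))
        if hyp is None:
            continue
        hypotheses.append(hyp)
        call = trio.resolve_compound_het(hyp, calls)
        if call is not None:
            entry = call.to_dict()
            entry["deletion_index"] = next(
                i for i, c in enumerate(calls) if c is call.deletion
            )
            comphets.append(entry)
            comphet_genes.add(call.gene)

    # --- splice consequences for splice-class candidates
    splice_results: dict[str, splice.SpliceConsequence] = {}
    for v in candidates:
        if v.consequence not in SPLICE_CLASSES:
            continue
        gene = genome.gene(v.gene)
        klass, ordinal, offset = splice.classify_splice_position(v.pos, gene)
        if klass == "none" or ordinal is None:
            logger.warning("%s annotated %s but not in a splice window", v.key_str, v.consequence)
            continue
        model = splice.TranscriptModel.from_gene(genome, gene)
        sc = splice.splice_consequence(model, ordinal)
        splice_results[v.key_str] = sc

    # --- ACMG classification
    population = config_obj.maf_population
    candidate_rows = []
    for v in candidates:
        evidence, ev_log = assign_evidence(
            v, rules, population,
            comphet_confirmed=v.gene in comphet_genes and cascade.TAG_PSEUDO_HOM in v.tags,
            splice_cons=splice_results.get(v.key_str),
        )
        result = acmg.classify(evidence)
        v.acmg_tier = result.tier
        sc = splice_results.get(v.key_str)
        candidate_rows.append({
            "key": v.key_str,
            "gene": v.gene,
            "transcript": v.transcript,
            "hgvs_c": v.hgvs_c,
            "consequence": v.consequence,
            "maf": {population: v.maf_for(population)},
            "conservation": v.conservation,
            "genotypes": {
                "father": v.genotypes.father.value,
                "mother": v.genotypes.mother.value,
                "proband": v.genotypes.proband.value,
            } if v.genotypes else None,
            "tags": list(v.tags),
            "stage_reached": v.stage_reached,
            "evidence": sorted(evidence.codes),
            "evidence_log": ev_log,
            "acmg": {
                "tier": result.tier,
                "fired_rules": result.fired_rules,
                "conflict": result.conflict,
            },
            "rationale": acmg.explain(evidence),
            "splice_consequence": sc.to_dict() if sc else None,
        })

    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]
    report = PipelineReport(
        metadata={
            "seed": config.get("seed"),
            "config_hash": config_hash,
            "reference_sample": reference,
            "n_input_variants": len(variants),
        },
        trace=trace,
        candidates=candidate_rows,
        deletion_calls=calls,
        hypotheses=hypotheses,
        compound_hets=comphets,
    )

    outdir = base_dir / config.get("output_dir", "out")
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    (outdir / "report.txt").write_text(report.to_text())
    variant_io.write_candidates(
        candidates, outdir / "candidates.vcf",
        contigs={genome.chrom: len(genome.sequence)},
    )
    cnv.calls_to_tsv(calls, outdir / "cnv_calls.tsv")
    cnv.calls_to_json(calls, outdir / "cnv_calls.json")
    trace.to_tsv(outdir / "trace.tsv")
    trace.to_sankey_json(outdir / "trace_sankey.json")
    return report
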