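"""Exome read-count copy-number detection by sample-to-reference ratios.

The computation mirrors how a heterozygous multi-gene deletion shows up in a
family exome study without any dedicated CNV caller: raw per-exon read counts
are normalized per sample to its total mapped reads (counts per million), the
normalized counts are summed per gene, each sample's per-gene value is divided
by a reference sample's (by default the father, the parent without the event),
and maximal runs of consecutive low-ratio genes become deletion segments. A
heterozygous deletion carrier sits near ratio 0.5, a homozygous loss near 0.

Bins are genes by default (exon-level tracks are available for finer
breakpoints). Coordinates are 1-based inclusive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneModel


class CountMatrixError(ValueError):
    """Inconsistent count matrix, totals, or bin sets."""


@dataclass
class ReadCountMatrix:
    """Per-exon raw counts per sample plus per-sample total mapped reads.

    ``exons`` has columns gene_id, exon (1-based ordinal), start, end and one
    integer column per sample. Totals include off-target reads, so they exceed
    the column sums.
    """

    exons: pd.DataFrame
    totals: dict[str, int]

    @property
    def samples(self) -> list[str]:
        fixed = {"gene_id", "exon", "start", "end"}
        return [c for c in self.exons.columns if c not in fixed]

    def validate(self) -> None:
        for s in self.samples:
            if s not in self.totals:
                raise CountMatrixError(f"no total mapped reads for sample {s!r}")
            if self.totals[s] <= 0:
                raise CountMatrixError(f"total mapped reads for {s!r} must be > 0")
            if (self.exons[s] < 0).any():
                raise CountMatrixError(f"negative counts for sample {s!r}")

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("#totals\t" + "\t".join(f"{s}:{self.totals[s]}" for s in self.samples) + "\n")
            self.exons.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReadCountMatrix":
        path = Path(path)
        with path.open() as fh:
            first = fh.readline().rstrip("\n")
            if not first.startswith("#totals\t"):
                raise CountMatrixError(f"{path}: missing #totals header line")
            totals = {}
            for item in first.split("\t")[1:]:
                name, value = item.rsplit(":", 1)
                totals[name] = int(value)
            exons = pd.read_csv(fh, sep="\t")
        return cls(exons=exons, totals=totals)


def normalize_exon_counts(matrix: ReadCountMatrix) -> pd.DataFrame:
    """Per-exon counts per million total mapped reads (per-sample scaling only)."""
    matrix.validate()
    out = matrix.exons[["gene_id", "exon", "start", "end"]].copy()
    for s in matrix.samples:
        out[s] = matrix.exons[s] / matrix.totals[s] * 1e6
    return out


def gene_level(normalized: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    """Sum normalized exon values within each gene; one row per gene, in genomic order."""
    known = {g.gene_id for g in genes}
    orphans = set(normalized["gene_id"]) - known
    if orphans:
        raise CountMatrixError(f"exons reference unknown genes: {sorted(orphans)}")
    fixed = {"gene_id", "exon", "start", "end"}
    samples = [c for c in normalized.columns if c not in fixed]
    summed = normalized.groupby("gene_id", sort=False)[samples].sum()
    rows = []
    for g in genes:
        if g.gene_id not in summed.index:
            continue
        row = {"gene_id": g.gene_id, "start": g.start, "end": g.end}
        row.update(summed.loc[g.gene_id].to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def median_reference(
    gene_values: pd.DataFrame, samples: list[str] | None = None,
    name: str = "median",
) -> pd.DataFrame:
    """Add a per-bin median-across-samples column to use as the reference.

    A robustness alternative to a designated reference sample; note that it
    misleads when the majority of samples carry the same event.
    """
    fixed = {"gene_id", "exon", "start", "end"}
    if samples is None:
        samples = [c for c in gene_values.columns if c not in fixed]
    out = gene_values.copy()
    out[name] = gene_values[samples].median(axis=1)
    return out


def ratio_track(
    gene_values: pd.DataFrame, sample: str, reference: str
) -> pd.DataFrame:
    """Per-bin sample/reference ratio and log2 ratio.

    Bins where the reference value is 0 are flagged ``uninformative`` (ratio
    and log2 set to NaN) rather than divided or dropped.
    """
    for col in (sample, reference):
        if col not in gene_values.columns:
            raise CountMatrixError(f"no column {col!r} in gene-level values")
    track = gene_values[["gene_id", "start", "end"]].copy()
    track["value"] = gene_values[sample]
    track["reference"] = gene_values[reference]
    informative = track["reference"] > 0
    track["uninformative"] = ~informative
    ratio = np.full(len(track), np.nan)
    ratio[informative.to_numpy()] = (
        track.loc[informative, "value"] / track.loc[informative, "reference"]
    )
    track["ratio"] = ratio
    with np.errstate(divide="ignore"):
        track["log2_ratio"] = np.where(ratio > 0, np.log2(np.where(ratio > 0, ratio, 1.0)), -np.inf)
    track.loc[~informative, "log2_ratio"] = np.nan
    return track


@dataclass
class Segment:
    start: int
    end: int
    first_bin: int
    last_bin: int
    mean_ratio: float


def segment_ratios(
    track: pd.DataFrame, loss_threshold: float = 0.7, min_bins: int = 2
) -> list[Segment]:
    """Maximal runs of >= ``min_bins`` consecutive bins with ratio below threshold.

    Uninformative bins break runs. Segment boundaries are the outermost bin
    interval edges.
    """
    if not (0 < loss_threshold < 1):
        raise ValueError("loss_threshold must lie in (0, 1)")
    if min_bins < 1:
        raise ValueError("min_bins must be >= 1")
    segments: list[Segment] = []
    run: list[int] = []

    def close_run() -> None:
        if len(run) >= min_bins:
            sub = track.iloc[run]
            segments.append(
                Segment(
                    start=int(sub["start"].iloc[0]),
                    end=int(sub["end"].iloc[-1]),
                    first_bin=run[0],
                    last_bin=run[-1],
                    mean_ratio=float(sub["ratio"].mean()),
                )
            )
        run.clear()

    for i in range(len(track)):
        r = track["ratio"].iloc[i]
        if not track["uninformative"].iloc[i] and not math.isnan(r) and r < loss_threshold:
            run.append(i)
        else:
            close_run()
    close_run()
    return segments


@dataclass
class DeletionCall:
    """A contiguous copy-loss interval shared across one or more samples."""

    chrom: str
    start: int
    end: int
    mean_ratio: float
    copy_state: int  # 1 = heterozygous loss, 0 = homozygous loss
    carriers: list[str]
    overlapped_genes: list[str] = field(default_factory=list)
    per_carrier_ratio: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "length_bp": deletion_span(self)[0],
            "length_mb": deletion_span(self)[1],
            "mean_ratio": round(self.mean_ratio, 4),
            "copy_state": self.copy_state,
            "carriers": self.carriers,
            "overlapped_genes": self.overlapped_genes,
            "per_carrier_ratio": {k: round(v, 4) for k, v in self.per_carrier_ratio.items()},
        }


#: ratio below which a loss is called homozygous (copy 0) rather than heterozygous
HOMOZYGOUS_RATIO_BOUND = 0.25


def call_deletions(
    tracks: dict[str, pd.DataFrame],
    chrom: str,
    genes: list[GeneModel] | None = None,
    loss_threshold: float = 0.7,
    min_bins: int = 2,
) -> list[DeletionCall]:
    """Merge per-sample loss segments into deletion calls with carrier sets.

    ``tracks`` maps sample name -> ratio track against the common reference.
    Overlapping loss segments across samples become one call; carriers are the
    samples whose mean ratio over the merged interval stays below the
    threshold. Copy state is 1 (heterozygous) for mean carrier ratio >=
    ``HOMOZYGOUS_RATIO_BOUND``, else 0.
    """
    bin_sets = {tuple(map(tuple, t[["start", "end"]].to_numpy())) for t in tracks.values()}
    if len(bin_sets) > 1:
        raise CountMatrixError("ratio tracks do not share a bin set")
    bins = sorted(bin_sets.pop())

    intervals: list[tuple[int, int]] = []
    for t in tracks.values():
        for seg in segment_ratios(t, loss_threshold, min_bins):
            intervals.append((seg.start, seg.end))
    if not intervals:
        return []

    def gap_has_bin(left_end: int, right_start: int) -> bool:
        return any(left_end < bs and be < right_start for bs, be in bins)

    # merge overlapping intervals, and adjacent ones whose gap holds no bin:
    # with no bin between two loss runs there is no evidence of normal copy
    # separating them, so they are one event at this resolution
    intervals.sort()
    merged: list[list[int]] = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1] or not gap_has_bin(merged[-1][1], s):
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    calls = []
    for s, e in merged:
        carriers, ratios = [], {}
        for sample, t in tracks.items():
            inside = (t["start"] >= s) & (t["end"] <= e) & (~t["uninformative"])
            if not inside.any():
                continue
            mean_ratio = float(t.loc[inside, "ratio"].mean())
            if mean_ratio < loss_threshold:
                carriers.append(sample)
                ratios[sample] = mean_ratio
        if not carriers:
            continue
        call_mean = float(np.mean([ratios[c] for c in carriers]))
        call = DeletionCall(
            chrom=chrom,
            start=s,
            end=e,
            mean_ratio=call_mean,
            copy_state=1 if call_mean >= HOMOZYGOUS_RATIO_BOUND else 0,
            carriers=sorted(carriers),
            per_carrier_ratio=ratios,
        )
        if genes is not None:
            call.overlapped_genes = overlap_genes(call, genes)[0]
        calls.append(call)
    return calls


def deletion_span(call: "DeletionCall | tuple[int, int]") -> tuple[int, float]:
    """(length in bp, length in Mb rounded to 2 decimals), 1-based inclusive.

    Accepts a DeletionCall or a bare (start, end) pair so printed breakpoints
    can be checked directly.
    """
    if isinstance(call, tuple):
        start, end = call
    else:
        start, end = call.start, call.end
    if start > end:
        raise ValueError(f"interval start {start} > end {end}")
    length = end - start + 1
    return length, round(length / 1e6, 2)


def overlap_genes(
    call: "DeletionCall | tuple[int, int]", genes: list[GeneModel]
) -> tuple[list[str], int]:
    """Genes with at least one base inside the call interval, and their count."""
    if isinstance(call, tuple):
        start, end = call
    else:
        start, end = call.start, call.end
    hit = [g.gene_id for g in genes if g.start <= end and g.end >= start]
    return hit, len(hit)


def calls_to_tsv(calls: list[DeletionCall], path: str | Path) -> None:
    """BED-like TSV of deletion calls; coordinates are 1-based inclusive."""
    cols = ["chrom", "start", "end", "length_bp", "length_mb", "mean_ratio",
            "copy_state", "carriers", "overlapped_genes"]
    with Path(path).open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in calls:
            d = c.to_dict()
            fh.write(
                "\t".join(
                    str(d[k]) if k not in ("carriers", "overlapped_genes")
                    else ",".join(d[k])
                    for k in cols
                ) + "\n"
            )


def calls_to_json(calls: list[DeletionCall], path: str | Path) -> None:
    Path(path).write_text(json.dumps([c.to_dict() for c in calls], indent=2) + "\n")
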