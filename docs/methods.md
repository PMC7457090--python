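# Methods

## Problem setting and scope

The package models the computational core of a trio whole-exome diagnosis for
an autosomal-recessive disorder in which the proband's two deleterious
alleles are of different kinds: a single-nucleotide splice variant on one
parental chromosome and a large heterozygous deletion on the other. The
pipeline starts from *called, annotated* variants and per-exon read counts;
read trimming, alignment, variant calling and the external in-silico
predictors (SIFT, PolyPhen-2, PROVEAN, FATHMM, MutationTaster, dbscSNV,
phastCons-style conservation) are upstream tools whose outputs are consumed
as annotation columns, never recomputed.

## Prioritization cascade

Stages run in fixed order; each only removes variants.

| stage | rule | default |
|---|---|---|
| panel | gene ∈ user-supplied disease-gene list | — |
| consequence | keep {missense, nonsense, frameshift, inframe-indel, canonical-splice, splice-region} | — |
| MAF | population frequency strictly < threshold; absent record = 0.0 | 0.05, population `taiwanese` |
| inheritance | autosomal-recessive patterns (below) | — |
| prioritize | ≥ k damaging predictor calls, OR splice/LoF consequence (positional bypass); rank by conservation desc, then damaging count | k = 2, conservation reference 0.8 |

The panel is a plain gene-list file rather than a live database query: no
network dependency, and the user pins the panel version. An absent frequency
record is deliberately treated as 0.0 at filter time (while stored as
absent): novel alleles are the most interesting ones and must not be rescued
from scrutiny by missing data. Unknown consequence strings are logged and
classed `other` (dropped). The three set-membership stages (panel,
consequence, MAF) commute; the inheritance and prioritize stages are also
pure filters, so trace counts are non-increasing and chain exactly.

Damaging-call rules per tool: SIFT < 0.05, PolyPhen-2 > 0.85, PROVEAN ≤
−2.5, FATHMM ≤ −1.5, MutationTaster > 0.5, dbscSNV (ADA/RF) > 0.6. The
quorum k = 2 and the 0.8 conservation reference are package defaults chosen
so that a variant supported by two independent predictors, or by strong
positional evidence plus high conservation, survives; both study-variant
analogs (phastCons 0.911 and 0.841) clear the conservation reference.

### Recessive-transmission patterns

With genotypes in {hom-ref, het, hom-alt} for father, mother, proband, three
patterns survive:

- **hom-AR** — proband hom-alt, both parents het (the classic recessive
  homozygote);
- **comphet-candidate** — proband het, exactly one het parent; kept only if
  the same gene carries ≥ 2 such variants of *different* parental origin;
- **pseudo-hom** — proband hom-alt, one het parent, one hom-ref parent. This
  violates diploid Mendelian transmission and is exactly what a diploid
  caller reports when the proband is hemizygous opposite a deleted allele.
  The variant is tagged `Mendelian-inconsistent: possible hemizygosity` and
  retained for CNV follow-up. Discarding such sites as genotyping errors is
  the failure mode this pipeline exists to avoid.

Triples with missing calls are routed by wildcard expansion over the missing
member and flagged `low-confidence`. De novo-looking patterns (both parents
hom-ref) are logged and not pursued — the scope is the recessive model.

## Hemizygosity hypotheses and compound-het resolution

Each pseudo-hom candidate yields a hypothesis: suspect parent = the hom-ref
parent, required region = the gene interval. Confirmation requires a
deletion call that (i) overlaps the gene by ≥ 1 bp (a partial-gene deletion
still disrupts the allele), (ii) is carried by the suspect parent and the
proband, and (iii) is *not* carried by the SNV-carrier parent (that would be
biallelic loss, a different diagnosis). A refuted hypothesis is reported
with the note that alternatives (uniparental disomy, genotyping artifact)
are not excluded.

## Read-ratio CNV detection

Per-exon counts c are normalized per sample to counts per million of total
mapped reads N (per-sample scaling only; totals include off-target reads),
summed within each gene, and divided by the same quantity in a reference
sample — by default the parent expected to be copy-normal over the region,
mirroring the family design (the caller is symmetric in the reference
choice). Heterozygous loss sits at ratio ≈ 0.5, homozygous loss ≈ 0.

Segmentation is run-length thresholding: maximal runs of ≥ `min_bins` = 2
consecutive bins with ratio < 0.7 (bins are genes by default; exon-level
tracks are available). Reference bins with value 0 are flagged
uninformative, never divided, and break runs. Per-sample segments are merged
into one call when they overlap, or when no bin lies strictly between them
(with no evidence of normal copy in the gap there is no basis for calling
two events at this resolution). Carriers are the samples whose mean ratio
over the merged interval stays below threshold; the call is copy 1 when the
carrier-mean ratio ≥ 0.25 and copy 0 below. The 0.7 threshold sits roughly
midway between the copy-1 and copy-2 ratio distributions at the default
simulation noise; a full changepoint method (e.g. circular binary
segmentation) is intentionally out of scope for a 2× event at gene
resolution.

Span arithmetic is 1-based inclusive (length = end − start + 1), matching
VCF/HGVS deletion conventions; calls report bin-edge precision only —
sub-bin breakpoints cannot come from exon-bin data.

## ACMG evidence combination

The 2015 categorical combining rules are implemented verbatim over category
counts (PVS, PS, PM, PP / BA, BS, BP), with rule-by-rule explanations.
Conflict policy: Uncertain-significance-with-conflict only when combining
rules fire on *both* sides; stray opposing codes that satisfy no rule on
their own side do not force a conflict (two BS codes plus a lone PM still
classify Benign — the only policy consistent with standard practice for
such sets). Codes are inputs: the engine never audits whether, say, PM4 was
appropriate for a given variant. Optional per-code strength overrides allow
down/up-weighting. The Bayesian point-based reformulation is out of scope.

Within the pipeline, code assignment is rule-driven and logged: MAF below
0.005 → PM2; confirmed compound het → PM3; splice consequence with a PTC
(gene-product length change) → PM4; MAF above 0.01 → BS1. PS3 and any other
code (PM1, BS2, BP6, …) enter only as user-declared config flags, because
they encode wet-lab or database evidence outside the pipeline's reach.

## Splice-acceptor consequence model

Acceptor offsets are numbered negatively from the intron's 3′ end (−1 is the
last intron base); −1..−2 are canonical, −3..−8 splice region; donors +1..+2
canonical, +3..+6 region. Disruption is modelled as **full retention of the
affected intron** — not exon skipping or cryptic-site use — which is the
appropriate consequence model when an upstream splice-prediction tool has
already reported the acceptor as broken. Negative-strand genes are
reverse-complemented once at transcript-model construction; all downstream
logic is strand-free.

The retained-intron transcript is translated from the CDS start; the PTC is
the first in-frame stop ending after the disrupted junction; the
additional-amino-acid count is the number of complete codons strictly
between the junction and the stop (a stop starting at the junction gives 0;
a codon straddling the junction counts for neither side). A transcript with
no stop is flagged read-through; a PTC past the retained intron is flagged.
NMD is predicted by the operational 50-nt rule — PTC ≥ 50 nt upstream of the
last remaining exon–exon junction — with the distance configurable; real NMD
efficiency is tissue-dependent and outside scope.

## Synthetic scenes: what they emulate, and what they do not

The default scene is a 22-gene region with the deletion spanning genes 8–15
and the splice SNV in gene 13 (the geometry of the motivating family's
locus at toy scale: ~30 kb instead of ~5 Mb, 8 deleted genes instead of 14).
Per scene: one paternal acceptor −3 SNV (MAF 0.001), one maternal deletion
transmitted to the proband, one benign recessive missense homozygote (MAF
0.034, SIFT/FATHMM-deleterious, PolyPhen/PROVEAN-tolerated), and 40
background variants cycling through six categories, each engineered to be
removed at a specific cascade stage (non-panel gene; synonymous; common
allele; non-recessive transmission; deep intronic; weak predictor support).
Background consequences are limited to {missense, synonymous, intronic} and
< quorum damaging calls, so the planted pair is the unique expected survivor
set — the generator defines the study conditions, not a difficulty dial.

Genotypes are emitted exactly as a diploid-assuming caller would see them:
within the heterozygous deletion, the carrier mother and the hemizygous
proband appear homozygous for the remaining allele. Exon counts are
negative-binomial with mean = depth × library factor × (exon length / read
length) × copy/2, dispersion 0.05 (variance μ + 0.05 μ²; exome capture is
overdispersed, so a pure Poisson would understate the caller's task) and
depth 100×. Library-size factors U(0.8, 1.2) force the total-mapped-reads
normalization to do real work. Totals derive from the expected *diploid*
on-target yield at an 82.8 % on-target rate: they emulate a whole-exome
library in which the simulated region is a negligible fraction of the
capture, so a regional deletion does not shift the library size. Exon
boundaries fall on codon boundaries, and the target intron is rewritten so
that retention yields a PTC after exactly 5 additional codons — pinning the
expected splice outcome while `find_ptc` itself stays phase-general (and is
tested on random-phase transcripts).

Not modelled: read-level artifacts (FASTQ, mapping noise, GC/mappability
bias), linkage between variants outside the deletion, genotyping error
outside the deliberate pseudo-hom artifact, off-target coverage bins, and
annotation error. Passing tests therefore demonstrate the *logic* of the
cascade/CNV/comphet chain under realistic count noise, not robustness to
alignment- or annotation-level failure modes of real exomes. The study's
absolute cascade counts (≈130 k → 27 k → 2 k → 392 → 2) depend on real
exomes and annotation versions and are not reproduction targets; the
package's properties (monotonicity, chain consistency, commutation,
planted-truth recovery) are.

The "no CNV support" variant scene (`deletion_in_counts=False`) keeps the
pseudo-hom genotype pattern but simulates counts at copy 2 everywhere,
emulating a spurious pseudo-hom (e.g. allele dropout): the hypothesis is
proposed and then refuted, and no compound het is reported.

## Numerical and design choices

- Coordinates 1-based inclusive everywhere (VCF/HGVS); BED-like outputs are
  explicitly documented as 1-based.
- Multi-allelic VCF sites are decomposed per alt allele before filtering.
- Determinism: every stochastic component takes an integer seed; scenes and
  reports are byte-identical across re-runs (reports carry a config hash and
  no timestamps).
- Candidate ranking tie-breaks: conservation (missing sorts last), then
  damaging-call count, then genomic position.
- The simulator treats each exon as one coverage bin; capture-kit bin
  structure is not modelled.
- Problem sizes in the test and acceptance runs (20 pipeline seeds, 100 CNV
  seeds, 1,000 random transcripts for the codon-scan oracle) were chosen as
  the smallest sizes at which the Monte-Carlo bands (ratio in [0.4, 0.6],
  ≥ 95 % breakpoint recovery) are stable across seeds.

## Known limitations

- The ratio caller needs a copy-normal reference sample over the region (or
  the per-bin median mode, `reference: "median"`, which in turn misleads
  when most samples share the event); a deletion shared by reference and
  test sample is invisible to the pairwise ratio.
- Breakpoints are reported at bin-edge resolution; single-base breakpoints
  require orthogonal data (e.g. array CGH) by construction.
- The ACMG engine implements the categorical 2015 combinations only; no
  specification updates, no Bayesian points.
- NMD prediction is the 50-nt heuristic; it does not model NMD escape in
  last-intron retention or long 3′ exons beyond the junction rule itself.
- The splice model assumes complete retention; partial/leaky splicing and
  cryptic-site activation are not quantified.
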