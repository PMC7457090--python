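# triodx — trio-exome diagnostics for SNV + deletion compound heterozygotes

`triodx` re-implements, as a tested and reusable pipeline, the diagnostic
computation behind a classic rare-disease trio exome study: an affected child
of asymptomatic parents, an autosomal-recessive candidate gene, and a
compound heterozygote that a naive analysis would miss because one of its two
alleles is not a point variant but a multi-gene heterozygous deletion.

It is written for clinical-bioinformatics and statistical-genetics
practitioners who want the individual computational steps — not a monolithic
black box — available as a library with planted-truth simulation for testing.

## What it computes

1. **Prioritization cascade** (`triodx.cascade`). Annotated trio variants are
   filtered in fixed order: disease-panel gene membership → protein/splice
   consequence → population MAF < 5 % (strict) → autosomal-recessive
   transmission → in-silico predictor quorum with a splice/LoF bypass. A
   `FilterTrace` records per-stage counts (the Sankey numbers).
2. **Pseudo-homozygosity rule** (`triodx.cascade`, `triodx.trio`). A proband
   genotyped hom-alt with one het parent and one hom-ref parent is Mendelian-
   inconsistent under diploid transmission. Instead of discarding the site as
   an error, the cascade tags it and `propose_hemizygosity` emits the
   hypothesis that the hom-ref parent carries a deletion over the gene.
3. **Read-ratio CNV calling** (`triodx.cnv`). Per-exon read counts are
   normalized per sample to total mapped reads (counts per million), summed
   per gene, and divided by a reference sample (the unaffected-by-CNV parent):
   r_g = (c_g^S / N^S) / (c_g^R / N^R). Runs of ≥ 2 consecutive genes with
   r < 0.7 become loss segments; mean r ≈ 0.5 ⇒ one-copy (heterozygous) loss,
   r < 0.25 ⇒ homozygous loss. Span and gene-overlap accounting included.
4. **Compound-het resolution** (`triodx.trio`). A hemizygosity hypothesis is
   confirmed when a deletion call overlaps the gene, is carried by the
   suspect parent and the proband, and is absent from the SNV-carrier parent
   — yielding an SNV-in-trans-with-deletion call.
5. **ACMG classification** (`triodx.acmg`). Criterion codes (PVS/PS/PM/PP,
   BA/BS/BP) are combined by the 2015 categorical rules into the five tiers,
   with conflict detection and a rule-by-rule explanation.
6. **Splice consequence** (`triodx.splice`). A splice-acceptor variant
   (offsets −1..−8; −1..−2 canonical) is modelled as full intron retention;
   the first in-frame stop at/after the disrupted junction is the premature
   termination codon (PTC), and nonsense-mediated decay (NMD) is predicted by
   the 50-nt last-junction rule.
7. **Synthetic trio scenes** (`triodx.synthetic`). A toy multi-gene region
   with a planted paternal acceptor −3 SNV, a maternal multi-gene deletion
   transmitted to the proband (hemizygous sites emitted as a diploid caller
   reports them: homozygous), a benign recessive missense, stage-targeted
   background variants, and negative-binomial exon coverage proportional to
   copy number. All truth is serialized.

## Worked example

```sh
python analysis/01_simulate_trio.py
python analysis/02_filter_cascade.py
python analysis/03_cnv_deletion.py
python analysis/04_diagnose.py
```

The cascade on the default simulated family (22 genes, 42 variants):

```
stage         in   -> out
panel          42 -> 35
consequence    35 -> 22
maf            22 -> 15
inheritance    15 -> 5
prioritize      5 -> 2

surviving candidates:
  chr_sim:15887:C:G  GENE13  splice-region  conservation=0.911  tags=Mendelian-inconsistent: possible hemizygosity
  chr_sim:19904:C:T  GENE16  missense       conservation=0.841  tags=hom-AR
```

Exactly two variants survive: the planted acceptor −3 SNV — retained
*through* its Mendelian inconsistency by the pseudo-homozygosity rule — and a
benign recessive missense. The CNV step then finds the maternal deletion:

```
deletion calls: 1
  chr_sim:9005-19001  9,997 bp (0.01 Mb), mean ratio 0.512, copy 1,
  carriers mother,proband, 8 genes: GENE08,...,GENE15
```

and the full diagnostic run resolves and classifies both candidates:

```
confirmed compound heterozygotes: 1
  GENE13: SNV chr_sim:15887:C:G (father) in trans with deletion (mother)
candidates:
  chr_sim:15887:C:G GENE13 splice-region ... ACMG=Pathogenic [PM2,PM3,PM4,PS3]
  chr_sim:19904:C:T GENE16 missense      ... ACMG=Benign    [BP6,BS1,BS2,PM1]

splice-consequence detail for the confirmed SNV:
  retained intron: 1
  PTC after 5 additional amino acids (position 189 in the retained-intron transcript)
  NMD predicted: True
```

Reading: the proband's disease allele pair is one paternal splice SNV whose
retained intron creates a premature stop 5 codons past the exon–intron
junction (NMD predicted), in trans with a maternal 8-gene deletion; the
evidence set PS3+PM2+PM3+PM4 combines to Pathogenic, while the frequent
missense homozygote combines to Benign (BS1+BS2 with a stray PM1, no
conflict).

The same commands are available from the shell: `triodx synth`, `triodx run
--config cfg.json`, `triodx classify --evidence PS3,PM2,PM3,PM4`, `triodx cnv
--counts counts.tsv --reference father`.

## Layout

- `src/triodx/` — the library (every computation lives here)
- `analysis/` — numbered narrative drivers over the library
- `tests/` — unit, property and acceptance tests (independent oracles:
  exhaustive enumerations, brute-force codon scans, hand-computed matrices)
- `docs/methods.md` — model assumptions, parameter choices, limitations
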