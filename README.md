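# foxyloci

Structural-variant genotyping and expression association at a synthetic
grape aroma-gene locus.

The "foxy" aroma of *Vitis labrusca*-derived grapes such as 'Concord' is
driven by methyl anthranilate (MA), whose biosynthetic gene *AMAT* is
regulated by a set of promoter indels: a 426-bp promoter element (with a
nested 26-bp element carrying the CBNAC repressor motif `TTGCTTA`; its
absence leaves the 400-bp variant), a 42-bp element sitting inside the
56-bp spacer between two consensus TATA boxes (`TATAWAW`), a 3-kb promoter
deletion, and exonic LTR-retroelement insertions (a 499-bp solo LTR or a
full 499 + 188 + 496 bp TRIM, both flanked by a 5-bp target-site
duplication). Alleles lacking the repressive promoter elements express the
gene several-fold higher; the exonic insertions and whole-locus loss
silence it.

`foxyloci` rebuilds this analysis as a fully testable pipeline on synthetic
data. It is aimed at method developers and teaching: every stage can be
verified against generator truth, with no sequencing downloads.

## What it does

* **`synthetic_locus`** — builds diploid promoter+gene haplotypes carrying
  any configuration of the indels above (each indel edge gets a boundary
  direct repeat and a nearby inverted repeat, the replication-slippage
  signature), and simulates short reads, qPCR Ct tables and MA panels with
  configurable effect sizes and noise.
* **`indel_detection`** — anchor-chained, base-level indel calling between
  alleles with VCF-style left-alignment; reports each call's placement
  ambiguity.
* **`junction_genotyping`** — 160-bp junction templates (80 bp per side),
  crossing-read counting (reads must span ≥ 20 bp on each side of the
  junction, template positions 61–100), a presence/absence decision table
  for diploid genotype strings (`0/426`, `426/-`, `-/-`, ...), and the
  equivalent PCR-assay interpreter.
* **`repeat_signature`** — boundary direct repeats, near-boundary inverted
  repeats, slippage-compatibility classification, IUPAC motif scanning and
  TATA-box spacing.
* **`te_classifier`** — TSD detection, terminal-repeat discovery, soloLTR /
  fullTRIM classification, and prediction of the LTR–LTR recombination
  product.
* **`association`** — comparative ΔΔCt folds (`2^−ΔΔCt` vs a baseline
  accession), genotype-group means ± SE, expression/MA rank concordance
  with discordance flags, and TPM/fold-change DEG pre-filters.

## Worked example

```bash
foxyloci run --seed 1 --outdir out
```

prints one row per accession of the default panel:

```
 accession genotype_426 genotype_42  signatures_ok  fold                        group te_class
      Alba      426/426         0/0           True  30.0 element present (X/X or X/-)      NaN
      Caco      426/426       42/42           True   2.0 element present (X/X or X/-)      NaN
   Catawba          0/0       42/42           True   7.0         element absent (0/-)      NaN
Chardonnay      426/426       42/42           True   0.0 element present (X/X or X/-) fullTRIM
   Concord          0/0       42/42           True  14.0         element absent (0/0)      NaN
   Hubbard          0/0       42/42           True  14.0         element absent (0/0)      NaN
   Hybrid1        0/426       42/42           True   8.0           heterozygous (0/X)      NaN
    Merlot      426/426       42/42           True   1.0 element present (X/X or X/-)      NaN
 PinotNoir      426/426       42/42           True   1.0 element present (X/X or X/-)  soloLTR
  Semillon          -/-         -/-           True   0.0           locus not detected      NaN
```

Reading the row for 'Concord': junction-template genotyping of its
simulated 30× reads calls it homozygous-absent for the 426-bp element
(`0/0`) and a carrier of the 42-bp element (`42/42`); all canonical indels
show slippage-compatible repeat signatures; its ΔΔCt fold versus the
'Merlot' baseline is 14 (two alleles, each expressing 7× the reference
allele unit because the repressive 426-bp element is missing).
'Semillon' has no locus at all (`-/-`, fold ≈ 0); 'Chardonnay' carries a
full TRIM in exon 2, silencing that allele. Note that junction genotyping
alone reports `426/426` for accessions that actually have one allele
missing (e.g. 'Merlot', truth `426/-`): distinguishing those requires a
locus-dosage input, mirroring the method's real limitation.

The intermediate artifacts (allele FASTA, read FASTQ, Ct/MA/genotype TSVs,
checksum manifest) land in `out/`.

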