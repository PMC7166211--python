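# Methods

## The synthetic locus

The generator emits a promoter + gene haplotype of about 5.1 kb: a 3300-bp
upstream region (coordinates −3300…−1, with the 'A' of the ATG start codon
at +1 and no position 0) followed by a fixed 600/300/900-bp
exon–intron–exon gene body. The gene-body proportions are arbitrary; only
the exon-2 insertion site matters downstream, so nothing is gained by
mimicking real exon sizes.

Structural variants are realized by deleting or inserting blocks in a
single "master" sequence built per background seed, so any two haplotypes
sharing a seed differ *only* by their configured variants:

| feature | location | size |
|---|---|---|
| 426-bp element | −2589…−2164 | 426 bp |
| nested 26-bp element (contains `TTGCTTA`) | −2420…−2395 | 26 bp |
| 42-bp element | −354…−313 | 42 bp |
| promoter deletion | −3150…−151 | 3000 bp |
| TATA boxes (`TATATAA`, `TATAAAT`) | −369…−363, −306…−300 | 7 bp each |
| exon-2 insertion site | 300 bp into exon 2 | TSD 5 bp |

The 42-bp element fills the middle of the 56-bp spacer between the two
consensus TATA boxes, so its removal leaves a 14-bp spacer. The element
coordinates −354…−313 and the 426-bp element's right edge at −2164 are the
published landmarks of the locus; where the published interval notation for
the 426-bp element spans 432 positions, the element *length* (426) is
treated as authoritative. The retroelement is a 499-bp 5′LTR, a 188-bp
internal region and a 496-bp 3′LTR (the 5′LTR minus three interior bases);
the solo-LTR variant is the 5′LTR alone. Both integrate with a 5-bp
target-site duplication, so the locus gains 1188 or 504 bp respectively.

Every indel edge is built with a 6-bp boundary direct repeat (one copy
leading the element, one immediately 3′ of it — the midpoint of the 5–8-bp
range such repeats span at this locus) and a 5-bp inverted repeat whose
outer arm overlaps the flanking direct-repeat copy and whose inner arm lies
inside the indel (midpoint of the reported 4–6/4–7-bp range; both
overridable). Guard bases pin each repeat to exactly its configured length
and keep generated indels left-aligned as placed, which is what lets tests
equate detector output with generator truth. The neutral background is
i.i.d. with GC ≈ 0.4 (no published background composition exists for the
locus); a deterministic cleanup pass removes chance `TATAWAW` matches from
the TATA region so the two stamped boxes are the only consensus hits.

Whole-locus loss emits an empty sequence — the haplotype contributes no
reads and no expression, like the accession in which the locus could not be
amplified at all.

## Read, Ct and MA simulation

Reads are single-end, uniformly placed, Poisson in number
(mean = coverage × length / read length per haplotype), half
reverse-complemented, with optional i.i.d. substitution errors. Read names
carry the haplotype of origin and start position as oracle labels.
Realistic error profiles and paired ends are deliberately out of scope: the
genotyping stage needs junction-spanning coverage, not platform realism, so
passing tests demonstrate correctness of the calling logic, not robustness
to real sequencing artifacts.

Expression follows an additive two-allele model: a functional allele
contributes one unit, multiplied by 7 when its 426-bp element is missing
and by 15 when its 42-bp element is missing; alleles with the promoter
deleted, an exonic insertion, or the locus lost contribute 0. The 7×
single-allele effect reproduces the reported 6–8-fold group contrast and
makes the homozygous-absent accession exactly twice its hemizygous parent;
15× places the 42-bp-deletion homozygote at the top of the observed
expression range. Folds are scaled so the baseline accession equals 1. Ct
values are generated at exact doubling efficiency
(Ct_target = Ct_ref + 5 − log2(fold), reference Ct 20, undetected capped at
40) with independent Gaussian noise of sd `ct_noise_sd` per well, so at
sd = 0 the ΔΔCt estimator inverts the model to machine precision. MA values
are a monotone (default identity) function of fold with log-normal noise;
flagged accessions get a low fixed MA regardless of expression, emulating
the high-expression/low-MA discordance real panels show (substrate or
degradation effects the model does not represent).

## Indel calling and canonicalization

Alleles are aligned by chaining k-mers unique in both sequences (k = 16;
k = 8 in tests on short sequences), taking the longest co-linear chain, and
resolving inter-anchor gap regions: a contiguous-indel fast path (longest
common prefix/suffix) where it applies, otherwise base-level global
alignment (edlib) parsed from its CIGAR. Anchors may overhang a gap when
the indel boundary carries a direct repeat; the gap start is slid back
along the previous anchor's diagonal to compensate. Every call is then
left-aligned — the most 5′ equivalent placement, the VCF convention, chosen
because no convention is stated for the locus' published coordinates — and
annotated with `ambiguity_range`, the span between leftmost and rightmost
equivalent placements. For a boundary tandem repeat this equals the repeat
length, which the repeat-signature module measures independently; the
cross-module equality is tested. Substitutions are reported separately and
ignored by all indel-consuming stages.

## Junction genotyping

A deletion is assayed by a 160-bp template joining 80 bp of flank on each
side of the deletion junction; the element's presence by a template
centered on the element's 5′ boundary; an insertion by a mirrored template
pair at its two boundaries. A read supports a template when its best
ungapped overlay (either strand, candidate offsets from shared 16-mers
sampled at stride 8, minimum 24-bp overlap) has ≤ 2 mismatches and covers
the crossing window — ≥ 20 bp on each side of the junction, template
positions 61–100 at default flanks. Gapped alignment is unnecessary because
simulated reads contain no indels. An allele state is "present" with ≥ 2
crossing reads; no threshold is published for the original survey, so 2 is
a declared default. The decision table is: junction+internal → heterozygous;
junction only → homozygous-absent; internal only → homozygous-present;
neither → locus not detected. Homozygous versus hemizygous (`X/X` vs
`X/-`) is not decidable from junctions alone; an optional locus-dosage
ratio (locus depth over a control region, threshold 0.65) demotes the
homozygous calls, and dosage evidence conflicting with a heterozygous call
raises an error. The insertion templates see only the outermost ~80 bp of
the inserted element, which is why solo-LTR and full-TRIM insertions
genotype identically — a limitation of the underlying method that the test
suite asserts rather than fixes.

## Repeat signatures and motifs

The boundary direct repeat is measured as the indel segment's homology
extension into its flanks (modular indexing, since a periodic region lets a
deletion slide farther than the segment is long); the larger of the 5′ and
3′ extensions is reported, capped at 12 bp, homopolymers suppressed.
Inverted repeats are all maximal reverse-complement arm pairs with both
arms within 30 bp of an indel boundary and arm length 4–8 bp,
homopolymers excluded, annotated with direct-repeat overlap and
arm-inside-indel flags. An indel is slippage-compatible when its direct
repeat reaches 5 bp and some inverted repeat reaches 4 bp (both
thresholds configurable; the classification is monotone in them). Motif
scanning is forward-strand IUPAC matching (overlaps included) — the TATA
and repressor motifs are orientation-specific — with an optional
both-strands flag. `tata_spacing` counts `TATAWAW` hits inside the
allele's recorded TATA region and reports the bases strictly between the
outermost two hits; fewer than two hits reports a missing spacer, not an
error.

## TE decomposition

The TSD is the longest ≤ 10-bp duplication consistent with integration,
read off the left-aligned insertion call (segment prefix equal to the bases
immediately 3′ of the insertion site). Terminal repeats are found by
seeding the insertion's leading 50 bp against its second half (edlib infix
search), then refining the 5′-arm length within ±10 bp by global alignment;
arms count when identity ≥ 0.9, a threshold tolerating the 499-vs-496-bp
divergence of the built element. Classification: terminal repeats plus a
non-empty internal region → fullTRIM; otherwise a whole-insertion match to
a supplied LTR reference (identity ≥ 0.9) → soloLTR, with a 400–700-bp
length heuristic as the reference-free fallback — heuristic by nature, and
the reason a random 500-bp insertion without a reference would be
mislabeled. The predicted recombination product is one LTR plus the
retained TSD; primer-binding-site and polypurine-tract motifs are
annotation-only and never required for classification, since no sequences
are published for them.

## Association

ΔΔCt folds use per-replicate ΔCt, per-accession means, and a fold range of
2^−(ΔΔCt ± sd(ΔCt)); the baseline fold is exactly 1 by construction. Group
summaries report mean and standard error **across accessions** (replicate
scatter feeds only the fold range), under a configurable genotype→group
mapping whose default follows the element-present/absent scheme; group
membership counts are config-driven, never hard-coded. No between-group
hypothesis test is offered as a headline result — the underlying analysis
reports group means ± SE only. Concordance is Spearman rank correlation,
undefined below 3 pairs; discordance is one-sided by design
(fold ≥ 10 with MA ≤ 2 is flagged as tolerated discordance; fold ≤ 2 with
MA ≥ 10 violates the expression-drives-metabolite model and is flagged
separately). The DEG pre-filters consume TPM tables (and an externally
computed adjusted-p table — differential-expression testing itself is out
of scope) with inclusive thresholds: ≥ 50 TPM at fruit set or veraison,
≥ 5-fold between those stages, and for the between-class list ≥ 5-fold with
padj ≤ 0.05 at both veraison and ripening, split by direction.

## Test design and problem sizes

Expected values come from independent oracles: placement enumeration by
string surgery, a hand-written Needleman–Wunsch DP, exhaustive substring
scans for repeats, positional IUPAC checks, and closed-form ΔΔCt
identities. Oracle-equivalence runs 1000 random deletion instances on
sequences ≤ 300 bp (the quadratic inverted-repeat cross-check on every
10th instance — the semantics do not vary between instances, the scans are
merely slow); genotype recovery runs 100 diploids at 30× error-free
coverage cycling through six genotype classes; noisy fold recovery uses
Ct sd 0.5 with 30 replicates and a 20% relative tolerance on the 7×
group-effect ratio (the per-accession fold error at those settings is ≈ 9%,
so 20% gives ~2σ headroom), and estimator-bias checks average over 20
simulated panels. Determinism is enforced end to end: every stochastic
step takes an explicit seed, and the pipeline writes a sha256 manifest that
tests compare across reruns.

## Known limitations

* The generator's indels are clean blocks on an i.i.d. background: no SNP
  heterozygosity between alleles, no repeat-induced mis-anchoring beyond
  the engineered boundary repeats, no structural heterogeneity within an
  element class. Detector behavior on real, messy promoters is not
  demonstrated by these tests.
* Junction genotyping assumes ungapped reads and modest error; real indels
  inside reads would require a gapped aligner.
* The reference-free solo-LTR heuristic is length-based and will mislabel
  LTR-sized random insertions.
* The additive, noise-free-mean expression model ignores trans effects,
  developmental stage, and efficiency differences between primer pairs.
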