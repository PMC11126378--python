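# founderseg

Founder-haplotype (shared identity-by-descent segment) detection around an
index variant, for rare-disease cohorts genotyped by genome or exome
sequencing.

## The problem

When several ostensibly unrelated patients carry the same rare pathogenic
allele, the allele often descends from a single ancestor. The carriers then
share a chromosomal segment around it — a *founder haplotype* — whose extent
shrinks each generation as recombination chips away at the flanks. Detecting
that segment from routine multi-sample variant calls supports the
identity-by-descent interpretation and dates the allele qualitatively: the
shorter the shared segment, the older the founder event.

The motivating use case is a cohort of five carriers of the perlecan
(*HSPG2*) missense allele chr1:21,839,005 G>A (p.G3324R, GRCh38) in
dyssegmental dysplasia of the Rolland–Desbuquois type (DDRD): two patients
homozygous, three compound-heterozygous, one genome-sequenced and four
exome-sequenced. `founderseg` packages that analysis as a reusable,
tested pipeline: cohort IO, the segment scan, catalog/annotation statistics,
splice-donor outcome classification, and a synthetic cohort simulator with
ground truth.

## The method

All carriers of the index allele are scanned over a window (default 5 Mb on
each side of the index variant). Homozygous carriers are autozygous across
the founder segment, so inside it every marker must be homozygous in them.
Heterozygous carriers hold the founder haplotype on one chromosome; because
the cohort is unphased, a heterozygous genotype in a heterozygous carrier is
assumed to lie on the founder allele. Each site's genotype pattern is
classified as:

* **BREAKER** — incompatible with sharing: a heterozygous genotype in a
  homozygous carrier; two homozygous carriers fixed for different alleles;
  or a haplotype-defining allele (homozygous-alternate in a homozygous
  carrier) confidently absent (0/0) from a heterozygous carrier;
* **CONSISTENT** — haplotype-defining and every callable genotype
  compatible (HOM_ALT in homozygous carriers; HET or HOM_ALT in
  heterozygous carriers);
* **UNINFORMATIVE** — everything else, including uncallable sites (exome
  gaps are explicit `MISSING`, never silently reference).

The shared segment is the maximal run around the index variant: scanning
outward, UNINFORMATIVE sites are skipped and extension stops at the first
BREAKER per side (or the window edge). Endpoints are the outermost
CONSISTENT sites; the closed-interval length is `end − start + 1`. An
incremental mode reproduces the practical workflow — find the homozygosity
run in the homozygous carriers first, then narrow it with each additional
carrier — and provably returns the same final segment for every sample
order.

## Worked example

```
$ founderseg detect --out segment.tsv
shared segment 1:21775527-21861499 (85973 bp, 7 supporting sites)
  p-side breaker at 21773254: HET_IN_HOMOZYGOUS_CARRIER in DDRD_P02
  q-side breaker at 21862954: ABSENT_IN_HETEROZYGOUS_CARRIER in DDRD_P06
```

The five carriers share an 85,973-bp segment (chr1:21,775,527–21,861,499).
The p-terminal margin is set by a heterozygous call in homozygous carrier
DDRD_P02 at 21,773,254 — impossible inside an autozygous segment — and the
q-terminal margin by the site at 21,862,954 whose alternate allele all other
carriers hold but heterozygous carrier DDRD_P06 confidently lacks. Seven
consistent markers (including the index variant) support the segment.

```
$ founderseg annotate
variants per disease: DDSH=8, SJS=44
SJS: 11 missense; InMeRF mean 0.598 SD 0.227; 2 missense in domain IV
```

The packaged catalog of pathogenic *HSPG2* variants holds 44 records for
Schwartz–Jampel syndrome (SJS) and 8 for the Silverman–Handmaker type of
dyssegmental dysplasia (DDSH). The 11 SJS missense variants have InMeRF
pathogenicity scores of mean 0.598 and sample SD 0.227 (the index missense
allele scores 0.752, above that mean), and exactly 2 of the 11 fall inside
perlecan domain IV (the immunoglobulin-repeat stretch, codons 1695–3655).

```
$ founderseg splice
HSPG2_intron54_donor: predicted EXON_SKIP_FRAMESHIFT (authentic 9.40, best candidate -6.23 at +6, exon 136 bp)
HSPG2_intron84_donor: predicted EXON_SKIP_FRAMESHIFT (authentic 6.54, best candidate -11.07 at -20, exon 110 bp)
```

For the two splice-donor variants in the cohort, every candidate cryptic GT
near the disrupted authentic donor scores far below it, so both are
predicted to skip the upstream exon (136 bp and 110 bp — neither a multiple
of 3, hence frameshifting). Outcomes are predictions from donor-strength
scores only.

The same analyses are available as library calls
(`founderseg.detect_segment`, `founderseg.score_summary`,
`founderseg.classify_outcome`, …), and `founderseg run` executes the whole
pipeline into a report bundle. `founderseg simulate --seed 7 --out dir/`
generates a synthetic cohort (VCF + roles + truth JSON) for method
evaluation; see `docs/methods.md` for the simulator's model.

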