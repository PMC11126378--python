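# Methods

## Model and assumptions

`founderseg` tests whether carriers of a rare index allele share the
surrounding chromosomal segment identically by descent, using only unphased
genotypes from a multi-sample call set. Three assumptions carry the whole
method:

1. **Autozygosity of homozygous carriers.** A sample homozygous for the
   index allele carries two copies of the founder haplotype, so every
   marker inside the shared segment must be callably homozygous in it. A
   heterozygous call in such a sample is incompatible with continued
   sharing and truncates the segment (breaker rule *a*); two homozygous
   carriers fixed for different alleles are likewise incompatible (rule
   *b*).
2. **The unphased-heterozygote assumption.** Compound-heterozygous carriers
   hold the founder haplotype on one chromosome. Without parental data a
   heterozygous genotype cannot be phased, so a HET call in a heterozygous
   carrier is *assumed* to sit on the founder allele. Only a confident
   homozygous-reference call can contradict sharing in these samples, and
   only at *haplotype-defining* sites — sites where at least one homozygous
   carrier is homozygous-alternate (rule *c*). One such carrier suffices:
   exome data routinely leaves the other homozygous carrier uncalled, and
   demanding both would discard most of the signal.
3. **Alt-alleles define the haplotype.** Where the homozygous carriers are
   callably homozygous-reference the founder haplotype carries the
   reference allele; heterozygous carriers' alternate alleles there may lie
   on their other chromosome and cannot break sharing. Such sites are
   UNINFORMATIVE and are skipped, as are sites that are missing in the
   deciding samples.

Consequences worth stating plainly: the detected segment is an **upper
bound** on the true IBD segment (assumption 2 can absorb chance
identity-by-state sharing), and a **lower bound** only down to marker
resolution (the endpoints are the outermost consistent markers, not the
unobserved recombination breakpoints, and the flanking breakers lie strictly
outside the reported segment). Coordinates are 1-based with fully closed
intervals throughout; a segment's length is `end − start + 1`.

### Scanning and narrowing

`detect_segment` classifies every site, then scans outward from the index
variant per side, skipping UNINFORMATIVE sites and stopping at the first
BREAKER (recorded with its offending sample and rule) or the window edge.
When split multi-allelic records share one position, a breaker at that
position wins over a consistent record (conservative truncation). The
default window is 5 Mb on each side of the index variant; no maximum
uninformative gap is imposed by default because exome data has long
uninformative gaps by construction (`max_uninformative_gap_bp` is available
for sensitivity analysis). The algorithm is deterministic.

`narrow_incrementally` reproduces the practical workflow: detect the
homozygosity run in the first homozygous carrier, then re-run detection on
growing sample subsets. Because breakers can only accumulate as samples are
added, each step's segment contains the next, *provided* the homozygous
carriers scanned first are fully callable (a genome-sequenced first carrier,
as in the reference cohort); with a partially callable first carrier a later
homozygous carrier can turn a missing site into a defining one. The final
step uses every sample and always equals joint detection, for any sample
order.

### Genotype semantics

`MISSING` (not callable) is distinct from `HOM_REF` (callably reference)
everywhere. The VCF reader maps `./.` to MISSING by default, which makes
read → write → read a fixed point. An optional coverage-aware mode
(`uncalled="infer"`) encodes the genome/exome asymmetry: an uncalled site in
a genome-sequenced sample is treated as confident HOM_REF, while in an
exome sample it is HOM_REF only inside that sample's callable capture
intervals (per-sample BED) and MISSING elsewhere.

## Catalog and annotation statistics

The packaged catalog fixtures transcribe the published tables of pathogenic
*HSPG2* variants (44 in Schwartz–Jampel syndrome, 8 in
Silverman–Handmaker-type dyssegmental dysplasia) and the five-patient
cohort table (4 distinct variants). Score summaries use the arithmetic mean
and the **sample** standard deviation (n−1 denominator), reported to 3
decimals; the population-SD alternative is rejected because summaries of a
small catalog estimate dispersion over a notional population of pathogenic
variants. Allele frequencies are computed from allele counts and rounded to
significant figures (default 2), matching the scientific-notation
convention for minor-allele frequencies; the exact rational is exposed.
Protein domains are closed, non-overlapping codon intervals; a missense
variant counts toward a domain only if its codon lies inside — variants
annotated at domain interfaces (e.g. "Domains IV and V") fall outside every
pure domain range and are counted in neither.

## Splice-donor outcome classification

For a variant destroying an authentic donor GT, every GT dinucleotide
within ±`window_bp` (default 35) is a candidate cryptic donor, scored on
its 9-mer window (3 exonic + 6 intronic bases) by an injected scorer.
Classification: if the best candidate reaches
`max(floor, authentic_score − margin)` the prediction is cryptic
activation; otherwise the upstream exon is predicted skipped, frameshifting
iff its length is not a multiple of 3. The thresholds are explicit
configuration (defaults `margin=3.0`, `floor=0.0` score units) because the
underlying judgement — a candidate "much lower" than the authentic site —
has no canonical cutoff; the packaged cases classify identically for any
margin in (0, 15]. The maximum-entropy donor model itself is not
implemented: its parameter tables are distributed separately, so the scorer
is a contract (`9-mer → float`), with a lookup-table implementation and a
packaged fixture mapping the synthetic context 9-mers to the published
scores. The packaged donor-context sequences are synthetic (the real
intronic sequence is not shipped); they reproduce the candidate-offset
geometry (+6; −20/+33) exactly. All outcomes are labelled predictions; no
transcript-level validation is implied.

## Synthetic cohort simulator

`simulate_cohort` generates the structure the detector assumes, plus ground
truth:

| parameter | default | meaning |
|---|---|---|
| `window_bp` | 10,000,001 | window centered on the index variant (5 Mb per side) |
| `n_hom_carriers` / `n_het_carriers` | 2 / 3 | founder copies: 2 per homozygous, 1 per heterozygous carrier |
| `n_genome_samples` | 1 | leading samples with genome coverage; the rest are exome |
| `generations_to_founder` | 20 | meioses separating each sample from the founder |
| `recomb_rate_per_bp_per_meiosis` | 1e-8 | ~1 cM/Mb |
| `marker_density_per_bp` | 1e-3 | markers on a regular grid (1 per kb) |
| `background_af_alpha/beta` | 0.2 / 2.0 | Beta background allele frequencies, skewed rare |
| `ancestral_alt_fraction` | 0.8 | fraction of markers where the founder haplotype is alt |
| `exome_fraction` | 1.0 | fraction of markers capturable in exome samples |
| `genotype_error_rate` | 0.0 | per-genotype error probability |

Each founder copy retains the ancestral haplotype over
`[index − L, index + R]` with `L, R ~ Exponential(rate = generations ×
recomb_rate)` per side — a Haldane-style no-interference approximation with
the correct length scale (at the defaults the intersection over 7 founder
copies spans ~0.7 Mb per side). The ancestral haplotype carries the alt
allele at a fixed fraction of markers, drawn independently of the
background frequency: markers are modelled as ascertained sites where
carriers differ from the reference, and tying the ancestral allele to the
population frequency would size-bias founder markers toward common alleles.
Outside retained intervals and on non-founder chromosomes, alleles are
Bernoulli draws from each marker's background frequency. Exome samples
share one capture mask. Index-site genotypes are exempt from error and
masking: they are the cohort's ascertainment condition. All randomness
derives from one master seed through named counter-based (Philox) streams,
so changing the sample count does not perturb earlier draws and equal seeds
give byte-identical VCFs.

**What the simulator does not emulate:** linkage disequilibrium and
population haplotype structure, marker ascertainment bias beyond the
ancestral-alt fraction, clustered exome targets (the capture mask is
i.i.d.), recombination interference and hotspots, and calling artifacts
correlated across samples. Passing recovery tests therefore show the
detector is correct *under its own model*, not that real cohorts yield
calibrated segment boundaries.

### Recovery metrics

`recovery_study` simulates, detects and compares per replicate. At genotype
error 0 with full coverage, no breaker can occur inside the true shared
interval, so the detected segment always contains the *informative core* of
the truth (every ancestral-alt marker inside it); a failure of that
containment is counted as a violation and never occurs under those
conditions. Overshoot past the truth boundary, by contrast, is expected and
reported separately: just outside the truth interval the shared pattern can
persist by chance with per-site probability of order the allele frequency —
the same identity-by-state effect that makes the detected segment an upper
bound on real data. Boundary error (mean absolute distance between detected
and true boundaries) stays at the marker-spacing scale at the default
density; the regular marker grid keeps that bound tight, which is why a
grid was chosen over a Poisson scatter.

## Numerical and degenerate-input choices

* Zygosity codes are int8 (`MISSING=-1, HOM_REF=0, HET=1, HOM_ALT=2`);
  site classification is vectorized over the whole matrix.
* Indels are parsimony-trimmed and left-aligned (anchor-base convention);
  left-shifting requires a reference context and stops at position 1.
* Report TSVs write integers without separators and scores with fixed
  decimals; reading a report back reproduces the segment bit-exactly.
* Degenerate cases: a segment may be a single site (`length 1`); a cohort
  whose index site is not CONSISTENT (e.g. no homozygous carrier) is
  rejected as malformed rather than guessed at; an empty candidate list in
  splice classification falls through to the exon-skip branch.
* Test problem sizes: oracle-equivalence runs 100 random cohorts of ≤300
  markers against exhaustive window enumeration; recovery runs 100
  replicates of the default 10,001-marker cohort; narrowing properties use
  50 simulated cohorts on sub-Mb windows — sizes chosen to exercise the
  asymptotics while keeping the suite fast.

## Known limitations

* No statistical IBD model: no genotype likelihoods, no population LD, no
  recombination-map-aware probabilities — the scan is rule-based, as is
  appropriate for a handful of carriers and a single locus.
* No phasing: the unphased-heterozygote assumption can only overestimate
  the shared segment; parental genotypes would tighten it.
* Structural variants are out of scope; markers are SNVs and small indels.
* The gene-panel fixture is illustrative (the gene of interest plus 61
  plausible skeletal-dysplasia genes), not a transcription of any published
  panel.
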