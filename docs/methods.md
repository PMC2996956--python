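# Methods

This note documents the models, algorithms, defaults and numerical
choices behind `ssr_survey`, and what the synthetic-data tests do and do
not establish about real sequence libraries.

## Repeat model and detection

A microsatellite locus is a maximal perfect tandem array of a primitive
repeat unit of 2–6 bp. Primitivity (the unit is not a whole-number
repetition of a shorter string) ensures each array has a unique smallest
period: by the Fine–Wilf periodicity lemma, an array of at least two
units whose leading unit is primitive cannot simultaneously carry a
shorter period, so requiring a primitive unit both fixes the reported
unit length to the smallest period and prevents the same tract being
reported again at a multiple of its period (an `(AT)n` array is never
also an `(ATAT)m` array). Mononucleotide runs are outside the repeat
model entirely.

Motif classes are orbits under cyclic rotation only. Reverse-complement
merging is deliberately not applied: single-pass BAC-end and EST reads
are directional, and the strand-specific class counts (6 dinucleotide, 20
trinucleotide) are what the downstream goodness-of-fit degrees of freedom
(5 and 19) are built on. Merging by reverse complement would collapse
these to 4 and 10 and change every df downstream. The canonical class
representative is the lexicographically smallest rotation — an arbitrary
but stable convention shared by common SSR miners.

The scanner compares the encoded sequence with itself shifted by k and
reads maximal match runs; it is exactly equivalent to trying every
(start, primitive unit) pair and extending maximally, which is how the
test-suite oracle is written. Any N terminates extension and never
participates in a match. Defaults:

| parameter | default | rationale |
|---|---|---|
| `min_units` | 5 complete units | the permissive reading of a "more than five units" rule, consistent with downstream analyses that bin loci starting at 5 repeats; a CLI flag |
| `unit_lengths` | 2–6 bp | the conventional microsatellite range above mononucleotides |
| `partial_extension` | on | the span includes a perfect partial trailing unit, but `repeat_count` stays integral (complete units only) |
| `max_gap_bp` (compound filter) | 0 | only abutting/overlapping arrays are treated as compound, as no interruption threshold is defined for the survey design; both members of a compound pair are removed |
| `min_flank_bp` (terminal flag) | 50 (CLI) | loci closer than this to a read end cannot anchor a primer |

Primer design itself (product size 200–350 bp, Tm 60 °C, bounded
self-complementarity) is out of scope; the terminal flag only records
flank feasibility.

## ORF model

An ORF is an ATG through the first in-frame stop (TAA/TAG/TGA), stop
included; every qualifying ATG yields a candidate, all three frames on
both strands are scanned, and candidates shorter than `min_orf_nt`
(default 300 nt = 100 codons, the historical NCBI ORF-finder default) are
dropped. ORFs that run off the read without a stop are not reported.
These are configuration choices, not biology: the tool that inspired the
workflow does not document its settings, so both the length threshold and
the strand set are flags (`--strands forward` suits directional EST
sets).

An SSR is *inside* if contained in at least one single ORF, *outside* if
disjoint from every ORF, and *bridging* otherwise — including the case
where the locus is covered by a union of ORFs but by no single one.
Bridging loci are excluded from the placement goodness-of-fit.

## Null models and tests

The "composition" motif null is the empirical k-mer class frequency of
the whole library: overlapping k-mers on the forward strand, N-containing
and non-primitive k-mers skipped, counts pooled by rotation class and
normalized. It is an order-0 background — no Markov structure — and is
compared against observed per-locus class counts (not repeat bases) with
X² = Σ (O−E)²/E on (#classes − 1) df. `exclude_ssr_spans` optionally
masks detected repeat tracts out of the background; it is off by default
so the background describes the complete library. For unit lengths ≥ 4
the test refuses to run below 20 loci (configurable): such motifs are too
rare for the chi-square approximation to mean anything.

The ORF-placement null is the fraction of bases covered by the union of
ORF spans, by default restricted to reads that contain at least one SSR,
so the expected inside/outside split (f·n, (1−f)·n) reflects the sequence
actually carrying the tested loci.

Cross-library abundance is tested as observed SSR counts against
exposure-proportional expectations with exposure selectable as reads or
bases; Yates continuity correction is off by default (a flag). Rank tests
come from scipy: Mann–Whitney U uses the exact null when n₁·n₂ ≤ 400 and
there are no ties, otherwise the tie-corrected normal approximation;
Kruskal–Wallis is tie-corrected with p from χ²(k−1), with the degenerate
all-tied case defined as H = 0. Spearman's ρ is Pearson on mid-ranks with
the two-sided t approximation; zero variance yields a NaN sentinel.
Cells with expected counts below 5 are recorded as warnings on the
result object rather than blocking the test.

## Richness analyses

Genotype screens are categorical band labels (band sizes are not
measured), one cell per individual, diploid duplicate bands collapsed;
richness is the count of distinct labels per locus over all individuals
jointly. The screening filters drop loci that failed to amplify in all
individuals, amplified in only one species, or showed a null allele, and
the accounting report must sum exactly: retained = screened − failures −
single-species − null-allele. A locus marked ok with a missing call is an
error, because every richness estimate must rest on the same full panel.
Trinucleotide loci are pooled by GC content of the motif (0/33/67/100%),
and repeat numbers are pooled into the survey's bins (5, 6, 7–8, 9–20,
21–42 for genomic libraries; 5, 6, 7, 8, 9+ for EST libraries) for
cross-tabulation.

## Synthetic-data generator

Defaults are the study conditions of the survey the package re-implements:
reads of mean 703 bp (sd 120), i.i.d. background bases at GC = 0.35
(mild AT richness typical of insect genomic sequence), one planted SSR
per read on average, unit counts 5 + Poisson(3), and a motif mix of
~72.5% dinucleotide / 25% trinucleotide / 2.5% tetranucleotide loci with
AT-skewed dinucleotides (AT 40%, AC = AG 20%, CT 10%, GT 8%, CG 2% within
the dinucleotide share) — motif lengths above 3 kept rare, as they are in
real insect libraries. Planted tracts receive *flank rejection*: the
bases immediately adjacent are redrawn until they cannot perfectly extend
the repeat, which is what makes coordinate-exact recovery a fair
requirement rather than a probabilistic one. Tracts are placed with ≥ 2 bp
clearance; a read that would need more than half its bases inside planted
tracts is a configuration error.

The genotype model is a test harness, not a mutation-model claim: locus
allele-pool size k = 1 + Poisson(exp(a + b·n)), truncated at twice the
panel size, with n the reference repeat number (defaults a = −1.0,
b = 0.25, giving mean pool sizes rising from ~1.5 at n = 5 to saturation
above n ≈ 20); each individual draws two alleles from a stepwise ladder
centred on the reference length with geometric weights (q = 0.5).
Screen-log statuses are injected at configurable rates for filter
testing. All randomness flows from a single integer seed through one
numpy generator, so outputs are byte-reproducible.

What the generator does **not** emulate: sequencing error and indels,
quality values, vector/adapter contamination, near-duplicate reads,
compositional heterogeneity along reads (isochores, coding vs non-coding
mix), imperfect/interrupted repeats, and linkage between loci. Passing
the planted-recovery and calibration tests therefore shows the detectors
and tests are correct under their own model assumptions; it does not show
that real libraries satisfy those assumptions.

## Validation design and problem sizes

The validation suite checks the detectors against independent brute-force
oracles (1,000 random 200-mers for the repeat finder across all unit
lengths; 100 random 2-kb sequences for the six-frame ORF scan), requires
100% coordinate-exact recovery of ≥ 500 planted repeats while measuring
the background false-positive rate on a repeat-free library (~20–40
chance loci/Mb at 5 units), and calibrates every test statistic — motif
GOF, ORF GOF, abundance chi-square, Mann–Whitney, Kruskal–Wallis — to a
type-I error inside [0.035, 0.065] at α = 0.05 over 2,000 null
simulations each. Power is checked by requiring ρ > 0 in ≥ 99% of 500
genotype-pipeline replicates at b = 0.25, and the composition null is
required to converge to uniform (max deviation < 0.01 per dinucleotide
class) on 5 Mb of uniform-base sequence. These sizes were chosen to give
stable Monte-Carlo estimates at modest cost.

## Known limitations

- Forward-strand, rotation-only motif classes mean results are not
  comparable to miners that merge reverse complements without remapping.
- The composition null is order-0; repeat-prone genomes with strong
  dinucleotide stacking would need a Markov background, which is out of
  scope.
- Near-duplicate (not byte-identical) reads are not collapsed; no
  similarity threshold is assumed.
- The exact contingency construction behind some historical two-library
  chi-square statistics is not recoverable; this package documents its
  exposure-based construction instead and exposes both exposure choices.
- Richness inference treats alleles as exchangeable labels; no stepwise
  mutation model is fitted.
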