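# ssr-survey

A toolkit for mining microsatellite (simple sequence repeat, SSR) markers
from genomic sequence libraries and for analysing the allelic richness of
the resulting loci. It targets the marker-development workflow used for
non-model organisms: screen BAC-end and EST single-pass reads for perfect
tandem repeats, ask whether particular repeat motifs are over- or
under-represented relative to the base composition of the library, ask
whether repeats avoid open reading frames, and relate the number of
alleles seen in a genotyping panel to the repeat structure of each locus.

## What it computes

**Repeat detection.** An SSR locus is a maximal perfect tandem array of a
primitive unit of 2–6 bp with at least *m* complete units (default
*m* = 5). Motifs are identified up to cyclic rotation of the unit (the
phase of a repeat within a read is arbitrary), so `(GA)n` and `(AG)n` are
the same class; reverse complements are kept distinct because single-pass
reads are directional. There are 6 dinucleotide and 20 trinucleotide
rotation classes. Compound repeats (abutting arrays of different motifs)
are filtered, and loci without enough flanking sequence for primer design
are flagged as terminal.

**Composition nulls.** The expected motif mix of a library is estimated
from the library itself: every overlapping k-mer is counted, pooled by
rotation class and normalized. Observed per-class locus counts *O* are
tested against expected counts *E = p·n* with the chi-square goodness of
fit, X² = Σ (O−E)²/E on k−1 degrees of freedom (5 for dinucleotides, 19
for trinucleotides). ORF placement is tested the same way: each SSR is
classified inside / outside / bridging relative to six-frame ATG-to-stop
ORFs, and the inside fraction is compared with the fraction of library
bases covered by ORFs.

**Allelic richness.** Genotype screens are tables of categorical gel-band
labels per locus × individual. After removing loci that failed to
amplify, amplified in only one species, or carried a null allele, richness
*A* is the count of distinct alleles per locus. The toolkit computes
Spearman's ρ of *A* against the reference repeat number, Kruskal–Wallis
heterogeneity of *A* across motif classes / GC bins / ORF placement, and
Mann–Whitney comparisons of repeat counts between libraries.

**Synthetic data.** `ssr_survey.synthetic_data` generates read libraries
with SSR tracts and ORFs planted at known coordinates (flanks are redrawn
so they cannot extend a planted repeat) and genotype tables whose
allele-pool size grows as 1 + Poisson(exp(a + b·n)) with repeat number n —
so detector recovery, false-positive rates and the statistical power of
the whole pipeline are measurable against ground truth.

## Worked example

```sh
$ ssr-survey simulate --out-prefix demo/sim --n-reads 80 --seed 5
80 reads, 73 planted SSRs, 74 detected loci, genotypes for 74 loci

$ ssr-survey scan --fasta demo/sim.fa --library-label SIM \
    --calls demo/calls.tsv --out demo/calls.gff3
74 SSR loci in 80 reads (56082 bases, 0 duplicate reads removed)

$ ssr-survey richness --genotypes demo/sim.genotypes.tsv \
    --screen-log demo/sim.screen.tsv
{
  "screening": {
    "n_screened": 74,
    "n_retained": 74,
    "removed": { "failed_all": 0, "single_species": 0, "null_allele": 0 }
  },
  "mean_richness": 3.1621621621621623,
  "spearman": { "rho": 0.587, "p": 3.85e-08, "n": 74 },
  "dinucleotide_motif_kruskal": { "H": 6.372, "p": 0.2716 }
}
```

All 73 planted repeats are recovered at exact coordinates (`scan` reports 74
loci: the planted 73 plus one chance background repeat), the mean
locus has about 3.2 alleles in a panel of 8
simulated individuals, and richness correlates positively with repeat
number (ρ ≈ 0.59) because the generator's slope parameter b is positive;
the Kruskal–Wallis test across dinucleotide motifs is null, as it should
be when the generator treats all motifs alike. Other subcommands:
`ssr-survey orf` (ORF scan + placement), `ssr-survey nulltest` (motif and
ORF goodness-of-fit), `ssr-survey survey` (two-library comparison).

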