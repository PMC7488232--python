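# Methods

## Sequence containers and coordinates

All user-visible coordinates are 1-based inclusive. Indels use the VCF
anchored-base convention (ref and alt share their first base). Genomes hold
uppercase A/C/G/T/N; any other character is converted to N on FASTA ingest
with a logged count. The two haplotypes are modeled as fixed sequences —
overlapping variants are a hard error, not a merge — because the pipeline
describes a species pair, not a population.

`apply_variants` returns both the alternate sequence of a window and a
coordinate map from reference to alternate positions; bases removed by a
deletion map to the last retained base, flagged. The map is what lets site
positions be compared across haplotypes.

## Restriction-site scanning

A site at position p means the window starting at p matches the enzyme's
IUPAC motif on the forward strand or the motif's reverse complement matches
there; a site is cuttable regardless of the strand the motif is written
for, so non-palindromic motifs (e.g. AciI CCGC) are matched both ways but
counted once per start position. N in the subject never matches any motif
character, so assembly gaps cannot inflate counts. Overlapping matches are
all reported.

Genome-wide statistics for RADseq planning: site count C, RAD marker yield
R = 2C (each site is sequenced from both flanks), and average fragment size
L̄ = round(G/C) for total genome length G — i.e. genome length divided by
site count, which makes C·L̄ ≈ G an internal-consistency law the tests
check. In-silico digestion places the cut at site start + cut offset,
defaulting to mid-site when the enzyme's offset is not specified; genotype
diagnostics depend only on fragment-size differences, so exact offsets are
not critical. The built-in catalog covers a 30-enzyme RADseq panel plus the
marker-design set (AciI, KpnI, MspI, StuI); user catalogs load from TSV.

## RFLP/CAPS marker design

For each variant/enzyme pair, windows of ±(motif length − 1) around the
variant's reference span are compared — the smallest radius at which every
affected site overlaps the window, so the search is complete. Reference
sites are mapped into alternate coordinates; a site whose mapped start no
longer matches is lost, an unmatched alternate site is gained. A variant
may create a site for one enzyme while destroying one for another; both
candidates are reported, with no precedence.

Amplicon design constraints (all configurable): length 200–600 bp; exactly
one site for the enzyme on the cut-bearing allele and none on the other;
no fragment shorter than the gel resolution (default 20 bp); and the three
per-genotype band patterns pairwise distinguishable, meaning one pattern
has a fragment with no counterpart within the gel resolution in the other.
The heterozygote pattern is the multiset union of the two homozygote
digests. Genotype calling matches an observed fragment multiset against the
three expected patterns with a per-fragment tolerance (sorted pairing,
which is optimal for interval matching on a line); zero or multiple matches
give `no_call`. Partial digestion and band intensity are not modeled, and
two same-length fragments are treated as two pattern entries even though a
real gel shows one band.

## Variant-consequence annotation

Region classification is per overlapping transcript, with multiplicity: a
variant can be exonic in one transcript and intronic or flanking in
another, so category counts can exceed the variant count. Splice extents
follow the common annotation-tool convention — acceptor/donor are the two
intronic bases abutting an exon boundary, the splice region covers intronic
bases 3–8 and exonic bases 1–3 from a boundary — both configurable, since
published "splicing region" counts rarely define the window. Upstream/
downstream flanks are 5 kb from the transcript span, strand-aware.
`intergenic` is the fallback, so every variant gets at least one
annotation.

Coding effects splice the CDS (reverse-complementing minus-strand
transcripts), apply the variant, and compare codons under the standard
genetic code: length-preserving SNPs are silent/missense/nonsense/
stop-lost/start-lost; indels are in-frame when the length change is a
multiple of 3, else frameshift. Transcripts with a CDS length not divisible
by 3 are skipped. The unit tests check every CDS position and every
alternative base against an independent whole-protein
translate-and-compare oracle, on both strands, plus a mirror-genome
symmetry property. The variant rate is covered length divided by variant
count, the convention behind "one variant per N bp" summaries.

## Synthetic genome pair

The reference is i.i.d. uniform A/C/G/T. Variant count is binomial with
one expected variant per 68 bp; types are 89.3% SNPs, 5.35% insertions and
5.35% deletions (the proportions of the interspecific variant catalog this
pipeline is designed for), indel lengths uniform on 1–8 bp. Variant loci
are assigned to disjoint slots so reference spans never overlap. Planted
RFLP variants write a concrete motif instance into the reference and then
choose a substitution verified to remove that site cleanly without
affecting any other panel enzyme; neutral variants are rejection-sampled to
be panel-silent, so the planted set is exactly the ground-truth answer key
for candidate discovery. Gene models are non-overlapping multi-exon
transcripts with in-frame CDS and UTR stubs. What the generator does not
emulate: realistic base composition, mutation-rate heterogeneity, linked
variation, or assembly gaps — so passing tests demonstrate algorithmic
correctness, not robustness to those properties of real assemblies.

## Backcross simulation

One mapped chromosome carries the markers; F1 carriers are heterozygous
everywhere with the causal dominant allele on the BW haplotype, exactly at
the causal marker. F1 gametes recombine under the Haldane map function
with no interference (interference is negligible at these marker
spacings); the PO parent always contributes PO, so N2 genotypes are BW/PO
or PO/PO, heterozygous with probability ½ per marker. Modifier loci are
unlinked and biallelic.

Spot size is lognormal with an additive shift on the log scale per PO
modifier allele beyond the all-BW background. The calibration targets are
the background summary statistics: all-BW modifiers → mean 77.6, sd
36.6 mm²; the F1 configuration (one PO allele per modifier) → 3.75,
1.56 mm². Log-mean and log-sd are interpolated linearly in the number of
PO alleles from these two anchors. "Resembles the F1 parent" is defined as
a spot size inside the central 95% of the F1 lognormal; under two
modifiers the resemblance fraction among spotted N2 concentrates near 25%
(heterozygous at both modifiers), which is what the modifier-count
inference consumes.

The deficit of affected animals is exposed as two config switches, because
phenotype data alone cannot distinguish them: `rescue_prob` (phenotypic
rescue of carriers homozygous PO at every modifier — with full rescue,
expected spotted ≈ ½·¾·N, i.e. ≈47 of 125) and `sn2_lethal_prob` (carrier
loss before phenotyping). Defaults are 0 (pure Mendelian segregation).
Note that under the rescue regime the resemblance fraction among spotted
animals rises toward ⅓ by construction, since the rescued class is exactly
the all-PO-modifier quarter — an ascertainment effect of the rescue
mechanism, not an inference failure; modifier-count recovery is therefore
validated with rescue off. The carrier-by-carrier intercross generator
flags homozygous carriers lethal (a quarter of embryos) when the lethality
switch is on.

## Statistics layer

χ² goodness-of-fit uses the reporting convention of the genetics
literature this pipeline targets: expected counts rounded half-up to
integers, last class by complement (so expectations sum exactly to N), no
continuity correction, df = classes − 1; the unrounded statistic is also
carried. For a 1:1 test with every observation in one class the statistic
equals N exactly when N is even (or always, unrounded); odd N rounds to
⌈N/2⌉/⌊N/2⌋. Expected counts of zero are an error; the exclusion test
falls back to unrounded expectations in the only degenerate case (N = 1).

Exclusion testing declares a marker excluded at ≥2 affected PO/PO animals
("multiple recombinants"); a single recombinant is arguably sufficient
genetically, so the threshold is configurable down to 1. Under the default
threshold, a marker 1 cM from the causal locus with 46 affected animals
stays linked with probability P(Bin(46, 0.0099) ≤ 1) ≈ 0.92; the tests
check this exact binomial prediction. Interval refinement takes the
longest run of markers heterozygous in all affected animals, bounded by
the nearest flanking markers with at least one recombinant, open-ended
where none exists.

Modifier-count inference tests the observed [resemble, not-resemble] split
against [2⁻ᵏ, 1 − 2⁻ᵏ] for each candidate k and retains those with
p ≥ α = 0.05. Welch's t is computed from summary statistics; degrees of
freedom by Welch–Satterthwaite, reported floored to an integer while the
two-sided p is computed at the unfloored value. Upper-tail p-values come
from the χ² and t distributions and are unit-tested against independent
closed forms (erfc for χ² at df 1, the regularized incomplete beta for t)
to 1e-10.

## Problem sizes

The analysis drivers use a 600 kb four-contig genome (≈8,800 variants, 12
planted RFLP variants, 24 genes) and single crosses of 125 N2 animals;
the simulation-based tests use 100–500 replicates of crosses up to 8,000
animals for the distributional checks. These sizes give per-check Monte
Carlo error well inside the asserted 3σ bands while keeping the whole
suite fast.

## Known limitations

No methylation sensitivity, star activity or two-enzyme ddRAD fragment
windows; no primer thermodynamics (primers are carried as opaque strings);
no dCAPS design; splice-variant effects on the protein are not computed
(splice categories are positional); no selenocysteine or readthrough; no
QTL interval mapping — the modifier analysis is a count-based
goodness-of-fit, not a scan.
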