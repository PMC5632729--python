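# Methods

This note records the models, parameter choices and numerical conventions
behind each analysis stage, what the synthetic-data generator does and does
not emulate, and the design decisions taken where more than one reasonable
convention exists.

## Coordinates and the data model

All coordinates are 0-based half-open. Plastomes are circular; a feature
interval whose end exceeds the genome length wraps the origin and is
interpreted modulo the length. GenBank's 1-based inclusive coordinates are
converted at the I/O boundary, and an origin-split `join(x..N,1..y)`
location is merged back into one modular segment. Ambiguity codes other
than N are mapped to N with a warning, because every downstream counter
assumes the closed alphabet {A,C,G,T,N}; N never matches anything,
including another N.

A feature is a pseudogene when the record carries a `/pseudo` qualifier;
optionally (`read_plastome(..., infer_pseudogenes=True)`) a CDS whose
length is not a multiple of 3 or that contains an internal stop is also
flagged. Unique-gene counts deduplicate by name, which makes IR-duplicated
genes and trans-spliced genes annotated in pieces (rps12) count once.

## Inverted-repeat detection

The IR pair is found by seed-and-extend: exact 31-mers shared between the
doubled sequence (circularity) and its reverse complement are grouped by
the anti-diagonal i + j of their paired endpoints — all seeds of one
inverted match share it — and each anti-diagonal is extended base by base
in both directions.

Two numerical choices matter here.

*Mismatch consumption.* A pure rate budget (consume a mismatch whenever
running identity stays above the bound) lets the boundary creep past the
true junction on a clean genome: after the junction, unrelated flanking
bases still match by chance one time in four, and a 26 kb IR leaves a
budget of ~26 mismatches unspent. Instead, a mismatch is consumed only
when the 20 bases beyond it match exactly; the probability that random
flanks satisfy this is 4^-20. On a mismatch-free IR the detected
boundaries therefore equal the true junctions exactly, while isolated
internal mismatches between near-identical IR copies are still absorbed.
The global identity bound (default ≥ 99.9%) is enforced afterwards by
trimming outermost mismatches.

*Labelling.* The shorter inter-IR segment is the SSC, the longer the LSC;
ties in candidate length break toward the smaller start coordinate. The
canonical linearization is LSC → IRb → SSC → IRa with LSC starting at 0.
SSC orientation is chosen so that ndhF lies on the SSC side nearer J_SB
(the conventional layout); with no ndh gene annotated, the orientation
with the lexicographically smaller SSC string is used, purely for
determinism.

## SSR census

A locus is a maximal perfect tandem run of a primitive 1–6 bp unit. The
unit-count minima default to 8 (mono), 5 (di) and 3 (tri- through
hexanucleotide), read inclusively (a GMATo-style "Min-length" is an
inclusive minimum); both thresholds and the strict-inequality reading are
configurable. A run reportable under several unit sizes is reported only
under its primitive unit; runs break at N; circular wrap-around runs are
counted once, anchored at their true start. Compound or interrupted
microsatellites are not merged — each perfect run is its own locus.
Context is coding only when the span lies entirely within exons of
functional genes (CDS/tRNA/rRNA; pseudogene remnants do not count),
non-coding when entirely outside, spanning otherwise. Reverse-complement
motifs are deliberately not merged in summaries (A- and T-runs count
separately).

## Dispersed-repeat census

A hit is a pair of copies ≥ 30 bp with hamming distance ≤ 3 and identity
≥ 90% (both enforced), in forward, palindromic (reverse-complement) or
reverse (reversed, uncomplemented) orientation. The reported set is
defined geometrically: on every (anti)diagonal, the maximal windows
containing at most 3 mismatches — extending either end would exceed the
budget or run off the sequence — are enumerated, trimmed so both boundary
columns match, and deduplicated. Trimming is what makes a planted exact
duplication surface at exactly its planted coordinates when its flanks are
dissimilar; without it every hit would drag chance-matching flank columns
along. Self-overlapping (tandem) pairs are excluded — they are SSR
territory — and, when a region partition is supplied, palindromic hits
whose copies reciprocally overlap IRb and IRa by ≥ 90% are dropped as the
quadripartite IR itself.

The production finder seeds on exact 12-mers (skipping seeds with internal
period ≤ 2, which would flood the diagonal set with homopolymer matches,
and capping per-k-mer occurrence lists at 500); a mismatched repeat whose
longest exact stretch falls below 12 bp can in principle escape seeding.
The brute-force all-diagonal enumerator in the test suite defines
correctness; the two agree exactly on kilobase-scale sequences.

## SV% divergence screen

Syntenic loci of a canonical plastome pair are protein-coding genes shared
and intact in both, intergenic spacers whose flanking gene names match,
and introns of shared multi-exon genes; IR-resident loci contribute one
copy (IRb), and non-coding loci shorter than 150 bp in either genome are
discarded. Alignment is global pairwise with affine gaps (match +1,
mismatch −1, open −4, extend −1; a deterministic replacement for a
multiple-aligner step, since only two sequences are ever compared). Coding
loci are aligned codon-aware by aligning translations (BLOSUM62) and
back-threading codons, so internal gaps are codon-sized and
frame-aligned; a coding locus with a broken frame is flagged and aligned
as nucleotide. Terminal gap columns are excluded before counting.

Counting rules: conserved = identical non-gap columns; substitution =
differing non-gap columns, including those adjacent to gaps; one InDel
event = one maximal run of gap columns regardless of length; columns
containing N are ignored for site counts and break gap runs like any other
non-gap column; a gap–gap column cannot occur in a pairwise alignment and
is asserted against. SV% is then

SV% = (substitutions + InDel events) / (conserved + substitutions + InDel events) × 100.

Hotspot ranking is restricted to non-coding loci (coding genes are
reported separately), descending by SV% with ties broken by name.
Statistics are Spearman rank correlations and two-sided Mann–Whitney
tests with raw p-values — no multiple-testing correction, matching the
screening (not confirmatory) character of the analysis.

## NG86 dN/dS

Synonymous site fractions are computed per codon — at each position, the
fraction of the three possible changes that preserve the amino acid, with
changes into stop codons counted as non-synonymous — and averaged over the
two sequences. Codon pairs differing at 2–3 positions are resolved by
averaging the synonymous/non-synonymous step counts over all minimal
mutational pathways, excluding pathways through stop codons (if every
pathway is blocked, all are used). Gapped or N-containing codons are
skipped, terminal stops removed, a codon with an internal stop in one
sequence is skipped with a warning, and internal stops in both flag the
locus as a pseudogene. Rates are Jukes–Cantor corrected; p ≥ 3/4 is
reported as saturated rather than extrapolated, and ω is undefined when
dS = 0. Counts (nd, sd, site totals) are additive, so the concatenated
estimate equals the count-sum over genes. The standard genetic code is the
default (the plastid code differs only in start-codon usage); the table id
is configurable. This codon-counting estimator is a deliberate,
documented substitute for maximum-likelihood pairwise estimation:
absolute rate values are expected to differ from ML outputs, and the
package's own validation is therefore calibration against simulations
with known ω, not reproduction of any particular published rate table.

## Junction typology and regression

The ndh inventory distinguishes intact, pseudogene and absent for each of
the 11 genes; retained ndh length sums annotated lengths of intact genes
and pseudogene remnants. Types: A = all 11 intact; B = all 11 absent;
C = anything in between (partial intact complement and/or remnants). The
alternative reading "B = zero intact genes even if remnants persist" is
selectable (`rule="zero_intact"`), since the verbal definitions in the
literature are ambiguous on that boundary.

The 5′-ycf1-to-J_SA distance is measured along ycf1's strand and is
positive when the junction lies downstream of the 5′ end, inside the gene
body. IR expansion/contraction is operationalized as the difference
between a plastome's distance and a type-A reference value (the genus
anchor). The shift-vs-retained-length relation is fitted by least squares
through the origin, with R² computed against the origin-constrained fit
(uncentered total sum of squares) and a seeded permutation p-value
(shuffling y against x, 999 permutations by default) in place of a
phylogenetically corrected correlation — the package analyses single
genomes, not trees, and says so rather than pretending otherwise.

## Synthetic plastome generator

The generator is first-class, tested code, and its defaults are the study
conditions: region lengths 83,035 (LSC) / 26,452 (IR) / 20,187 (SSC) bp,
AT fraction 0.64, a gene complement of ~60 plastid genes with realistic
names and lengths (several multi-exon genes supply introns), ycf1 spanning
the IRa/SSC junction with a 991 bp overhang into IRa, and ndhF adjacent
to J_SB. Genomes are assembled as LSC + IRb + SSC + revcomp(IRb); the IRb
tail is defined as the reverse complement of ycf1's 5′ region so the
overhang is self-consistent. Coding sequences are random sense codons
with ATG/TAA termini and no internal stops. All randomness flows from one
seed through purpose-tagged generators, so output is byte-identical across
runs and platforms, and the emitted GenBank records exercise the real
reader.

Three constructions exist to make ground-truth recovery exact rather than
merely probable, and are part of the generator's contract:

- *Junction guards.* One spacer base adjacent to each IR junction is set
  to mismatch its would-be pairing partner, because a chance match there
  (probability 1/4 per junction) would extend the detected IR past the
  planted boundary.
- *Element guards.* Planted SSRs get flanking bases that break the tandem
  period; planted repeat pairs get four mismatching flank columns per
  side, so maximality trimming lands exactly on the planted coordinates.
  Mismatch columns of planted repeats are placed so that every clean
  sub-window stays below the 30 bp census floor (which bounds mismatched
  planted repeats to < 60 bp); otherwise prefix/suffix windows of the
  planted pair would be legitimately reportable hits absent from the
  ledger.
- *SSR scrubbing.* AT-rich random sequence of plastome size contains
  threshold-passing chance microsatellites with near-certainty, so after
  assembly any unplanned run is broken by changing one base, chosen to
  break the period, avoid creating stops in CDS, mirror into the other IR
  copy, and — inside a planted repeat copy — apply as a paired edit that
  preserves the planted relationship.

Mutation model: a star genealogy with two independent descendants, so
expected pairwise divergence is the sum of the two branches. Each
descendant receives per-site Bernoulli substitutions (pairwise defaults:
0.02 in non-coding, 0.01 in coding sequence — the coding/non-coding
asymmetry emulates purifying selection and gives the severalfold
non-coding SV excess typical of congeneric plastome pairs) and Poisson
InDel events per locus (default 1.5 per non-coding locus pair; 0.2 per
CDS) with geometric lengths of mean 3 bp, coding indels forced to
multiples of 3 and kept inside single exons. Substitutions in the IR are
mirrored into the other copy (concerted evolution), which keeps each
descendant's IR internally exact; indels avoid the IR, planted elements
and guards, and never overlap each other, so every event is its own gap
run in the true alignment. Annotations and the region partition are
lifted through every indel. CDS substitutions that would create an
internal stop are re-drawn.

Scenario machinery: type B deletes all ndh genes and expands the IR into
the SSC by a configured amount (sequence adjacent to J_SA is duplicated
into both IR copies, exactly how real IR expansion behaves); type C
truncates/deletes ndh genes to a requested retained total and extends the
IR by slope × retained length (default slope 0.136, with retained targets
in multiples of 125 bp so the shift is integral and noiseless cohorts
recover the slope with R² = 1 exactly). Scenario A is a no-op and
reproduces the ancestor byte for byte.

The codon-pair simulator evolves two sequences from a common ancestor
under an acceptance filter — synonymous point mutations always accepted,
non-synonymous with probability ω, stops rejected — giving a known
selection strength for estimator calibration.

What the generator does *not* emulate: codon-usage and context-dependent
mutation biases, rate heterogeneity across sites, gene conversion beyond
perfect IR concerting, rearrangements/inversions, real intergenic
sequence composition, and ndhB's real residence in the IR (all 11 ndh
genes are placed in the SSC to keep the loss scenarios single-copy).
Passing the recovery tests therefore demonstrates correctness of the
measurement machinery under the stated model, not robustness to every
feature of real plastome data — in particular, alignment-dependent choices
(gap placement near tandem context) can differ from other aligners on
real, more repetitive sequence.

## Problem sizes

Property sweeps and recovery cohorts run on a compact ~17 kb genome with
the same architecture (the recovery properties are scale-free), 100-genome
cohorts for planted-recovery checks, 200 replicates per setting for
Monte-Carlo SV recovery, and 1,000 codons for ω calibration; paper-scale
[~156 kb] genomes are used where absolute architecture numbers matter
(structure metrics, the divergence screen, the junction distance). These
sizes are the package's choices for routine validation; all of them are
configuration, not constants.

## Known limitations

- The repeat finder's seeding can miss heavily mismatched repeats with no
  12 bp exact stretch; the contract (and the oracle) is defined on
  maximal windows, so lowering `k` trades speed for completeness.
- Alignment-derived counts (substitutions next to gaps, InDel event
  boundaries) inherit the aligner's gap-placement conventions; other
  tools can legitimately count a locus one event differently.
- The Mann–Whitney and Spearman outputs are descriptive; no correction
  for multiple loci is applied.
- `detect_inverted_repeat` assumes one dominant inverted pair; genomes
  with degenerate or absent IRs are reported as IR-lacking rather than
  searched for secondary structure.
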