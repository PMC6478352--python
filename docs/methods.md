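# Methods

This note documents the models, rules and numerical choices behind
`hatseq`, and what the synthetic-data generator does and does not emulate.

## Assay model

The pipeline assumes amplicon libraries primed from the L1Hs-diagnostic
"AC" motif near the element's 3' end, with 2/4/6 random bases added ahead
of the primer (phase shifting, to de-homogenise the flow-cell image).
Merged read pairs therefore span the full 3' junction and, stored
flank-first, have the structure

```
[3' genomic flank][poly-T][reverse-complemented L1Hs 3' end][phase bases]
```

(the poly-A tail reads as poly-T on this strand). One sequenced molecule
corresponds to one sonication fragment; all reads from one cell carrying an
insertion share one fragmentation breakpoint, so the number of unique read
start positions at a locus ("signals") estimates the number of carrier
cells sampled, and PCR duplicates of a signal corroborate that it is not a
one-off polymerase artifact. These two observations carry the whole somatic
calling logic.

## Read-level rules

* **Primer/phase.** The 28-mer primer must match exactly at offset 2, 4 or
  6. Exact matching is the conservative reading of "retained and trimmed";
  the tolerance is configurable.
* **L1 identity.** The post-primer remainder is compared end-anchored and
  ungapped to the consensus 3' end; > 4 mismatches fail (≥ 95% identity on
  a 100-mer). No gap model is defined for this step, so an indel simply
  degrades downstream positions into mismatches.
* **Diagnostic G.** The consensus position of the subfamily-diagnostic G is
  a property of the bundled consensus (`diagnostic_offset`); reads whose L1
  segment does not reach it fail as `motif_not_covered`, separating
  "wrong subfamily" from "segment too short".
* **Poly-T trimming.** The tract needs an 8-T seed; it is then extended
  through isolated non-T bases while the trailing 4-base window stays
  ≥ 75% T, and snapped back so it starts and ends on a T. Real tails carry
  sporadic substitutions, so seed-only trimming would truncate them.
* **Poly-A length.** From the first ATTAT anchor scanning outward from the
  L1 junction (the known L1-segment offset is used when available), the
  scan walks toward the contig start scoring +1 per T and −2 per non-T.
  Scanning stops at the first negative running score and the reported
  length is the furthest T reached. This X-drop-style rule reproduces pure
  run lengths exactly, tolerates isolated mismatches inside long tails
  (T T T A T T T T → 8), and reports 0 when the base adjacent to the
  anchor is not a T. A "furthest nonnegative position" rule without the
  end-on-T condition would over-extend through a trailing mismatch; the
  brute-force oracle in the tests enumerates every prefix under the chosen
  definition.

## Alignment-level filters

* **Improper alignment:** flank aligned < 30 bp or > 3 mismatches.
* **Poly-A chimera:** the best on-contig placements of the retrotransposon
  and genomic segments overlap > 10 bp with A ≥ 50%, or 6–10 bp with
  A < 50% (A measured on the retrotransposon-sense strand, i.e. the T
  fraction of the stored contig). Chimeric molecules bridge inside the
  low-complexity tail, which is exactly where the two placements collide.
* **Misalignment:** two independent placements (two aligners in the
  original design; the simulator supplies both) must agree in chromosome,
  strand and start within the global 1-bp shift tolerance. A missing
  secondary placement passes, flagged `unverified`.
* **Local SV:** the full contig is aligned (infix edit distance, both
  orientations) into a window spanning the flank alignment plus 2 kb
  beyond the junction. A match with edit distance ≤ 8% of the contig
  length means the read is explained by nearby reference sequence (e.g. a
  reference L1 with its genomic A-tail) rather than a novel insertion. The
  8% budget is a package choice — no identity threshold is published for
  this step — and is configurable; genuine junction contigs carry ≥ 100 bp
  of sequence absent from the window, far beyond any plausible budget.

## Peaks and classification

Peaks are triggered wherever per-base depth exceeds 1, extended over the
containing depth ≥ 1 region, and merged across end-exclusive gaps ≤ 100 bp;
non-reference calling is strand-specific because the 3' flank preserves
insertion orientation. RPM uses the library's uniquely mapped L1Hs-derived
read count as denominator (the only reads loaded). Classification routes
each peak to exactly one category; the per-filter ledger plus survivors
always sums to the input count, which the tests assert. KR criteria use
strict inequalities (RPM > 40, overlap > 200 bp) and KNR/UNK inclusive ones
(≥), following the published wording exactly. The somatic stage merges
start positions differing by 1 bp (the higher-depth start represents the
pair; ties take the smaller coordinate), requires at least one
duplicate-supported signal, and rejects loci carrying candidates in two or
more individuals (joined at the same ±100 bp strand-specific tolerance as
peak joining). Clonal somatic calls need ≥ 2 duplicate-supported merged
signals. The unassembled-read mode applies the same chain minus the two
junction-dependent filters (poly-A chimera, local SV), requires ≥ 3
signals, and marks every call `low_confidence`.

## TPRT hallmarks

Distances are measured from the called junction base to the start of the
nearest of seven endonuclease motifs on the strand-adjusted ±2 kb window,
negative upstream; ties between equidistant up/downstream motifs resolve
downstream. Motif start (not the T/A cleavage phosphate) is the reference
point — the choice shifts all distances by a constant ≤ 5 bp and cancels in
the case/control comparison. Control positions are uniform over the
genome, dropping windows with > 20% of bases below mappability 0.25
(per-base thresholding, as stated) or > 90% N. |distance| distributions
are compared with the two-sided rank-sum test: exact null for small
tie-free samples, normal approximation with tie correction otherwise, and
p = 1 when all values tie. Poly-A histograms use 1-bp bins (10 bp for the
EN-distance histograms); bimodality is flagged when two non-adjacent bins
both reach 90% of the tallest.

## Quantification

Within one library every template is amplified under the same conditions,
so read-count ratios estimate copy-number ratios. Somatic content is
reads(somatic)/reads(KNR); KNRs are used because they traverse the same
non-reference calling path as somatic insertions. The per-cell rate
multiplies this ratio by the individual's KNR insertion count, taken as the
per-cell copy number because KNRs are predominantly heterozygous (no
homozygosity correction; the maximum KNR call count across an individual's
samples is used). Group summaries report mean, S.E.M. and a Student-t 95%
CI with n−1 degrees of freedom (a normal-approximation CI does not
reproduce the benchmark column summaries); brain vs non-brain uses a
two-sided paired t-test on per-individual differences, with no
multiple-testing correction anywhere (raw p-values are reported).

The spike-in model: an insertion diluted to λ copies among the ~3,000-cell
input is sampled Poisson(λ), so E[detectable sites] = N(1 − e^(−λ)) and
sensitivity is identified/expected. The detection probability of a
single-copy site further thins by the probability that its one signal
carries a PCR duplicate; with the simulator's geometric duplicate model
(mean m) that is 1 − 1/m, giving the closed form 1 − e^(−λ(1−1/m)) used in
the end-to-end recovery test.

## Enrichment statistics

Gene annotation uses the canonical transcript (longest transcript among
those with the longest CDS); positions are classed 5'UTR/CDS/3'UTR/intron/
intergenic with UTR sides resolved by transcript strand, and overlapping
genes tie-break toward the most exonic assignment (CDS > UTR > intron) —
stable and biologically conservative. Expected region fractions come from
the exact base-pair shares of the supplied annotation, never from hardcoded
constants. Binomial tests are exact and two-sided (summing outcome
probabilities ≤ the observed one); Fisher's test reports the probability-
mass two-sided p with the conditional maximum-likelihood odds ratio and its
exact 95% CI. Sample clustering uses Jaccard distance over polymorphic
(KNR + UNK) loci with average linkage; KR loci are present in essentially
every sample and carry no identity information, so they are down-weighted
to zero by default.

## Synthetic data: what it emulates, and what it does not

The generator plants a 400-bp synthetic L1Hs 3'-end consensus (primer
28-mer, diagnostic G at a declared offset, ATAAT terminus) as reference
repeats — followed by a 20-bp genomic A-tail, so reference-derived
artifacts are constructible — plus mutated older-subfamily copies and toy
gene models. Libraries draw, per heterozygous germline site, a Poisson
number of signals (mean 60; twice that for homozygous), one uniform
30–150 bp fragment length per signal, and a geometric duplicate count
(mean 4): one signal then carries a duplicate with probability 0.75.
Site-level poly-A tails are 10 + Binomial(30, ½) bp, mode 25. Somatic
sites receive their sampled cell count directly. Artifact constructors
straddle the chimera-filter boundaries (overlaps 5–12 bp, A% 40–60%),
misplace the secondary alignment, or copy reference sequence at an
unplanted reference-L1 junction.

Not emulated: base-quality errors and quality trimming, alignment
ambiguity in repetitive sequence, real hg19 coordinates and repeat
density, inter-locus amplification bias, and 3' transductions. Passing
tests therefore demonstrate that the decision logic is implemented
correctly and behaves as designed under the assay's sampling model — not
that the filters' published thresholds are optimal for real data.

## Problem sizes and determinism

Default test genomes are two 150-kb contigs with six L1Hs and two older
copies; cohort simulations use five individuals × two tissues
(~2,500–3,500 contigs per library). The end-to-end sensitivity check runs
100 seeded dilution replicates of 16 single-copy sites (λ = 0.3) and
compares the detected fraction to the thinned-Poisson expectation within
three Monte-Carlo standard errors; the acceptance script runs 60
replicates of the same design. All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give byte-identical
outputs, which the tests assert.

## Known limitations

* KR insertion coordinates are reported as peak boundaries rather than
  base-precise junctions (the reference copy already fixes the locus).
* The KNR-count-as-copy-number assumption ignores homozygous KNRs, biasing
  per-cell rates slightly upward for individuals with many homozygous
  polymorphisms.
* The local-SV edit-distance budget trades sensitivity to small local
  rearrangements against robustness to sequencing noise; both extremes are
  reachable through configuration but only the default is exercised by the
  test suite.
* `classify_unassembled` consumes pre-tabulated read-pair placements; it
  does not attempt its own pairing of orphan mates.
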