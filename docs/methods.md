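# Methods

## Coordinate model

All positions are 1-based inclusive; position 1 is the TSS (first base of
the spliced transcript). Intron 1 never appears in sequences: it exists
only as `intron1_offset`, the last 5′UTR position of the before-Intron-1
section, so the sections are `before = [1, intron1_offset]` and
`after = [intron1_offset + 1, utr5_len]`. Intronless transcripts carry a
single `whole` section instead of erroring out of section-wise operations.
When annotated, the main-ORF start equals `utr5_len + 1` and must sit on an
ATG. The accepted alphabet is A/C/G/T/N after upper-casing and U→T
normalization; N never matches a codon and is excluded from GC counts
(but counts against repetition-subset fractions).

## Conservation scoring

Identity and occupancy are treated as two independent per-column criteria:
identity = modal non-gap base count over the non-gap count, occupancy =
non-gap count over the number of rows. The identity denominator excludes
gaps deliberately — occupancy already penalizes gappy columns, and folding
gaps into identity would conflate the two signals. Both thresholds are
strict inequalities ("more than"), which is what makes the 84 % occupancy
rule on 59 sequences resolve to a minimum of 50. Modal-count ties keep the
tied count for identity; the reported modal base is alphabetically first
and is display-only. All-gap columns score 0/0 and can never be hot spots.
Raising either threshold can only remove hot-spot columns (tested as a
property). Hot-spot runs are maximal consecutive-column intervals;
projection onto a transcript maps each run's non-gap columns through the
row's gap structure, which always yields a contiguous sequence interval.

## uORF geometry and contexts

ORF coordinates are stop-inclusive: `len_nt = stop_end − start + 1` and a
stopped ORF codes `len_nt/3 − 1` residues. This convention is forced by
the bundled ABCA1 reference table (111 nt ↔ 36 aa). The gap to the main
ORF is `morf_start − stop_end − 1`; zero means the stop abuts the sATG and
negative values mean the uORF runs past it (overlapping uORF). ORFs
without an in-frame stop before the sequence end are flagged open and end
at the last full-codon base; they are excluded from summary tables by
default. The codon census scans with step 1 (overlapping occurrences, any
frame); a codon belongs to the section containing its first base, and
codons whose third base would cross the 5′UTR/CDS boundary are excluded.
Alternate start codons (GTG/CTG/TTG/ACG) are available for the census and,
via configuration, for ORF calling, but uORF summaries default to ATG only.

Start-codon context windows are 9 nt + ATG + 9 nt, clipped at sequence
ends; −3 or +4 falling outside the sequence yields class *undetermined*.
Classification: *strong* = purine at −3 and G at +4, *weak* = neither,
*adequate* = exactly one. `codon_at_offset` reads codons in sATG-relative
coordinates (−1 is the base just 5′ of the sATG A), so the conserved
in-frame uTGA test is simply "codon at −9..−7 equals TGA".

The pipeline's per-transcript summary reports the 5′-most uORF that starts
in the after-Intron-1 section — the conserved uATG this analysis targets
sits just past the splice junction — falling back to the 5′-most uORF
overall for intronless records. All called uORFs remain in the full output.

## Composition and segmentation

GC is computed as `Count(G+C)/Count(A+T+G+C) × 100` with N removed from
both sides; reports round to one decimal, internal values keep full
precision. Section profiles flag `after_dominant` when the after section
leads by more than 8 percentage points and `before_dominant` when the
before section leads by more than 14.

Base-repetition-rich subregions are a quantitative re-casting of a
qualitative visual notion, and the defaults are this package's own:
windows of 30 nt (step 1) whose subset fraction reaches 0.8 are unioned;
gaps of at most 5 nt are bridged only when the merged stretch still meets
the fraction threshold (so the reported fraction can never fall below it);
boundaries are then re-localized as the maximal-scoring subsegment of the
candidate, scoring member bases `1 − fraction_min` and non-members
`−fraction_min`, with ties broken 5′-most; segments shorter than 20 nt are
dropped. Overlapping candidates of different labels are resolved by higher
fraction, then smaller subset, then 5′-most start — so a 2-base label beats
its 3-base superset at equal enrichment. Boundary localization against a
uniform background (where a 2-base subset still covers half the positions)
is inherently stochastic: on planted 40-nt blocks of fraction 0.9 the
recovered boundaries fall within ±5 nt in roughly nine out of ten random
backgrounds, which the test suite asserts as a rate over a fixed seed list
alongside a deterministic single-seed example. Note that a planted block
whose impurities belong to a superset label (e.g. C impurities in a G/A
block) is a *perfect* G/C/A region and will legitimately be reported under
the superset label.

## Structures

The structure module analyzes supplied dot-bracket strings; folding free
energies are intentionally not computed (thermodynamic prediction stays
with external folders, and reimplementing an energy model is out of
proportion to its role here). The Vienna dialect accepted is: optional
FASTA-style header, sequence line, structure line, with a trailing
parenthesized energy annotation tolerated and ignored. A hairpin loop is a
base pair enclosing only unpaired bases, at least one. Section assignment
uses the midpoint `⌊(i+j)/2⌋` of the closing pair; a loop whose closing
pair straddles the boundary is labelled spanning but counts with its
midpoint's section, and a midpoint exactly on the boundary counts as
before. These are this module's own tie-break decisions. The included
`maxpair_fold` is a Nussinov base-pair maximizer over AU/GC/GU pairs with a
minimum hairpin loop of 3 and a deterministic traceback (pair the 5′ base
with its smallest admissible partner before leaving it unpaired); it exists
so structure handling can be tested without external tools and is not a
thermodynamic prediction.

## Variant overlap and length statistics

Variant input is a list of distinct transcript positions; membership is
closed-interval containment against merged hot-spot intervals, and the
percentage is rounded to the nearest integer, half away from zero
(39/161 → 24). Genome-to-transcript liftover is upstream of this package.
Group comparisons use two-sided Mann–Whitney U: the exact distribution when
the smaller group has ≤ 8 observations and no ties, otherwise the normal
approximation with tie correction; Bonferroni multiplies by the number of
pairs actually tested and caps at 1. Groups with fewer than two
observations are skipped with a log note.

## Synthetic families

The generator emits the alignment directly from a consensus instead of
running an aligner, so ground truth is exact by construction and no test
depends on external alignment software. Its default family mirrors the
study conditions the analysis assumes: 59 transcripts in nine
vertebrate-style groups (17 primates, 16 rodents, 7 other placentals, 2
marsupials, platypus, 4 reptiles/birds, coelacanth, 11 ray-finned-fish
transcripts in two paralog groups); a 15-nt conserved block at the start of
the after section (`CAGTTAATGACCAGC`, one out-of-frame uATG, a uTAA
overlapping it); a 90-nt planted uORF starting at that uATG with
group-banded geometry (primates overlap the mORF by 22 nt; rodents gap 1;
other placentals and platypus 7; reptiles/birds 16; marsupials 29;
coelacanth 22; ray-finned fishes 4 — gaps that are multiples of 3 are
excluded because they would put the uATG in frame with the sATG); GC
targets of 59 % (before) and 67 % (after); background substitution 0.35,
block/uORF substitution 0.02, deletion 0.02. Because the after-section
length is an arithmetic consequence of the uORF geometry once the block is
anchored at the junction, `FamilySpec.validate` enforces
`after_len = block_offset + uATG offset + uORF len + gap` per group and
rejects inconsistent specifications.

Design choices that make parameter recovery testable:

* Substitutions *resample* from the section's base distribution rather
  than forcing a different base, so composition is stationary and a
  substitution may be silent.
* Consensus stretches are emitted with composition matched to the GC
  target exactly (rounded counts, shuffled), and the filler between the
  uORF stop and the sATG is composition-solved to offset the fixed
  block/uORF content; pooled section GC therefore recovers the target
  within ±2 pp for sections of ≥ 300 nt. Shorter after sections are
  dominated by the fixed block and make no such claim.
* Deletions and background-rate substitutions never touch the conserved
  block/uORF region, whose divergence is governed solely by
  `block_sub_rate`; planted hot-spot columns therefore keep full occupancy,
  and with `block_sub_rate = 0` the uORF caller returns the planted
  coordinates exactly for every record.
* Before-section length variation is modelled as 5′ truncation of a shared
  consensus (TSS drift), which left-pads alignment rows with gaps.

What the generator does **not** model: tree-aware evolution (species are
i.i.d. around the consensus within groups), insertions (only deletions),
transition/transversion bias, and depletion of background uATGs. Passing
recovery tests therefore show correctness of the measurement machinery on
data with the assumed structure, not performance on real alignments, whose
gap patterns and phylogenetic correlation are richer.

## Problem sizes and determinism

All randomness flows through one `numpy` generator seeded from the spec;
the same spec yields byte-identical sequences, alignments and truth JSON,
and the pipeline's combined report is byte-identical across reruns on the
same inputs (timestamps live only in the run log). The test suite runs the
Monte-Carlo checks at deliberately modest sizes — 200 seeded 20-species
families for hot-spot recovery, 1000 random ≤ 60-nt sequences for the ORF
oracle, structures ≤ 40 nt and foldings ≤ 12 nt for the exhaustive
structure oracles, 1000 null sequences for the segmentation false-positive
rate — sizes at which the brute-force oracles are exact and the whole
suite completes in well under a minute.

## Known limitations

* The hot-spot caller scores whichever single alignment it is given; it
  does not compare alternative aligners, so conserved-column counts are
  conditional on alignment quality.
* Segmentation boundaries near weakly contrasting backgrounds are
  stochastic (see above); labels of enriched regions with superset-member
  impurities resolve to the superset.
* Variant counting treats positions, not variant records; multi-allelic
  sites count once.
* Open-ended ORFs are reported but excluded from summaries; deciding their
  biological status is left to the user.
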