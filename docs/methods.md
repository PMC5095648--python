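# Methods

This note documents the models, conventions and numerical choices behind
`risprofile`, in the spirit of a methods section: what each stage assumes,
which knobs matter, and what the synthetic data does and does not emulate.

## Coordinates and distances

All coordinates are 0-based, half-open `[start, end)` (BED convention);
1-based inputs (SAM `POS`) are converted at the parser boundary. An
integration site is a single junction base: the first genomic base adjacent
to the vector LTR, which on minus-strand placements is the
highest-coordinate matched base. The convention is applied identically to
observed and random sites, so every distance comparison is unaffected by
the choice.

Distance from a point to an interval is 0 inside, otherwise the number of
base steps to the nearest contained base (`start − p` to the left edge,
`p − (end − 1)` past the right edge). TSS distance is unsigned; upstream
and downstream are not distinguished because the summary tables and
histograms report unsigned proximity only. Two wordings coexist
deliberately: "within X kb" (peak proximity, hotspot membership) is
inclusive (`≤`), "< X kb" (TSS, oncogene, centromere table columns) is
strict. Nearest-feature ties return all co-nearest features ordered by
(start, name); callers needing one take the first.

## Read preprocessing

Truncation removes the 3rd low-quality base (Phred Q < 27, i.e. error
probability ≥ 0.002) and everything 3′ of it. The alternative reading —
keep the triggering base — differs by one base and is available as
`keep_trigger=True`. Truncation is idempotent and its output never
contains 3 or more low-quality bases.

Pair merging is a deterministic best-overlap scorer (matches minus
mismatches, ties to the longer overlap, mismatch rate capped at 10 % by
default, minimum overlap 10 bp) with quality-weighted consensus: the
higher-Q base wins and keeps its quality, quality ties keep the forward
base. A maximum-likelihood merge in the style of dedicated pair mergers is
intentionally not reimplemented — merging is upstream plumbing here, and
pre-merged FASTQ is accepted in its place.

`naive_locate` is a seed-and-verify matcher (three exact seeds, Hamming
verification with ≤ 2 mismatches by default, score = matching bases, both
strands) intended for megabase-scale synthetic references in end-to-end
tests. It is not a genome aligner and no gapped alignment is attempted;
production alignments enter as scored records (TSV or SAM with `AS` tags).

## Site calling and the ambiguity rule

A read is ambiguous when `second > 0.95 × best` (strict), relaxed to
`0.90` when `best < 100`; "< 100" is read as applying to the best score,
since the rule modulates confidence in the top placement. The comparison
is evaluated by integer cross-multiplication (`100·second > 95·best`)
rather than floating-point multiplication: 0.95 has no exact binary
representation, and the boundary case (200, 190) — exactly 95 % — must be
classified "unique" by the strict inequality, not by rounding noise.
Exactly tied top scores are ambiguous (ratio 1). Duplicate junctions
collapse by exact (chrom, position, strand); no positional tolerance is
applied because junction PCR recovers exact coordinates. The collapsed
ambiguity flag is a majority vote, ties counting ambiguous.

Ambiguous sites are excluded from every downstream analysis except repeat
and centromere proximity, where repeat-placed reads are the object of
study; summary denominators record this split explicitly.

## Annotation

Peak sets are sorted by strength and cut into 10 equal deciles, bin 1
weakest, bin 10 strongest. When the count is not divisible by 10 the extra
peaks go to the *low* bins, keeping the strongest bin conservative and
never inflated; strength ties at boundaries break by genomic order. The
headline "near strong peaks" flags use the strongest bin only
(configurable to any bin subset); per-bin distances are always retained.
Whether peak "strength" is the score column or the signalValue of a
narrowPeak file is configurable (score column by default).

In-gene membership is containment in any transcript (no merging of
isoforms); repeat membership is containment of the junction base, with
overlapping repeat intervals resolved by a fixed priority (Satellite,
LINE, SINE, LTR, DNA, Other). Repeat classes outside the five named ones
map to Other and are reported but excluded from the five-class table.

Per-chromosome feature queries are vectorized: features sorted by start
with a running maximum of interval ends give the exact nearest distance by
binary search, identical to an exhaustive scan (the test suite verifies
this equivalence directly).

## Hotspots

A hotspot is a window of fixed width (5 or 50 kb) holding ≥ 3 sites.
Candidate windows are anchored at site positions with an inclusive right
edge. The greedy scan walks sorted sites, opens a window at each site not
already consumed by an emitted hotspot, and emits when the window holds
the minimum count; sites of sub-threshold windows remain available as
later anchors. Under site-anchoring this greedy provably maximizes the
number of disjoint qualifying windows (earliest feasible anchor never
hurts, because any later anchor blocks at least as much of the suffix),
and an independent dynamic program over anchor choices
(`method="exhaustive"`) recomputes the same count — the suite checks
equality on hundreds of random fixtures and validates the DP itself
against full subset enumeration at tiny n. Hotspots never span
chromosomes; strand is ignored.

Vectors with different site yields are compared on non-overlapping,
seeded-shuffle subsets of identical size (e.g. 320 or 511 sites, at least
3 subsets, leftovers unused); counts are reported as mean ± SEM (sample
SD / √n over subsets).

## Enrichment and the random control

The control (a uniform random site set, classically 10,000 sites, strand
uniform, sampled with replacement over the unmasked genome) supplies the
expected category proportions; the test set's counts are the observations
of a χ² goodness-of-fit with df = k − 1. The GOF conditions on the
expected proportions being known: it is well calibrated when the control
is exact or much larger than the test set, which is why the calibration
experiment tests uniform draws against exact genome fractions and why the
random control is an order of magnitude larger than typical test sets.
Comparing two equally small samples this way would roughly double the
statistic under the null and is not what the test is for. Significance is
starred at 0.05 / 0.01 / 0.001 per comparison; no multiple-testing
correction is applied by default (a Bonferroni adjustment would be a
one-line wrapper over the reported p-values, and per-comparison stars are
the convention being mirrored).

## Clonality

Capture frequency is read-count based: reads per unique site over total
reads of retained (unambiguous) sites. Fragment-length ("sonic")
abundance correction is out of scope. The ≥ 1 % reporting threshold is
inclusive. Because ambiguous sites are dropped from the denominator,
clone counts of repeat-targeted vectors may be slightly underrepresented;
the report carries the excluded-site count.

## Synthetic data: what it emulates, and what it does not

The generator builds, deterministically under a seed: a 3 × 10 Mb genome
(coordinate-level by default; with sequence for read-level runs), 300
genes of 5–60 kb placed outside a ±600 kb pericentromeric zone, 30 of
them designated proto-oncogenes; 200 CpG islands (70 % within 2 kb of a
TSS); interspersed LINE/SINE/LTR/DNA repeats; 20 satellite blocks of
25 kb per chromosome tiled outward from a 100 kb centromere (satellite
coverage ≈ 5 % of the genome); and 200 peaks with log-normal strengths,
boosted ×8 in the pericentromeric zone so the strongest decile is a
gene-poor, centromere-proximal set — the defining property of strong
heterochromatin peaks, and the structural coupling that makes satellite
enrichment, centromere proximity and strong-peak proximity co-occur.

Site sets are drawn from a three-component mixture: `pi_peak` of sites
within `d_peak` (default 10 kb, hence always within the 50 kb proximity
rule) of a random strongest-bin peak, `pi_sat` uniform inside satellite
blocks, the rest uniform over the genome with an optional gene-body
weight. The presets are the study conditions used throughout tests and
the acceptance script: retargeted = (0.35, 0.30), control = (0, 0) with a
mild 1.5× gene preference emulating an unmodified vector. These weights
are simulator parameters chosen once to reproduce the *direction and
rough scale* of a heterochromatin-retargeting experiment; they are not
estimates of any real data set.

Junction reads are simulated from a 150 bp template starting at the
junction base and running 3′ on the site's strand; the pair is the
template head and reverse-complemented tail (100 bp each, 50 bp overlap),
with optional substitution errors and an injectable low-quality tail.
Exact 2 kb duplications ("decoys") copied between chromosomes produce
tied alignment scores and exercise the ambiguity rule end to end.

Not modelled: realistic human sequence composition, PCR/GC bias,
fragment-length effects, chimeric reads, gapped alignment, isoform
structure, or expression-weighted gene activity. Passing tests therefore
demonstrate the correctness of the *rules and statistics* on data whose
ground truth is known, not the biological accuracy of any particular
percentage on real libraries.

## Problem sizes and determinism

Default experiment sizes — 1,000-site vector sets against a 10,000-site
random control, 200 read pairs on a 10 Mb sequence-level genome, 200
calibration replicates — were chosen so the full suite and the acceptance
script each complete in well under a minute on one CPU while keeping
binomial noise far below the effect sizes under test. Every stochastic
component takes an explicit seed or `numpy` Generator; identical seeds
give byte-identical outputs, including the TSVs written by `run_profile`.
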