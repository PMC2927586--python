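# Methods

## Coordinates and templates

All internal coordinates are 0-based half-open on the + strand axis;
GFF3's 1-based inclusive convention is converted at the parsing boundary
and never leaks inward. The design template for a gene spans
`[ATG − 3000, ATG + 150)` for a + strand gene and the mirror interval,
reverse complemented, for a − strand gene, so a template always reads
promoter → ATG → coding and the ATG sits at offset `upstream_achieved`
(3000 when the full span exists). Intervals running past a contig end
are clipped rather than rejected — how genes closer than 3 kb to a
contig end (or to an upstream neighbour) were handled in the original
workflow is not recoverable, so clipping plus an explicit
`short_upstream` flag is this package's choice. A template whose
achieved upstream span is below 2150 bp cannot host any product in the
2150–2650 bp range and is marked undesignable before primer picking.
Annotated translation starts are trusted but verified (a non-ATG start
flags the model; nothing is silently dropped); unannotated candidates
are anchored by exact match of the CDS 5′ prefix (default 30 nt, both
strands, all contigs), with the anchor length doubled on ambiguity — a
deterministic desk-scale stand-in for a spliced aligner, valid while
the first exon is at least as long as the anchor.

## Melting temperature

`compute_tm` implements the SantaLucia (1998) unified nearest-neighbor
ΔH/ΔS table with terminal initiation terms, the symmetry entropy
correction for self-complementary oligos (with duplex concentration
`CT` rather than `CT/4`), and the Owczarzy (2004) reciprocal-temperature
monovalent salt correction
`1/Tm(Na⁺) = 1/Tm(1 M) + (4.29·f_GC − 3.95)·10⁻⁵·ln[Na⁺] + 9.40·10⁻⁶·ln²[Na⁺]`.
Default conditions are 50 mM monovalent, no divalent, 50 nM oligo;
divalent cations, when supplied, are folded into a sodium equivalent
(von Ahsen 2001). The implementation is cross-checked in the test suite
against Biopython's independent `Tm_NN` under the identical convention.

## Pair enumeration and ranking

Hard constraints (placement, product size, target containment, length,
GC, Tm window, homopolymer ≤ 5, no N) are non-negotiable; the penalty
`w_tm·|Tm − 60| + w_len·|len − 20|` per primer plus `w_diff·|Tm_L − Tm_R|`
(all weights 1.0, configurable) only orders feasible pairs. Ties break
lexicographically on (left start, right end, left length, right length),
making ranked output fully deterministic. Self-dimer scores use the
stated match=+1/mismatch=0 ungapped convention (`self_any` over all
antiparallel offsets, `self_end` over offsets pairing the 3′-terminal
base). Under this convention random 18–27-mers score ~8–14, so the caps
are set near the upper tail of that distribution (`max_self_any` 16,
`max_self_end` 12): only strongly palindromic oligos — a perfect 20-mer
palindrome scores 20 — are rejected. Hairpin stems (longest contiguous
complementary run closable with a ≥ 3 nt loop) are reported but not
filtered. For efficiency each side keeps a shortlist of the 150 best
candidates by individual penalty before pairing; since a pair penalty is
bounded below by the sum of its primers' individual penalties, the
top-20 pair list is unaffected at any realistic shortlist depth.

An `enforce_frame` option additionally requires the downstream offset to
be ≡ 0 (mod 3). It is off by default: the published picker settings
impose no frame constraint, and the recombination linker geometry, not
the native offset, sets the fusion frame.

## Specificity screen

Matching is ungapped over the full primer length on both strands —
short-oligo similarity at 80 % identity is substitution-dominated, and
the restriction keeps the exhaustive scan an exact oracle. Overlapping
windows on one strand merge into a single locus anchored at the
best-identity offset (ties leftmost). The published acceptance rule,
"a maximum of 3 hits in the genome per pair of primers (it will hit
itself)", is ambiguous between per-primer loci and amplicon-forming
co-placements; the default reads it per-primer (each primer ≤ 3 loci,
boundary inclusive), which the self-hit parenthetical supports, and a
stricter `amplicon` mode counting convergent co-placements within 10 kb
is provided. The seeded matcher partitions a primer into
`⌊(1 − identity)·len⌋ + 1` disjoint exact seeds; by pigeonhole every
window within the mismatch budget contains one seed, so
seed-and-verify returns exactly the oracle's locus set whenever the
seeds fit, and falls back to the oracle (with a warning) otherwise.
Note the default 11 nt seed only satisfies the condition for high
identity thresholds; at 80 % on 20-mers the guarantee needs seeds of
≤ 4 nt. The default pair evaluator uses the vectorized exhaustive scan,
which at desk scale (≤ a few hundred kb) is faster than seeding.

## Gateway constants

The partial tails are stored exactly as published: upstream
`aaaaagcaggct` (12 nt, matching the attB1 adapter suffix) and
downstream `agaaagctggt` (11 nt). The published attB2 adapter ends
`…AGAAAGCTGGGT`, a 12 nt suffix that differs from the 11 nt tail by one
G; the discrepancy is preserved, not resolved, and
`GatewayConstants.standard_attb2()` supplies the conventional 12 nt tail
for users who want the pair to agree. Tails are stored lowercase and
compared case-insensitively; order files emit uppercase. Wet-lab
recipes are out of scope; only the two cycling programs are modelled,
verbatim, as structured metadata.

## Funnel and PO analytics

Funnel progress is monotone by construction (a record stores its
furthest stage). Success rates are rounded half-up to one decimal,
matching the convention of the printed 74.8/75.4 values; note the study
also quotes 94.4 % and 79.7 % for two transitions whose printed counts
give 94.2 % and 79.9 % — this package always computes from counts and
reports the discrepancy rather than matching those two figures.
"Same expression pattern" is undefined in the source; consistency here
means exact equality of the non-empty PO-code sets formed by each
line's union over the four screening stages (plate at day 10, rosette,
pre-flowering, flowering), with a relaxed non-empty-intersection mode
off by default. The five categories (consistent multi-line, single
recovered line expressing, single expressing among several,
inconsistent, none expressing) partition any gene's line set.
Promoters-per-code summaries count a gene once per code regardless of
image count. Aggregate wet-lab outcomes that depend on unpublished
line-level data (1,885 lines, 761 expressing plants, 2,287 images,
3,371 PO assignments, the 112/19/14/5 split, 79 independent-dip genes)
are packaged as metadata and consistency-checked, never recomputed.

## Synthetic data

Backgrounds are i.i.d. nucleotides at a configurable GC fraction
(default 0.5), deliberately free of repeat structure so that planted
truths are provable: a planted gene is recovered with its ATG at
template offset 3000; an off-target copy planted with exactly
`round((1 − identity)·len)` substitutions (end bases protected by
default) contributes exactly one locus at exactly that identity. This
is what passing tests demonstrate — correct arithmetic and exact screen
behaviour — not performance on real genomes, whose repeat families and
segmental duplications make off-target counts far higher and anchoring
harder. The funnel generator samples independent per-transition
Bernoulli survival (defaults follow the packaged study funnel:
469/627, 442/469, 353/442, 266/353, …), up to 3 dips × 3 seedlings = 9
lines per construct, and per-line expression/deviation probabilities
(0.8 and 0.05) chosen as plausible for a reporter screen; patterns are
drawn from the packaged 81-code vocabulary weighted by its promoter
counts.

## Problem sizes

The default verification batches use 20 synthetic genes on 20 kb
contigs for design statistics, 100 random primer/genome draws on 5–30 kb
genomes for matcher-equivalence checks, and a 6-gene batch with 0–5
planted 85 %-identity primer copies for the specificity cap; these sizes
exercise every code path while keeping the whole suite and the
acceptance script in the tens of seconds.

## Known limitations

Tm ignores dangling ends, mismatch and loop thermodynamics; the screen
ignores gapped alignments and 3′-end-weighted mispriming; anchoring
does not handle a first exon shorter than the anchor; the penalty model
deliberately reproduces only the placement-relevant subset of a full
primer-design penalty function (no positional weighting, no template
mispriming term, no secondary-structure ΔG).
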