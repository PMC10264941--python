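# Methods

This note records the models, conventions and numerical choices behind
`mgecore`, and what the synthetic-data generator does and does not emulate.

## Coordinates and the replicon model

All coordinates are 1-based and inclusive, matching the published
comparison tables this kind of analysis is reported in. A replicon is an
ordered mosaic of segments (`unique`, `mge`, `tsd`) that tile `[1, length]`
exactly; the two TSD copies of one element must be byte-identical (N is
disallowed inside TSDs so that equality is meaningful). Circular replicons
carry a rotation anchor; with no anchor supplied, the lexicographically
minimal rotation (Booth's algorithm) is the canonical form, which makes
rotation-invariant string comparisons deterministic.

The core ↔ total coordinate map is a sorted ledger of removed intervals.
`core_to_total` is strictly increasing and round-trips with
`total_to_core`; total positions inside a removed element raise a distinct
"no core image" signal rather than an error-free wrong answer. Rebuilding
the total sequence from a core plus the ledger's removed spans is
byte-identical by construction and is tested as such.

## Core construction

An element copy is classified against the strain panel by junction probes:
the *empty-site probe* joins 250 bp of left flank (including the retained
TSD copy) to 250 bp beyond the downstream TSD; the *occupied-site probe*
joins the left flank to the element start. The empty site is searched in
the other strain's provisionally MGE-purged sequence — this is what lets
two distinct insertion sites a few hundred bp apart (the closely-spaced
case) resolve as two strain-specific calls instead of one shared one.
Matching requires a 30 bp exact window on each side of the junction and
tolerates 2 mismatches over the rest of the probe: the strains this method
targets are ~99.99 % identical, so near-exact matching suffices and avoids
pulling a full aligner into the classifier. Finding both probes in one
strain is reported `ambiguous` (possible mixed population) and never
silently resolved; an element carried by every strain is never removed.

Which TSD copy is removed is a free choice (the copies are equal); the
downstream copy is removed, deterministically. Flank length (250 bp), the
exact window (30 bp) and the mismatch allowance (2) are this package's
declared defaults, not claims about any other implementation.

## The HSP engine

Seed → chain → extend with megablast-like scoring (match +1, mismatch −2,
gap open −5 per event, gap extend −2 per column; 20-mer seeds, repeat cap
16 per seed):

* exact seed matches are merged along diagonals into exact segments;
* segments within `max_gap` (default 30 bp) on both sequences chain
  greedily; larger indels split HSPs — deliberately, since the published
  tables treat even a 38 bp duplication as two overlapping HSPs rather
  than one gapped HSP;
* only exact runs of at least `solid_min` (100 bp) are trusted as fixed
  anchors. A shorter run flanked by two opposing indels can be profitably
  bypassed by the true optimum (found empirically against a
  Smith–Waterman oracle), so short seeds are dissolved into the
  inter-anchor fill, which is a full affine (Gotoh) DP — banded once a
  fill exceeds 10⁶ cells, since the optimum cannot profitably wander far
  off-diagonal under affine costs;
* chain ends are extended by a banded x-drop DP keeping the
  maximum-scoring endpoint. `x_drop` (60) is deliberately below the cost
  of a `max_gap`+1 gap (67), so the split-at-large-indels rule holds at
  the extension stage too.

Equivalence with an independent dynamic-programming aligner (Biopython's C
Smith–Waterman, same scoring) is asserted on random mutated pairs up to
2 kb: identical optimal score and identical match/total counts. The
generated pairs keep their terminal 150 bp mutation-free: end-trimming of
divergent termini is exactly where any x-drop heuristic (BLAST included)
legitimately differs from full DP, and the engine's actual regime —
end-to-end near-identical core sequences — has no divergent termini.

**Identity display.** Per-HSP identity is truncated (floored) at two
decimals, `⌊match/total·10⁴⌋/100`: several published cells are only
reproducible under truncation (506,862/506,880 → 99.99, where rounding
gives 100.00; 48,433/48,453 → 99.95, where rounding gives 99.96), and
truncation guarantees 100.00 appears iff every column matches. The
aggregate over a whole comparison is a summary statistic and uses
conventional half-up rounding — 1,844,079/1,850,787 is 99.6376 %, printed
99.64 — so the two display rules are intentionally different and both are
tested.

`gap_chars` counts gap *columns* (not gap events), following the published
tables' "number of gap characters".

## Break classification

For consecutive colinear HSPs, each genome's junction value is
`next.start − prev.end − 1`: positive is a gap (unaligned interval), zero
directly adjacent, negative an overlap of that many bases (a short
duplication: the same bases aligned in both neighbouring HSPs). An overlap
on one genome with adjacency on the other is classified as an insertion in
the *other* genome (the extra tandem copy lives there). Unique sequence on
both sides is a replacement — the footprint of a deletion-coupled
insertion; extreme asymmetry (2.3 kb against 164.2 kb) is allowed.

Two length conventions are reported because the published tables mix them:
`primary_length` counts only the unaligned interval (a "9,476 bp
insertion" with an 8 bp overlap opposite), while `combined_length` adds
the adjacent overlap (a 104 bp gap opposite a 29 bp overlap is reported as
a "133 bp deletion"). Why the published account uses one convention here
and the other there is not stated anywhere; exposing both labelled values
avoids guessing intent.

Break size bins follow the published classes: short < 2 kb, long 3.2–9.4 kb,
very long ≥ 10 kb; the gaps between the printed class edges (3.0–3.2 kb,
9.4–10 kb) are closed upward (medium runs to 3.2 kb, long to 10 kb) so the
binning is total and deterministic.

Cross-comparison deduplication keys a break by 60 bp of core sequence on
each side of its junction in the strain common to the comparisons (hash),
falling back to query-side junction coordinates when no sequence is at
hand (as with printed-table input). Key collisions with disagreeing
coordinates are flagged, never merged.

Inverted duplications are maximal minus-strand self-matches of at least
`min_arm` (default 1 kb), deduplicated for the self-symmetry and for
palindrome overlap.

## Subassembly walking

The walker's contract is to make the repeat boundary *explicit* rather
than guess across it:

* extension uses reads containing the terminal 500 bp anchor exactly
  (error-free mode); per-position consensus must be unanimous, with a
  2 kb per-iteration cap (well under the read length, so blocking
  triggers before any misassembly);
* a read matching the anchor but disagreeing with the contig *upstream*
  proves the anchor occurs in another context: the walk stops
  `repeat_blocked`. The established minimum repeat length is backward
  agreement of the conflicting reads with the contig + anchor + forward
  unanimous consensus of the anchored reads — a true lower bound on the
  repeat, typically slightly above the read length at the default depth;
* conflicting extensions with at least 2 reads per branch fork into
  variants with support counts (strain-internal variability / mixed
  populations — whether variants coexist within single cells is not
  decidable from reads and is left undecided);
* circularity is declared when the contig wraps onto its own first
  1 kb exactly.

Guide resolution places contigs on a circular guide by unique terminal
flanks (windows grown 2→16 kb until the match is unique, so a terminus
lying *inside* a twice-occurring arm is still placed via the unique
sequence further in), fills inter-contig spans with guide sequence, and
reports a provenance mask (`read` / `guide`) that partitions the output
exactly. Competing placements or unplaceable contigs are reported, not
forced.

In-silico completion requires both termini of the partial assembly to
place uniquely on the donor's forward strand (i.e. inside a shared
duplication) and transfers the intervening donor span. The heterogeneity
scan places every read at its maximal-match position(s) — all seed
occurrences, both orientations, ties kept — and refuses completion if any
span position is supported by no read. This per-position-coverage
formulation is what makes the scan correct inside *inverted* duplications:
a read from the other arm otherwise seed-places at the wrong copy and
looks like a false conflict, while a genuine single-base donor/reads
disagreement leaves exactly that base uncovered (every read prefers the
other copy) and is caught.

Noisy-read selection (k-mer density) is provided best-effort; the
validated regime is error-free long reads.

## The simulator and what passing tests mean

The generator's defaults are the study conditions it emulates: a 2 Mb
chromosome at 65 % GC with a 61 kb AT-rich island, plasmids of 235 / 229 /
190 / 43 kb, a 16 kb block duplicated between two plasmids, an inverted
duplication with 32 kb core arms and a 40 kb extended version, strains
~99.99 % identical differing by 15 strain-specific MGE insertions
(elements 0.7–2.9 kb, TSDs 4–20 bp), point-mutation clouds (120 per
strain) and a small planted indel plan spanning the published break-size
classes (38 bp duplication up to a 47 kb ↔ 61 kb isopositioned
replacement). Reads are error-free 3 kb (log-normal lengths available),
depth 20, sampled across circular origins, with per-read origin records.

Two geometry decisions were genuinely open:

* the two repeat-bearing plasmids share one *contiguous* 130 kb cassette
  (arm + spacer-with-block + reverse arm). This mirrors the "very long
  duplication" between the real 190 kb and 229 kb plasmids and is what
  makes in-silico completion well-posed: the completed plasmid's missing
  region is contiguous in the donor, and completion demonstrably requires
  donor/truth identity over the span (the heterogeneity scan enforces it);
* the unextended 32 kb inverted pair is planted on the 235 kb plasmid,
  the 40 kb extended version on the cassette — one plasmid family with
  each arm length, as in the real strains.

Planted truth is *canonicalised at sampling time* (never at
interpretation time): payload termini are forced to mismatch the opposing
junction context, deletion/duplication endpoints avoid microhomology, MGE
sites are accepted only if the longest flanking direct repeat equals the
planted TSD, and repeat-arm boundaries are non-extendable. Without this,
any local aligner — ours, Smith–Waterman or BLAST — extends a few lucky
bases across a junction and "exact coordinate recovery" is ill-defined
rather than wrong. Real data contains such micro-homologies; on real
junctions the reported coordinates are correct up to this intrinsic
ambiguity, which is also why published tables themselves mix gap/overlap
bookkeeping at junctions.

What the simulations do **not** model: sequencing error profiles and base
quality, substitution-model realism or selection, IS-element target-site
preference, and replicon copy-number variation. Passing the recovery suite
therefore shows the *logic* of every stage is exact under its stated
preconditions — not that real PacBio data would assemble as cleanly.

## Problem sizes used in validation

The recovery suite runs the full default conditions: 3 strains × (2 Mb
chromosome + 4 plasmids), 15 MGEs, 9 planted chromosomal break events
across the two comparisons, ~2,800 plasmid reads; the aligner-oracle check
uses 200 random pairs ≤ 2 kb and the liftover check 1,000 random ledgers.
One full run takes about a minute on one CPU.
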