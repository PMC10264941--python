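# mgecore

Mobilome-aware comparison of near-identical prokaryotic genomes.

## The problem

In haloarchaea such as *Halobacterium salinarum*, strain differences are
dominated by a highly active mobilome: insertion sequences (ISH elements,
0.5–3 kb, flanked by 4–20 bp target-site duplications) transpose so
frequently that the rare differences carrying real evolutionary signal —
indels, deletion-coupled insertions ("replacements"), inverted duplications,
plasmid rearrangements — are buried under transposition noise. On top of
that, megaplasmids in these strains carry perfect duplications of 16–40 kb,
far longer than a long read, which defeats ordinary overlap assembly.

`mgecore` implements the comparison strategy used to resolve such strain
relationships, for people doing comparative genomics of near-identical
strains (bacterial or archaeal) with long reads:

1. **Tagged replicons** — each replicon is an ordered mosaic of unique
   segments, mobile genetic elements (MGEs) and their TSDs (tagged-dialect
   text or GFF3), with 1-based inclusive coordinates throughout.
2. **Core construction** — an MGE copy is *strain specific* iff another
   strain of the panel shows the joined empty site; removing it together
   with one TSD copy restores the pre-insertion state. Every removal is
   documented in a ledger that fully determines a bidirectional
   core ↔ total coordinate map (`total = core + Σ removed`).
3. **HSP engine** — a from-scratch seed–chain–extend gapped local aligner
   (match +1, mismatch −2, gap open −5, gap extend −2, 20-mer seeds)
   producing BLASTn-style alignment blocks. Identity is displayed
   *truncated* at two decimals — ⌊m/t·10⁴⌋/100 — so 506,862/506,880 prints
   99.99 and only a perfect block prints 100.00; the aggregate over a
   comparison is a summary and rounds (1,844,079/1,850,787 → 99.64 %).
4. **Break classification** — consecutive colinear HSPs leave a junction on
   each genome: a gap (unique sequence), direct adjacency, or an overlap of
   N bp. Categories: insertion in either genome, replacement
   (deletion-coupled insertion: unique sequence on *both* sides), adjacency
   artifact. Both published length conventions are reported: the unaligned
   interval alone (*primary*) and interval + adjacent overlap (*combined*).
   Events recurring across pairwise comparisons are deduplicated by a
   junction flank key.
5. **Subassembly walking** — contigs grow from anchored reads by unanimous
   consensus; a read matching the terminal anchor but disagreeing upstream
   proves the anchor lies in a repeat (`repeat_blocked`, with the
   established minimum repeat length); supported conflicting extensions are
   variant junctions, never averaged. Blocked junctions are crossed with
   *guide* replicons (related plasmids), and a partial assembly whose
   termini lie in a duplication shared with a *donor* is completed in
   silico after a read-level heterogeneity scan — with a provenance mask
   separating read-supported, guide-inferred and donor-transferred bases.
6. **Simulator** — an ancestral genome (~2 Mb chromosome, 43–235 kb
   plasmids, a 16 kb inter-plasmid block, 32/40 kb inverted arms) evolved
   into strains through an explicit event log, plus error-free or noisy
   long reads with origin records: exact ground truth for every stage.

## A worked example

```bash
python examples/02_published_tables_recomputed.py
```

```
identity cells (truncation, not rounding):
  506,862/506,880 -> 99.99 (rounding would give 100.00)
  48,433/48,453   -> 99.95 (rounding would give 99.96)

breaks, 63-R2 core chromosome vs R1:
  insertion_in_q   primary   9476 bp  combined   9484 bp
  insertion_in_s   primary     29 bp  combined     42 bp
  insertion_in_q   primary      0 bp  combined     38 bp
  insertion_in_q   primary    104 bp  combined    133 bp

distinct breakpoint events across both comparisons: 5
  (4 breaks vs R1 + 3 vs NRC-1, two shared junctions)

overall 63-R2 vs 91-R6 chromosome identity: 99.64 %
```

Reading this: the published core-chromosome comparison of *Hbt. salinarum*
63-R2 against R1 needs only five HSPs; the first break is a 9,476 bp
insertion in 63-R2 whose other side overlaps by 8 bp, the second is the
42 bp (14-codon) htrVI deletion, the third a 38 bp duplication, the fourth
the 133 bp rRNA-promoter deletion in R1. Merged with the NRC-1 comparison,
only five distinct events explain every breakpoint. The two 1934 Lochhead
isolates align at 99.64 % over 1.85 Mb of core chromosome.

The other examples show the tagged dialect and liftover (`01`), a full
simulated panel with exact break recovery (`03`), and repeat-spanning
plasmid reconstruction — walking, guide resolution, in-silico completion of
a 229 kb plasmid whose 40 kb duplicated arms exceed every read (`04`).

A thin CLI wraps the same stages
(`mgecore tag|core|align|classify|simulate|walk|pipeline`, all accepting
`--seed`).

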