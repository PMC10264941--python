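"""Subassembly walking: repeat-aware contig extension from long reads.

Duplications longer than any read cannot be resolved by overlap assembly:
once a contig end lies inside a repeat, reads from *all* repeat copies match
it and extension past the far junction would be a guess.  The walker makes
that boundary explicit:

* contigs are extended stepwise from anchored reads, by unanimous consensus;
* a read that matches the terminal anchor but disagrees with the contig
  *upstream* of it proves the anchor sequence occurs in another context —
  the walk stops ``repeat_blocked`` and reports the minimum established
  length of the blocking repeat (how far read agreement extends around the
  junction);
* conflicting extensions with real support on both sides are never
  averaged: they are reported as variant junctions (strain-internal
  variability / mixed populations);
* blocked junctions are then crossed with *guide* replicons (related
  plasmids): contigs are placed on the guide by their unique terminal
  flanks and the intervening repeat sequence is taken from the guide, with
  a provenance mask separating read-supported from guide-inferred bases;
* a partial assembly whose both termini lie inside a duplication shared
  with a *donor* replicon is completed in silico by transferring the
  corresponding donor span — only after a heterogeneity scan proves no read
  conflicts with the donor inside the duplication.

All operations are exact-match based (error-free long reads, the regime the
acceptance simulations run in); a noisy-read mode selects reads by shared
k-mer density and is best-effort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .replicon import AnnotatedReplicon, revcomp


def _seq_of(x: Union[str, AnnotatedReplicon]) -> str:
    return x.sequence if isinstance(x, AnnotatedReplicon) else x


# -- read index ------------------------------------------------------------


class ReadIndex:
    """Exact substring lookup over a read set, both strands."""

    def __init__(self, reads: Sequence[tuple[str, str]]):
        self.reads = list(reads)
        parts: list[str] = []
        self._bounds: list[tuple[int, int, int]] = []  # (blob_start, read_idx, strand)
        pos = 0
        for i, (_rid, seq) in enumerate(self.reads):
            parts.append(seq)
            self._bounds.append((pos, i, +1))
            pos += len(seq) + 1
            rc = revcomp(seq)
            parts.append(rc)
            self._bounds.append((pos, i, -1))
            pos += len(rc) + 1
        self.blob = "#".join(parts)
        self._starts = [b[0] for b in self._bounds]

    def find(self, sub: str) -> list[tuple[int, int, int]]:
        """All occurrences as (read_idx, offset_in_oriented_read, strand)."""
        import bisect

        out = []
        i = self.blob.find(sub)
        while i != -1:
            k = bisect.bisect_right(self._starts, i) - 1
            start, ridx, strand = self._bounds[k]
            out.append((ridx, i - start, strand))
            i = self.blob.find(sub, i + 1)
        return out

    def oriented(self, ridx: int, strand: int) -> str:
        seq = self.reads[ridx][1]
        return seq if strand > 0 else revcomp(seq)


# -- read selection --------------------------------------------------------


@dataclass
class ReadSet:
    reads: list[tuple[str, str]]
    anchor: str
    feature_class: str = "uncovered_unique"
    diagnostic: str = ""


def select_reads(
    reads: Sequence[tuple[str, str]],
    anchor: Union[str, AnnotatedReplicon],
    min_match: int = 100,
    feature_class: str = "uncovered_unique",
    noisy: bool = False,
    noisy_kmer: int = 16,
    noisy_density: float = 0.5,
) -> ReadSet:
    """All reads sharing an exact window of >= min_match bp with the anchor.

    In noisy mode a read is selected when at least ``noisy_density`` of a
    read-window's k-mers occur in the anchor (a k-mer density filter;
    best-effort, for error-carrying reads).
    """
    aseq = _seq_of(anchor)
    if len(aseq) < min_match:
        raise ValueError("anchor shorter than min_match")
    if noisy:
        akmers = {aseq[i : i + noisy_kmer] for i in range(len(aseq) - noisy_kmer + 1)}
        akmers |= {revcomp(k) for k in akmers}
        hits = []
        for rid, seq in reads:
            n = max(1, len(seq) - noisy_kmer + 1)
            shared = sum(1 for i in range(0, n, 4) if seq[i : i + noisy_kmer] in akmers)
            if shared / (n / 4) >= noisy_density * 0.5:
                hits.append((rid, seq))
        return ReadSet(hits, aseq, feature_class,
                       "" if hits else "anchor absent from sample (noisy mode)")
    idx = ReadIndex(reads)
    # any shared run >= min_match contains a complete grid-aligned window of
    # half that size; candidates are then verified by maximal extension
    w = max(12, min_match // 2)
    selected: dict[int, tuple[str, str]] = {}
    for w0 in range(0, len(aseq) - w + 1, w):
        window = aseq[w0 : w0 + w]
        for ridx, off, strand in idx.find(window):
            if ridx in selected:
                continue
            r = idx.oriented(ridx, strand)
            run = (w + _gallop_left(r, off, aseq, w0)
                   + _gallop_right(r, off + w, aseq, w0 + w))
            if run >= min_match:
                selected[ridx] = idx.reads[ridx]
    hits = [selected[i] for i in sorted(selected)]
    return ReadSet(hits, aseq, feature_class,
                   "" if hits else "anchor absent from sample")


# -- walking ---------------------------------------------------------------


@dataclass
class WalkParams:
    anchor_len: int = 500  # terminal window used to re-select reads
    step: int = 2_000  # cap per extension iteration (<< read length)
    min_depth: int = 3
    het_min: int = 2  # reads per branch to call a variant fork
    circ_overlap: int = 1_000


@dataclass
class Frontier:
    status: str = "extendable"  # extendable | exhausted | repeat_blocked | variant_fork
    repeat_min: int = 0  # established minimum repeat length when blocked
    variants: list[tuple[str, int]] = field(default_factory=list)  # (context, reads)


@dataclass
class WalkContig:
    sequence: str
    left: Frontier
    right: Frontier
    circular: bool = False
    junction_log: list[dict] = field(default_factory=list)
    support: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


def _consensus_tails(tails: list[str], het_min: int) -> tuple[str, Optional[list[tuple[str, int]]]]:
    """Greedy unanimous consensus of read tails.

    Returns (consensus, variants): consensus grows while every covering tail
    agrees; on disagreement, if at least two branches have >= het_min reads
    the caller has hit a variant fork and the branch contexts are returned.
    A disagreement below het_min is treated as end of extension.
    """
    tails = [t for t in tails if t]
    if not tails:
        return "", None
    out = []
    i = 0
    while True:
        chars = {}
        for t in tails:
            if i < len(t):
                chars.setdefault(t[i], []).append(t)
        if not chars:
            break
        if len(chars) > 1:
            branches = sorted(
                ((c, len(ts)) for c, ts in chars.items()), key=lambda x: -x[1]
            )
            strong = [b for b in branches if b[1] >= het_min]
            if len(strong) >= 2:
                prefix = "".join(out)[-50:]
                variants = []
                for c, _n in strong:
                    ts = chars[c]
                    ctx = max(ts, key=len)[i : i + 300]
                    variants.append((prefix + ctx, len(ts)))
                return "".join(out), variants
            # otherwise follow the majority branch
            best = branches[0][0]
            tails = chars[best]
            out.append(best)
            i += 1
            continue
        out.append(next(iter(chars)))
        i += 1
    return "".join(out), None


def _circle_close(contig: str, p: WalkParams) -> Optional[int]:
    """Period of the circle if the contig has wrapped around, else None."""
    if len(contig) < 2 * p.circ_overlap:
        return None
    head = contig[: p.circ_overlap]
    j = contig.rfind(head)
    if j > 0 and contig[j:] == contig[: len(contig) - j]:
        return j
    return None


def _extend_right(
    contig: str, idx: ReadIndex, p: WalkParams, log: list[dict]
) -> tuple[str, Frontier, Optional[int]]:
    """Extend rightward until exhausted / blocked / forked / circularized."""
    while True:
        period = _circle_close(contig, p)
        if period is not None:
            log.append({"action": "circularized", "length": period})
            return contig[:period], Frontier("exhausted"), period
        anchor = contig[-p.anchor_len :]
        hits = idx.find(anchor)
        consistent: list[tuple[int, int]] = []  # (ridx, offset)
        inconsistent: list[tuple[int, int]] = []
        for ridx, off, strand in hits:
            r = idx.oriented(ridx, strand)
            u = min(off, len(contig) - p.anchor_len)
            if u > 0 and r[off - u : off] != contig[-p.anchor_len - u : -p.anchor_len]:
                inconsistent.append((ridx, off, strand))
            else:
                consistent.append((ridx, off, strand))
        if inconsistent:
            # The anchor occurs in another context: a repeat at least as long
            # as read agreement around this junction.  Conflicting reads agree
            # with the contig backwards up to the repeat entry (the contig has
            # already walked into the repeat), so their common suffix extends
            # the established length.
            tails = [
                idx.oriented(ridx, strand)[off + p.anchor_len :]
                for ridx, off, strand in consistent
            ]
            fwd, _ = _consensus_tails(tails, het_min=10**9)
            body = contig[: len(contig) - p.anchor_len]
            back = 0
            for ridx, off, strand in inconsistent:
                r = idx.oriented(ridx, strand)[:off]
                k = 0
                while k < min(len(r), len(body)) and r[-1 - k] == body[-1 - k]:
                    k += 1
                back = max(back, k)
            repeat_min = back + p.anchor_len + len(fwd)
            log.append({"action": "repeat_blocked", "contig_len": len(contig),
                        "repeat_min": repeat_min,
                        "conflicting_reads": len(inconsistent)})
            return contig, Frontier("repeat_blocked", repeat_min=repeat_min), None
        tails = [
            idx.oriented(ridx, strand)[off + p.anchor_len :][: p.step]
            for ridx, off, strand in consistent
        ]
        ext, variants = _consensus_tails(tails, p.het_min)
        if variants:
            log.append({"action": "variant_fork", "contig_len": len(contig),
                        "branches": [(v[:40], c) for v, c in variants]})
            return contig, Frontier("variant_fork", variants=variants), None
        if not ext:
            log.append({"action": "exhausted", "contig_len": len(contig)})
            return contig, Frontier("exhausted"), None
        contig = contig + ext
        log.append({"action": "extend", "by": len(ext), "contig_len": len(contig)})


def _coverage(contig: str, idx: ReadIndex, probe: int = 64) -> list[int]:
    """Approximate per-base read depth by exact placement of each read."""
    cov = [0] * len(contig)
    for ridx in range(len(idx.reads)):
        placed = None
        for strand in (+1, -1):
            r = idx.oriented(ridx, strand)
            mid = max(0, len(r) // 2 - probe // 2)
            pos = contig.find(r[mid : mid + probe])
            if pos != -1:
                start = pos - mid
                placed = (max(0, start), min(len(contig), start + len(r)))
                break
        if placed:
            for i in range(placed[0], placed[1]):
                cov[i] += 1
    return cov


def walk(
    reads: Union[ReadSet, Sequence[tuple[str, str]]],
    seed: str,
    params: Optional[WalkParams] = None,
    compute_support: bool = False,
) -> WalkContig:
    """Iteratively extend a seed sequence in both directions.

    Stops per direction when no read extends (``exhausted``), when the
    terminal anchor proves repeat-ambiguous (``repeat_blocked``), or when
    supported conflicting extensions fork (``variant_fork``); a circular
    reconstruction is detected when the two ends overlap by at least
    ``circ_overlap`` identical bases.
    """
    p = params or WalkParams()
    read_list = reads.reads if isinstance(reads, ReadSet) else list(reads)
    idx = ReadIndex(read_list)
    if len(seed) < p.anchor_len:
        raise ValueError(f"seed shorter than anchor_len ({p.anchor_len})")
    if len(idx.find(seed)) < p.min_depth:
        raise ValueError(
            f"seed occurs in fewer than min_depth={p.min_depth} reads"
        )
    log: list[dict] = []
    contig, right, period = _extend_right(seed, idx, p, log)
    circular = period is not None
    left = Frontier("exhausted")
    if not circular:
        # leftward: walk the reverse complement rightward
        rc, left, period = _extend_right(revcomp(contig), idx, p, log)
        contig = revcomp(rc)
        if period is not None:
            contig = contig[-period:]
            circular = True
            left = right = Frontier("exhausted")
    out = WalkContig(sequence=contig, left=left, right=right,
                     circular=circular, junction_log=log)
    if compute_support:
        out.support = _coverage(contig, idx)
    return out


# -- guide-based junction resolution ----------------------------------------


@dataclass
class MaskSegment:
    start: int  # 1-based inclusive on the assembled sequence
    end: int
    source: str  # read | guide | donor


@dataclass
class GuideResolution:
    sequence: str
    mask: list[MaskSegment]
    circular: bool
    junctions_resolved: int
    unresolved: list[str]


def _unique_hit(hay_doubled: str, sub: str, period: int) -> Optional[int]:
    """0-based position of a unique (mod period) forward-strand occurrence."""
    hits = []
    i = hay_doubled.find(sub)
    while i != -1 and len(hits) < 3:
        if i < period:
            hits.append(i)
        i = hay_doubled.find(sub, i + 1)
    hits = sorted({h % period for h in hits})
    return hits[0] if len(hits) == 1 else None


def _place_contig(
    seq: str, guide2: str, period: int, min_flank: int
) -> Optional[tuple[int, int, str]]:
    """Place a contig on a circular guide by its unique terminal flanks.

    Returns (guide_start_of_first_base, guide_pos_of_last_base, oriented
    sequence); flank windows are grown until they hit a unique match, so a
    terminus lying inside a (twice-occurring) repeat arm is still placed via
    the unique sequence further in.
    """
    for oriented in (seq, revcomp(seq)):
        start = end = None
        for L in (min_flank, 2 * min_flank, 4 * min_flank, 8 * min_flank):
            if L > len(oriented):
                L = len(oriented)
            if start is None:
                h = _unique_hit(guide2, oriented[:L], period)
                if h is not None:
                    start = h
            if end is None:
                h = _unique_hit(guide2, oriented[-L:], period)
                if h is not None:
                    end = (h + L - 1) % period
            if start is not None and end is not None:
                return start, end, oriented
    return None


def resolve_with_guide(
    contigs: Sequence[Union[str, WalkContig]],
    guide: Union[str, AnnotatedReplicon],
    min_flank: int = 2_000,
) -> GuideResolution:
    """Order, orient and join contigs across repeats using a guide replicon.

    Contigs are placed on the (circular) guide by unique terminal flanks;
    gaps between consecutive placements — typically repeat arms no read
    could cross — are filled with guide sequence and masked ``guide``;
    contig bases are masked ``read``.  Junctions are crossed only where the
    placement is unambiguous; contigs that cannot be placed are reported.
    """
    gseq = _seq_of(guide)
    guide2 = gseq + gseq
    seqs = [c.sequence if isinstance(c, WalkContig) else c for c in contigs]
    placements = []
    unresolved = []
    for i, s in enumerate(seqs):
        hit = _place_contig(s, guide2, len(gseq), min_flank)
        if hit is None:
            unresolved.append(f"contig {i}: no unambiguous placement on guide")
        else:
            placements.append((hit[0], hit[1], hit[2], i))
    if not placements:
        return GuideResolution("", [], False, 0, unresolved or ["no contigs placed"])
    placements.sort()
    # check for competing placements
    for (s1, e1, _, i1), (s2, e2, _, i2) in zip(placements, placements[1:]):
        span1 = (e1 - s1) % len(gseq) + 1
        if (s2 - s1) % len(gseq) < span1 - min_flank:
            unresolved.append(
                f"contigs {i1} and {i2} compete for the same guide region"
            )
            return GuideResolution("", [], False, 0, unresolved)
    parts: list[str] = []
    mask: list[MaskSegment] = []
    junctions = 0

    def add(seg: str, source: str) -> None:
        if not seg:
            return
        start = sum(len(x) for x in parts) + 1
        parts.append(seg)
        mask.append(MaskSegment(start, start + len(seg) - 1, source))

    for k, (s, e, oriented, _i) in enumerate(placements):
        add(oriented, "read")
        nxt = placements[(k + 1) % len(placements)]
        gap = (nxt[0] - e - 1) % len(gseq)
        if gap > 0 or len(placements) > 1:
            add(guide2[e + 1 : e + 1 + gap], "guide")
            junctions += 1
    circular = len(placements) >= 1
    return GuideResolution(
        sequence="".join(parts), mask=mask, circular=circular,
        junctions_resolved=junctions, unresolved=unresolved,
    )


# -- in-silico completion ---------------------------------------------------


class HeterogeneityConflict(ValueError):
    def __init__(self, positions: list[int]):
        self.positions = positions
        super().__init__(
            f"reads conflict with the donor inside the duplication at "
            f"donor-span positions {positions[:10]}"
        )


@dataclass
class Completion:
    sequence: str
    mask: list[MaskSegment]
    transferred: int  # bp taken from the donor


def _gallop_left(a: str, ia: int, b: str, ib: int) -> int:
    """Length of the maximal common suffix of a[:ia] and b[:ib] (C-speed)."""
    lo, hi = 0, min(ia, ib)
    step = 64
    k = 0
    while k + step <= hi and a[ia - k - step : ia - k] == b[ib - k - step : ib - k]:
        k += step
        step *= 2
    while k < hi and a[ia - k - 1] == b[ib - k - 1]:
        k += 1
    return k


def _gallop_right(a: str, ia: int, b: str, ib: int) -> int:
    """Length of the maximal common prefix of a[ia:] and b[ib:]."""
    hi = min(len(a) - ia, len(b) - ib)
    step = 64
    k = 0
    while k + step <= hi and a[ia + k : ia + k + step] == b[ib + k : ib + k + step]:
        k += step
        step *= 2
    while k < hi and a[ia + k] == b[ib + k]:
        k += 1
    return k


def _scan_duplication_conflicts(
    span: str, reads: Sequence[tuple[str, str]], seed_len: int = 200, stride: int = 1_000
) -> list[int]:
    """Span positions not supported by any read at its best placement.

    Every read overlapping the span is placed at its maximal-match
    placement(s): all seed hits (both orientations, every occurrence — a
    read from the other copy of an inverted repeat otherwise seed-places at
    the wrong arm) are extended maximally and every placement achieving the
    best matched length marks the span region it supports.  A span position
    supported by no read is where the reads contradict the donor (e.g. a
    single-base difference leaves exactly that base uncovered, because every
    read prefers the other repeat copy); those positions are returned.
    """
    diff = [0] * (len(span) + 1)
    for _rid, seq in reads:
        placements: list[tuple[int, int, int]] = []  # (matched_len, start, end)
        for oriented in (seq, revcomp(seq)):
            for i in range(0, max(1, len(oriented) - seed_len + 1), stride):
                probe = oriented[i : i + seed_len]
                if len(probe) < seed_len:
                    break
                j = span.find(probe)
                while j != -1:
                    left = _gallop_left(oriented, i, span, j)
                    right = _gallop_right(oriented, i + seed_len, span, j + seed_len)
                    start = j - left
                    end = j + seed_len + right  # exclusive
                    placements.append((end - start, start, end))
                    j = span.find(probe, j + 1)
        if not placements:
            continue
        best = max(p[0] for p in placements)
        for ln, start, end in set(placements):
            if ln == best:
                diff[start] += 1
                diff[end] -= 1
    uncovered = []
    c = 0
    for k in range(len(span)):
        c += diff[k]
        if c == 0:
            uncovered.append(k)
    return uncovered


def insilico_complete(
    partial: Union[str, WalkContig],
    donor: Union[str, AnnotatedReplicon],
    reads: Optional[Sequence[tuple[str, str]]] = None,
    flank: int = 1_000,
) -> Completion:
    """Complete a partial assembly by transferring the missing donor span.

    Both termini of ``partial`` must lie inside a region shared with the
    (circular) ``donor``: the terminal flanks are located uniquely on the
    donor's forward strand and the donor sequence between them (wrapping
    around the circle) is appended, yielding a circular completed sequence.
    When ``reads`` are given, the transferred span (duplication) is first
    scanned for read-level heterogeneity; any conflict refuses completion.
    """
    pseq = partial.sequence if isinstance(partial, WalkContig) else partial
    dseq = _seq_of(donor)
    if len(pseq) < 2 * flank:
        raise ValueError("partial shorter than twice the flank length")
    donor2 = dseq + dseq
    tail = pseq[-flank:]
    head = pseq[:flank]
    t_hit = _unique_hit(donor2, tail, len(dseq))
    h_hit = _unique_hit(donor2, head, len(dseq))
    if t_hit is None or h_hit is None:
        raise ValueError(
            "partial termini could not be placed uniquely on the donor "
            "forward strand (not inside a shared duplication?)"
        )
    t_end = (t_hit + flank - 1) % len(dseq)  # donor pos of partial's last base
    gap = (h_hit - 1 - t_end) % len(dseq)
    transfer = donor2[t_end + 1 : t_end + 1 + gap]
    if gap == 0:
        return Completion(sequence=pseq, mask=[MaskSegment(1, len(pseq), "read")],
                          transferred=0)
    if reads is not None:
        margin = min(flank, 500)
        span = pseq[-margin:] + transfer + pseq[:margin]
        conflicts = _scan_duplication_conflicts(span, reads)
        if conflicts:
            raise HeterogeneityConflict(conflicts)
    completed = pseq + transfer
    mask = [MaskSegment(1, len(pseq), "read"),
            MaskSegment(len(pseq) + 1, len(completed), "donor")]
    return Completion(sequence=completed, mask=mask, transferred=gap)


# -- heterogeneity detection ------------------------------------------------


@dataclass
class HeterogeneityReport:
    status: str  # ok | undecidable
    variants: list[tuple[str, int]] = field(default_factory=list)


def detect_heterogeneity(
    reads: Sequence[tuple[str, str]],
    locus_window: str,
    min_depth: int = 3,
    context: int = 300,
) -> HeterogeneityReport:
    """Partition reads spanning a locus window by their junction structure.

    Reads containing the window are grouped by the sequence that follows
    it; each group is one variant with its support count.  Whether variants
    coexist within single cells or reflect a mixed population is not
    decidable from reads alone — below ``min_depth`` spanning reads the
    status is ``undecidable``.
    """
    idx = ReadIndex(reads)
    hits = idx.find(locus_window)
    if len(hits) < min_depth:
        return HeterogeneityReport("undecidable")
    tails = []
    for ridx, off, strand in hits:
        r = idx.oriented(ridx, strand)
        tails.append(r[off + len(locus_window) : off + len(locus_window) + context])
    clusters: list[list[str]] = []
    for t in sorted(tails, key=len, reverse=True):
        for cl in clusters:
            ref = cl[0]
            overlap = min(len(ref), len(t))
            if overlap and ref[:overlap] == t[:overlap]:
                cl.append(t)
                break
        else:
            clusters.append([t])
    variants = sorted(
        ((cl[0], len(cl)) for cl in clusters), key=lambda v: -v[1]
    )
    return HeterogeneityReport("ok", variants=variants)
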