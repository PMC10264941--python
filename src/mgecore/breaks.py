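"""Tiling of HSPs into breaks, breakpoint classification, deduplication.

Between two core replicons, consecutive colinear HSPs leave a *break* on
each genome: a gap (unaligned interval), a directly-adjacent junction, or an
overlap of N bp (the same bases aligned in both neighbouring HSPs, i.e. a
short duplication).  Categories:

* ``insertion_in_q`` / ``insertion_in_s`` — unique sequence on one side only
  (an insertion in one strain, equivalently a deletion in the other);
* ``replacement`` — unrelated sequence on *both* sides at the same junction,
  the footprint of a deletion-coupled insertion;
* ``adjacency_artifact`` — no unique sequence on either side.

Two length conventions are reported for every event, because published
tables mix them: ``primary_length`` counts only the unaligned interval
(a 9,476 bp insertion with an 8 bp overlap on the other genome is reported
as 9,476), while ``combined_length`` adds the adjacent overlap (a 104 bp gap
opposite a 29 bp overlap is the footprint of a 133 bp deletion).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .align import HSP, find_maximal_matches
from .replicon import AnnotatedReplicon

FLANK_KEY_BP = 60  # flanking bases hashed into the cross-comparison key

SIZE_BINS = (
    ("short", 0, 2_000),  # below 2 kb
    ("medium", 2_000, 3_200),
    ("long", 3_200, 10_000),  # the 3.2-9.4 kb class
    ("very_long", 10_000, None),
)


@dataclass
class BreakEvent:
    """One classified inter-HSP junction."""

    q_gap: Optional[tuple[int, int]]  # unaligned interval in query, or None
    s_gap: Optional[tuple[int, int]]
    q_relation: str  # "gap" | "directly_adjacent" | "overlap"
    s_relation: str
    q_overlap: int = 0  # bp, when relation == "overlap"
    s_overlap: int = 0
    category: str = "adjacency_artifact"
    primary_length: int = 0
    combined_length: int = 0
    annotation: str = ""
    identity_key: str = ""
    terminal: bool = False  # break at a replicon end rather than between HSPs

    @property
    def size_bin(self) -> str:
        return size_bin(self.primary_length)

    def swapped(self) -> "BreakEvent":
        """The same event seen with query and subject exchanged."""
        cat = {
            "insertion_in_q": "insertion_in_s",
            "insertion_in_s": "insertion_in_q",
        }.get(self.category, self.category)
        return BreakEvent(
            q_gap=self.s_gap,
            s_gap=self.q_gap,
            q_relation=self.s_relation,
            s_relation=self.q_relation,
            q_overlap=self.s_overlap,
            s_overlap=self.q_overlap,
            category=cat,
            primary_length=self.primary_length,
            combined_length=self.combined_length,
            annotation=self.annotation,
            identity_key=self.identity_key,
            terminal=self.terminal,
        )


def size_bin(length: int) -> str:
    for name, lo, hi in SIZE_BINS:
        if length >= lo and (hi is None or length < hi):
            return name
    raise ValueError(f"negative length {length}")


def bin_break_sizes(events: Sequence[BreakEvent]) -> dict[str, int]:
    """Histogram of break primary lengths over the size bins."""
    hist = {name: 0 for name, _, _ in SIZE_BINS}
    for ev in events:
        hist[ev.size_bin] += 1
    return hist


def _classify(qg: int, sg: int) -> str:
    if qg > 0 and sg > 0:
        return "replacement"
    if qg > 0:
        return "insertion_in_q"
    if sg > 0:
        return "insertion_in_s"
    # no unique interval on either side: an overlap on one genome means the
    # other genome carries an extra (tandem-duplicated) copy of those bases
    if sg < 0 and qg == 0:
        return "insertion_in_q"
    if qg < 0 and sg == 0:
        return "insertion_in_s"
    return "adjacency_artifact"


def _lengths(qg: int, sg: int, category: str) -> tuple[int, int]:
    if category == "insertion_in_q":
        primary = max(qg, 0)
        combined = primary + max(-sg, 0)
    elif category == "insertion_in_s":
        primary = max(sg, 0)
        combined = primary + max(-qg, 0)
    elif category == "replacement":
        primary = max(qg, sg)
        combined = primary
    else:
        primary = 0
        combined = max(-qg, 0) + max(-sg, 0)
    return primary, combined


def _junction_key(q_seq: Optional[str], left_end: int, right_start: int,
                  qg: int, sg: int) -> str:
    """Cross-comparison identity key for a break.

    When the shared reference (query) sequence is available the key hashes
    FLANK_KEY_BP of core sequence on each side of the junction; otherwise it
    falls back to the query-side junction coordinates, which identify the
    event within one fixed reference strain.
    """
    if q_seq is not None:
        left = q_seq[max(0, left_end - FLANK_KEY_BP) : left_end]
        right = q_seq[right_start - 1 : right_start - 1 + FLANK_KEY_BP]
        h = hashlib.sha1(f"{left}|{right}".encode()).hexdigest()[:16]
        return f"flank:{h}"
    return f"coord:{left_end}:{right_start}:{1 if qg > 0 else 0}"


def tile_and_break(
    hsps: Sequence[HSP],
    q_len: int,
    s_len: int,
    q_seq: Optional[str] = None,
) -> list[BreakEvent]:
    """Emit and classify every inter-HSP junction of a colinear tiling.

    HSPs must be plus-strand and colinear (run minus-strand blocks through
    :func:`detect_inverted_duplication` / inversion handling first); they are
    processed in query order.  Gap arithmetic per side:
    ``next.start - prev.end - 1`` — positive is a gap interval, zero directly
    adjacent, negative an overlap of that many bases.  Terminal unaligned
    intervals (before the first / after the last HSP) are emitted as breaks
    flagged ``terminal`` so every base of both replicons is accounted for.
    """
    if not hsps:
        raise ValueError("no HSPs to tile")
    ordered = sorted(hsps, key=lambda h: (h.q_start, h.s_start))
    for h in ordered:
        if h.strand != "+":
            raise ValueError(
                "minus-strand HSP in colinear tiling; lift inversions out first"
            )
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.q_end <= prev.q_end or nxt.s_end <= prev.s_end or nxt.s_start < prev.s_start:
            raise ValueError("HSPs are not colinear; resolve inversions/repeats first")
    events: list[BreakEvent] = []
    # leading terminal break
    first = ordered[0]
    if first.q_start > 1 or first.s_start > 1:
        qg = first.q_start - 1
        sg = first.s_start - 1
        events.append(_make_event(qg, sg, 0, first.q_start, 0, first.s_start,
                                  q_seq, terminal=True))
    for prev, nxt in zip(ordered, ordered[1:]):
        qg = nxt.q_start - prev.q_end - 1
        sg = nxt.s_start - prev.s_end - 1
        events.append(
            _make_event(qg, sg, prev.q_end, nxt.q_start, prev.s_end, nxt.s_start, q_seq)
        )
    last = ordered[-1]
    if last.q_end < q_len or last.s_end < s_len:
        qg = q_len - last.q_end
        sg = s_len - last.s_end
        events.append(_make_event(qg, sg, last.q_end, q_len + 1, last.s_end, s_len + 1,
                                  q_seq, terminal=True))
    return events


def _make_event(qg: int, sg: int, q_prev_end: int, q_next_start: int,
                s_prev_end: int, s_next_start: int,
                q_seq: Optional[str], terminal: bool = False) -> BreakEvent:
    category = _classify(qg, sg)
    primary, combined = _lengths(qg, sg, category)
    q_rel = "gap" if qg > 0 else ("directly_adjacent" if qg == 0 else "overlap")
    s_rel = "gap" if sg > 0 else ("directly_adjacent" if sg == 0 else "overlap")
    return BreakEvent(
        q_gap=(q_prev_end + 1, q_next_start - 1) if qg > 0 else None,
        s_gap=(s_prev_end + 1, s_next_start - 1) if sg > 0 else None,
        q_relation=q_rel,
        s_relation=s_rel,
        q_overlap=-qg if qg < 0 else 0,
        s_overlap=-sg if sg < 0 else 0,
        category=category,
        primary_length=primary,
        combined_length=combined,
        identity_key=_junction_key(q_seq, q_prev_end, q_next_start, qg, sg),
        terminal=terminal,
    )


def tiling_conservation(hsps: Sequence[HSP], events: Sequence[BreakEvent],
                        q_len: int, s_len: int) -> bool:
    """Check sum(HSP spans) + sum(gaps) - sum(overlaps) == length, per genome."""
    q = sum(h.q_span for h in hsps)
    s = sum(h.s_span for h in hsps)
    for ev in events:
        q += (ev.q_gap[1] - ev.q_gap[0] + 1) if ev.q_gap else 0
        q -= ev.q_overlap
        s += (ev.s_gap[1] - ev.s_gap[0] + 1) if ev.s_gap else 0
        s -= ev.s_overlap
    return q == q_len and s == s_len


# -- deduplication across comparisons --------------------------------------


@dataclass
class DistinctEvent:
    identity_key: str
    members: dict[str, BreakEvent] = field(default_factory=dict)
    flagged: bool = False  # key collision with conflicting coordinates


def dedupe_events(break_lists: dict[str, Sequence[BreakEvent]]) -> list[DistinctEvent]:
    """Merge breaks that recur across pairwise comparisons.

    Breaks are matched by their identity key (flank hash, or junction
    coordinates, in the strain common to all comparisons).  A key collision
    whose query-side coordinates disagree is flagged for review rather than
    merged.
    """
    by_key: dict[str, DistinctEvent] = {}
    order: list[str] = []
    for comparison, events in break_lists.items():
        for ev in events:
            key = ev.identity_key
            if key not in by_key:
                by_key[key] = DistinctEvent(identity_key=key)
                order.append(key)
            distinct = by_key[key]
            for other in distinct.members.values():
                if (other.q_gap, other.q_overlap) != (ev.q_gap, ev.q_overlap):
                    distinct.flagged = True
            distinct.members[comparison] = ev
    return [by_key[k] for k in order]


# -- replacements ----------------------------------------------------------


def classify_replacement(event: BreakEvent, min_side: int = 100) -> BreakEvent:
    """Refine an event: replacement iff both unique sides reach min_side.

    Extreme asymmetry is allowed (a 2.3 kb side replaced by a 164.2 kb side
    is still a replacement).  The side lengths are recorded in the
    annotation.
    """
    q_side = (event.q_gap[1] - event.q_gap[0] + 1) if event.q_gap else 0
    s_side = (event.s_gap[1] - event.s_gap[0] + 1) if event.s_gap else 0
    if q_side >= min_side and s_side >= min_side:
        event.category = "replacement"
        event.annotation = (
            f"replacement: {q_side} bp (query) <-> {s_side} bp (subject)"
            + (f"; {event.annotation}" if event.annotation else "")
        )
    return event


# -- inverted duplications --------------------------------------------------


@dataclass(frozen=True)
class InvertedDuplication:
    arm1: tuple[int, int]  # 1-based inclusive, arm1 ends before arm2 starts
    arm2: tuple[int, int]
    arm_len: int
    spacer: int  # bp between the two arms


def detect_inverted_duplication(
    source: Union[str, AnnotatedReplicon, tuple],
    min_arm: int = 1_000,
) -> Union[list[InvertedDuplication], dict[str, list[InvertedDuplication]]]:
    """Find long inverted repeat pairs via minus-strand self matches.

    For a single sequence, returns maximal inverted arm pairs of at least
    ``min_arm`` bp.  For a pair of replicons (tuple), each is analysed and
    the result keyed by replicon id — the nested 32 kb core / 40 kb extended
    arm structure of related plasmids then shows up as the two arm lengths.
    """
    if isinstance(source, tuple):
        out: dict[str, list[InvertedDuplication]] = {}
        for item in source:
            name = item.id if isinstance(item, AnnotatedReplicon) else f"seq{len(out) + 1}"
            out[name] = detect_inverted_duplication(item, min_arm=min_arm)
        return out
    seq = source.sequence if isinstance(source, AnnotatedReplicon) else source
    if len(seq) < 2 * min_arm:
        return []
    matches = find_maximal_matches(seq, seq, min_len=max(12, min_arm))
    dups: list[InvertedDuplication] = []
    seen = set()
    for a_pos, b_pos, length, strand in matches:
        if strand != "-" or length < min_arm:
            continue
        lo, hi = sorted((a_pos, b_pos))
        # self symmetry reports each pair twice; a palindromic arm pair also
        # matches itself when lo == hi
        key = (lo, hi, length)
        if key in seen or lo == hi:
            continue
        seen.add(key)
        arm1 = (lo, lo + length - 1)
        arm2 = (hi, hi + length - 1)
        if arm1[1] >= arm2[0]:
            continue  # overlapping arms: a palindrome, not a duplication
        dups.append(
            InvertedDuplication(arm1=arm1, arm2=arm2, arm_len=length,
                                spacer=arm2[0] - arm1[1] - 1)
        )
    return sorted(dups, key=lambda d: (-d.arm_len, d.arm1))


# -- colinear selection -----------------------------------------------------


def colinear_chain(hsps: Sequence[HSP], max_overlap: int = 5_000) -> list[HSP]:
    """Best-scoring colinear plus-strand subset (weighted increasing chain).

    Repeat-induced extra HSPs (and minus-strand blocks) are excluded so the
    result satisfies the preconditions of :func:`tile_and_break`.  Weight is
    match_bases; succession requires strictly increasing starts and ends on
    both genomes with per-side overlap at most ``max_overlap``.
    """
    plus = sorted((h for h in hsps if h.strand == "+"), key=lambda h: (h.q_start, h.s_start))
    n = len(plus)
    if n == 0:
        return []
    best = [h.match_bases for h in plus]
    prev = [-1] * n
    for i in range(n):
        hi = plus[i]
        for j in range(i):
            hj = plus[j]
            if (
                hj.q_start < hi.q_start
                and hj.q_end < hi.q_end
                and hj.s_start < hi.s_start
                and hj.s_end < hi.s_end
                and hj.q_end - hi.q_start + 1 <= max_overlap
                and hj.s_end - hi.s_start + 1 <= max_overlap
            ):
                cand = best[j] + hi.match_bases
                if cand > best[i]:
                    best[i] = cand
                    prev[i] = j
    end = max(range(n), key=lambda i: best[i])
    chain = []
    while end != -1:
        chain.append(plus[end])
        end = prev[end]
    return chain[::-1]
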