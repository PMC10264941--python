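"""Core-sequence construction: TSD detection, strain-specificity, removal.

A mobile element is *strain specific* when at least one other strain of the
panel shows the joined empty site (left flank + target site + right flank
with no element in between) while the focal strain carries the element.
Removing a strain-specific element together with exactly one copy of its
target-site duplication (TSD) restores the pre-insertion state, so cores of
strains that differ only by mobilome activity collapse onto identical
strings.  Every removal is documented in a ledger which fully determines the
core<->total coordinate map and from which the total sequence can be rebuilt
byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .replicon import AnnotatedReplicon, CoordinateMap

DEFAULT_FLANK = 250
EXACT_WINDOW = 30  # exact match required this close to the junction
MAX_MISMATCH = 2  # tolerated in the remaining flank (strains ~99.99% identical)


@dataclass(frozen=True)
class TsdResult:
    length: int
    sequence: str
    truncated: bool = False  # search clipped by a linear replicon end


def find_tsd(sequence: str, mge_interval: tuple[int, int], max_tsd_len: int = 25) -> TsdResult:
    """Longest exact direct repeat immediately flanking an element interval.

    ``mge_interval`` is the 1-based inclusive span of the element itself
    (TSD copies excluded).  Returns length 0 when the flanks share no
    immediate repeat.  On a linear replicon, an interval touching either end
    truncates the search and the result is flagged.
    """
    ms, me = mge_interval
    if not (1 <= ms <= me <= len(sequence)):
        raise ValueError(f"interval [{ms},{me}] outside sequence of {len(sequence)} bp")
    if max_tsd_len < 0:
        raise ValueError("max_tsd_len must be >= 0")
    left_avail = ms - 1
    right_avail = len(sequence) - me
    limit = min(max_tsd_len, left_avail, right_avail)
    truncated = limit < max_tsd_len and (left_avail < max_tsd_len or right_avail < max_tsd_len)
    best = 0
    for t in range(1, limit + 1):
        if sequence[ms - 1 - t : ms - 1] == sequence[me : me + t]:
            best = t
    return TsdResult(best, sequence[me : me + best], truncated)


@dataclass
class MgeSpecificity:
    """Classification of one MGE copy against a strain panel."""

    replicon: str
    focal_strain: str
    mge_index: int  # index of the mge segment within replicon.segments
    mge_type: str
    removal_interval: tuple[int, int]  # element + downstream TSD copy, 1-based
    tsd_length: int
    category: str  # strain_specific | shared | shared_subset
    carriers: frozenset[str] = frozenset()
    junction_evidence: dict[str, str] = field(default_factory=dict)
    # per-strain: mge_present | empty_site_present | ambiguous | no_evidence


def _fuzzy_find(hay: str, probe: str, junction: int) -> bool:
    """Locate probe in hay: exact near the junction, tolerant further out.

    The probe is a joined flank pair; ``junction`` is the 0-based offset of
    the join.  An exact window of EXACT_WINDOW bp on each side of the join is
    required; up to MAX_MISMATCH mismatches are allowed over the rest.
    """
    if probe in hay:
        return True
    lo = max(0, junction - EXACT_WINDOW)
    hi = min(len(probe), junction + EXACT_WINDOW)
    core = probe[lo:hi]
    if not core:
        return False
    start = hay.find(core)
    while start != -1:
        p0 = start - lo
        if p0 >= 0 and p0 + len(probe) <= len(hay):
            window = hay[p0 : p0 + len(probe)]
            mismatches = sum(1 for x, y in zip(window, probe) if x != y)
            if mismatches <= MAX_MISMATCH:
                return True
        start = hay.find(core, start + 1)
    return False


def _mge_units(rep: AnnotatedReplicon) -> list[tuple[int, int, int, int, str]]:
    """(segment_index, removal_start, removal_end, tsd_len, mge_type) per MGE.

    The removal interval covers the element plus its downstream TSD copy, so
    that excising it restores the empty (pre-insertion) site.
    """
    units = []
    segs = rep.segments
    for i, seg in enumerate(segs):
        if seg.kind != "mge":
            continue
        t = 0
        if i + 1 < len(segs) and segs[i + 1].kind == "tsd":
            t = segs[i + 1].length
        units.append((i, seg.start, seg.end + t, t, seg.mge_type or "MGE"))
    return units


def purge_all_mges(rep: AnnotatedReplicon) -> tuple[str, CoordinateMap]:
    """Sequence with every annotated MGE (+ one TSD copy) removed.

    Used as the search space for empty sites in *other* strains, so that
    distinct insertion sites closer together than the flank length are still
    resolved (each strain's own elements cannot shadow the probe).
    """
    removals = [(start, end - start + 1) for _, start, end, _, _ in _mge_units(rep)]
    cmap = CoordinateMap(total_length=len(rep), removals=removals)
    seq = _apply_removals(rep.sequence, removals)
    return seq, cmap


def _apply_removals(sequence: str, removals: list[tuple[int, int]]) -> str:
    parts = []
    pos = 0
    for start, length in sorted(removals):
        parts.append(sequence[pos : start - 1])
        pos = start - 1 + length
    parts.append(sequence[pos:])
    return "".join(parts)


def classify_specificity(
    focal: AnnotatedReplicon,
    mge_index: int,
    others: dict[str, AnnotatedReplicon],
    flank_len: int = DEFAULT_FLANK,
) -> MgeSpecificity:
    """Decide whether one MGE copy of the focal strain is strain specific.

    For every other strain the *empty-site probe* (left flank, including the
    retained TSD copy, joined to the right flank beyond the downstream TSD)
    is searched in that strain's provisionally MGE-purged sequence, and the
    *occupied-site probe* (left flank joined to the element start) in its raw
    sequence.  Finding both is reported as ``ambiguous`` (possible mixed
    population) and never silently resolved.
    """
    units = {i: (i, s, e, t, m) for i, s, e, t, m in _mge_units(focal)}
    if mge_index not in units:
        raise ValueError(f"segment {mge_index} of {focal.id} is not an MGE")
    _, rstart, rend, tsd_len, mge_type = units[mge_index]
    seq = focal.sequence
    left = seq[max(0, rstart - 1 - flank_len) : rstart - 1]
    right = seq[rend : rend + flank_len]
    occupied_tail = seq[rstart - 1 : rstart - 1 + min(flank_len, rend - rstart + 1)]
    probe_empty = left + right
    probe_occupied = left + occupied_tail
    evidence: dict[str, str] = {}
    for strain, rep in others.items():
        purged, _ = purge_all_mges(rep)
        has_empty = _fuzzy_find(purged, probe_empty, len(left))
        has_occ = _fuzzy_find(rep.sequence, probe_occupied, len(left))
        if has_empty and has_occ:
            evidence[strain] = "ambiguous"
        elif has_empty:
            evidence[strain] = "empty_site_present"
        elif has_occ:
            evidence[strain] = "mge_present"
        else:
            evidence[strain] = "no_evidence"
    empties = {s for s, e in evidence.items() if e == "empty_site_present"}
    occupied = {s for s, e in evidence.items() if e == "mge_present"}
    if not others:
        category = "strain_specific"  # single-strain input: vacuous evidence
    elif empties and not occupied:
        category = "strain_specific"
    elif occupied and not empties:
        category = "shared"
    elif occupied and empties:
        category = "shared_subset"
    else:
        category = "shared"  # no decisive evidence: conservative, never remove
    carriers = frozenset({focal.strain or "focal"} | occupied)
    return MgeSpecificity(
        replicon=focal.id,
        focal_strain=focal.strain or "focal",
        mge_index=mge_index,
        mge_type=mge_type,
        removal_interval=(rstart, rend),
        tsd_length=tsd_len,
        category=category,
        carriers=carriers,
        junction_evidence=evidence,
    )


@dataclass(frozen=True)
class LedgerRow:
    strain: str
    replicon: str
    mge_type: str
    total_start: int
    total_end: int
    tsd_length: int


@dataclass
class RemovalLedger:
    """Documentation of every MGE eliminated during core construction."""

    rows: list[LedgerRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strain": r.strain,
                    "replicon": r.replicon,
                    "mge_type": r.mge_type,
                    "total_start": r.total_start,
                    "total_end": r.total_end,
                    "tsd_length": r.tsd_length,
                }
                for r in self.rows
            ],
            columns=["strain", "replicon", "mge_type", "total_start", "total_end", "tsd_length"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def removals_for(self, replicon: str) -> list[tuple[int, int]]:
        return [
            (r.total_start, r.total_end - r.total_start + 1)
            for r in self.rows
            if r.replicon == replicon
        ]


@dataclass
class CoreSequence:
    """An MGE-purged replicon plus its coordinate map and removal ledger."""

    replicon: str
    strain: str
    sequence: str
    cmap: CoordinateMap
    ledger: RemovalLedger


def build_core(
    rep: AnnotatedReplicon,
    specificities: list[MgeSpecificity],
    max_passes: int = 10,
) -> CoreSequence:
    """Remove the strain-specific MGEs of one replicon; emit map + ledger.

    Only entries classified ``strain_specific`` are removed, each together
    with its downstream TSD copy (the upstream copy stays, restoring the
    empty-site state).  The segment model forbids overlapping annotations,
    but nested or composite elements encountered in re-annotated input are
    handled by iterating innermost-first until a fixpoint (cycle guard at
    ``max_passes``).
    """
    to_remove = [
        s
        for s in specificities
        if s.category == "strain_specific" and s.replicon == rep.id
    ]
    removals: list[tuple[int, int]] = []
    rows: list[LedgerRow] = []
    for s in sorted(to_remove, key=lambda s: (s.removal_interval[1] - s.removal_interval[0])):
        start, end = s.removal_interval
        if any(not (end < a or start > a + ln - 1) for a, ln in removals):
            continue  # inner element already removed this span
        removals.append((start, end - start + 1))
        rows.append(
            LedgerRow(
                strain=rep.strain or "focal",
                replicon=rep.id,
                mge_type=s.mge_type,
                total_start=start,
                total_end=end,
                tsd_length=s.tsd_length,
            )
        )
        if len(rows) > max_passes * max(1, len(to_remove)):
            raise RuntimeError("removal did not reach a fixpoint")
    removals.sort()
    rows.sort(key=lambda r: r.total_start)
    cmap = CoordinateMap(total_length=len(rep), removals=removals)
    core_seq = _apply_removals(rep.sequence, removals)
    assert len(core_seq) == cmap.core_length
    return CoreSequence(
        replicon=rep.id,
        strain=rep.strain or "focal",
        sequence=core_seq,
        cmap=cmap,
        ledger=RemovalLedger(rows),
    )


def restore_total(core: CoreSequence, removed_sequences: list[str]) -> str:
    """Rebuild the total sequence from a core plus the removed spans.

    ``removed_sequences`` must be ordered like the ledger rows; conservation
    (restore == original total) is the invariant the ledger guarantees.
    """
    rows = sorted(core.ledger.rows, key=lambda r: r.total_start)
    if len(rows) != len(removed_sequences):
        raise ValueError("one removed sequence per ledger row required")
    out = []
    core_pos = 0
    total_pos = 1
    for row, rseq in zip(rows, removed_sequences):
        keep = row.total_start - total_pos
        out.append(core.sequence[core_pos : core_pos + keep])
        if len(rseq) != row.total_end - row.total_start + 1:
            raise ValueError(f"removed sequence length mismatch at {row.total_start}")
        out.append(rseq)
        core_pos += keep
        total_pos = row.total_end + 1
    out.append(core.sequence[core_pos:])
    return "".join(out)


def build_core_panel(
    genomes: dict[str, dict[str, AnnotatedReplicon]],
    flank_len: int = DEFAULT_FLANK,
) -> tuple[dict[str, dict[str, CoreSequence]], RemovalLedger, list[MgeSpecificity]]:
    """Classify every MGE of every strain against the panel and build cores.

    ``genomes`` maps strain -> replicon id -> AnnotatedReplicon; replicons
    correspond across strains by id.  Returns cores (same nesting), the
    combined removal ledger, and all specificity calls.
    """
    cores: dict[str, dict[str, CoreSequence]] = {}
    ledger = RemovalLedger()
    calls: list[MgeSpecificity] = []
    for strain, reps in genomes.items():
        cores[strain] = {}
        for rep_id, rep in reps.items():
            others = {
                other: g[rep_id]
                for other, g in genomes.items()
                if other != strain and rep_id in g
            }
            specs = [
                classify_specificity(rep, i, others, flank_len=flank_len)
                for i, seg in enumerate(rep.segments)
                if seg.kind == "mge"
            ]
            calls.extend(specs)
            core = build_core(rep, specs)
            cores[strain][rep_id] = core
            ledger.rows.extend(core.ledger.rows)
    return cores, ledger, calls
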