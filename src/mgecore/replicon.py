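"""Data model for annotated replicons.

A replicon is represented as an ordered mosaic of segments: unique sequence,
mobile genetic elements (MGEs, e.g. ISH2 or ISH3B insertion sequences) and the
target-site duplications (TSDs) that flank them.  Coordinates are 1-based and
inclusive throughout the package, matching the convention of published
comparison tables for these genomes.

Two text representations are supported:

* a *tagged dialect* — plain FASTA-like text in which an MGE block (with its
  TSD) is delimited by ``>>MGE type=ISH2 tsd=ACGTACGT`` / ``<<MGE`` lines, so
  mobile elements remain visually identifiable in the sequence file;
* GFF3 with ``mobile_genetic_element`` and ``target_site_duplication``
  features, TSD copies linked to their element via ``Parent``.

The module also provides the core<->total coordinate liftover used when
strain-specific MGEs are purged from a replicon: a ``CoordinateMap`` is a
sorted ledger of removed intervals, and positions are translated in either
direction (total positions inside a removed element have no core image).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class TaggedParseError(ValueError):
    """Raised on malformed tagged-dialect input; carries the line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(ValueError):
    """Raised when a replicon violates a structural invariant."""


@dataclass(frozen=True)
class Segment:
    """One piece of a replicon mosaic, 1-based inclusive interval."""

    start: int
    end: int
    kind: str  # "unique" | "mge" | "tsd"
    mge_type: Optional[str] = None  # e.g. "ISH2", set when kind == "mge"
    partner: Optional[int] = None  # index of the paired TSD segment

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def shifted(self, delta: int) -> "Segment":
        return replace(self, start=self.start + delta, end=self.end + delta)


@dataclass
class AnnotatedReplicon:
    """A replicon sequence plus its ordered segment annotation.

    Invariants (checked by :meth:`validate`):

    * segments are sorted, non-overlapping, and tile ``[1, len(sequence)]``;
    * every ``mge`` segment is flanked by a pair of ``tsd`` segments whose
      sequences are identical (TSD length may be zero, in which case no tsd
      segments are recorded);
    * circular replicons carry a rotation anchor (the current start base is
      position 1 by construction; ``rotation_offset`` records how far the
      sequence has been rotated from its original start).
    """

    id: str
    sequence: str
    topology: str = "linear"  # "linear" | "circular"
    segments: list[Segment] = field(default_factory=list)
    strain: str = ""
    rotation_offset: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            if self.sequence:
                self.segments = [Segment(1, len(self.sequence), "unique")]
        if self.topology not in ("linear", "circular"):
            raise ValidationError(f"unknown topology {self.topology!r}")

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive subsequence."""
        return self.sequence[start - 1 : end]

    @property
    def mge_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "mge"]

    def validate(self) -> None:
        n = len(self.sequence)
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValidationError(f"{self.id}: invalid characters {sorted(bad)}")
        pos = 1
        for seg in self.segments:
            if seg.start != pos:
                raise ValidationError(
                    f"{self.id}: segment tiling broken at {seg.start} (expected {pos})"
                )
            if seg.end < seg.start:
                raise ValidationError(f"{self.id}: empty segment at {seg.start}")
            pos = seg.end + 1
        if pos != n + 1:
            raise ValidationError(f"{self.id}: segments cover [1,{pos - 1}], sequence is {n} bp")
        # each MGE: flanking tsd pair with identical sequence
        for i, seg in enumerate(self.segments):
            if seg.kind != "mge":
                continue
            left = self.segments[i - 1] if i > 0 else None
            right = self.segments[i + 1] if i + 1 < len(self.segments) else None
            has_left = left is not None and left.kind == "tsd"
            has_right = right is not None and right.kind == "tsd"
            if has_left != has_right:
                raise ValidationError(f"{self.id}: unpaired TSD around MGE at {seg.start}")
            if has_left and has_right:
                a = self.slice(left.start, left.end)
                b = self.slice(right.start, right.end)
                if a != b:
                    raise ValidationError(
                        f"{self.id}: TSD pair mismatch for {seg.mge_type or 'MGE'} "
                        f"at {seg.start}: {a!r} != {b!r}"
                    )
                if "N" in a:
                    raise ValidationError(
                        f"{self.id}: N inside TSD of {seg.mge_type or 'MGE'} at {seg.start}"
                    )

    # -- rotation ----------------------------------------------------------

    def rotated(self, offset: int) -> "AnnotatedReplicon":
        """Rotate a circular replicon so that position ``offset + 1`` becomes 1."""
        if self.topology != "circular":
            raise ValidationError(f"{self.id}: cannot rotate a linear replicon")
        n = len(self.sequence)
        offset %= n
        if offset == 0:
            return self
        seq = self.sequence[offset:] + self.sequence[:offset]
        segs: list[Segment] = []
        for seg in self.segments:
            segs.append(seg.shifted(-offset))
        # re-wrap segments that fell off the front; a segment spanning the cut
        # is split in two
        out: list[Segment] = []
        for seg in segs:
            if seg.end < 1:
                out.append(seg.shifted(n))
            elif seg.start < 1 <= seg.end:
                out.append(replace(seg, start=seg.start + n, end=n))
                out.append(replace(seg, start=1, end=seg.end))
            else:
                out.append(seg)
        out.sort(key=lambda s: s.start)
        merged = _merge_adjacent_unique(out)
        return AnnotatedReplicon(
            id=self.id,
            sequence=seq,
            topology="circular",
            segments=merged,
            strain=self.strain,
            rotation_offset=(self.rotation_offset + offset) % n,
        )


def _merge_adjacent_unique(segments: list[Segment]) -> list[Segment]:
    out: list[Segment] = []
    for seg in segments:
        if out and out[-1].kind == "unique" == seg.kind and out[-1].end + 1 == seg.start:
            out[-1] = replace(out[-1], end=seg.end)
        else:
            out.append(seg)
    return out


def rotate_to_anchor(
    rep: AnnotatedReplicon, anchor: Optional[str | int] = None
) -> AnnotatedReplicon:
    """Rotate a circular replicon so the anchor starts at position 1.

    ``anchor`` may be a subsequence (must occur exactly once, searched on the
    doubled sequence so matches across the origin are found), a 1-based
    position, or None — in which case the lexicographically minimal rotation
    is chosen as a deterministic canonical form.
    """
    if rep.topology != "circular":
        raise ValidationError(f"{rep.id}: rotation requires a circular replicon")
    n = len(rep.sequence)
    if anchor is None:
        offset = _least_rotation(rep.sequence)
    elif isinstance(anchor, int):
        if not 1 <= anchor <= n:
            raise ValidationError(f"{rep.id}: anchor position {anchor} outside [1,{n}]")
        offset = anchor - 1
    else:
        doubled = rep.sequence + rep.sequence[: len(anchor) - 1]
        hits = []
        i = doubled.find(anchor)
        while i != -1:
            hits.append(i)
            i = doubled.find(anchor, i + 1)
        if len(hits) != 1:
            raise ValidationError(
                f"{rep.id}: anchor occurs {len(hits)} times (need exactly 1)"
            )
        offset = hits[0] % n
    return rep.rotated(offset)


def _least_rotation(s: str) -> int:
    """Booth's algorithm: index of the lexicographically least rotation."""
    s2 = s + s
    f = [-1] * len(s2)
    k = 0
    for j in range(1, len(s2)):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


# -- coordinate liftover ---------------------------------------------------


class NoCoreImage(LookupError):
    """Signal: a total position lies inside a removed MGE interval."""


@dataclass
class CoordinateMap:
    """Bidirectional core<->total map defined by a removal ledger.

    ``removals`` is a sorted list of ``(total_start, removed_length)`` pairs,
    1-based, non-overlapping.  ``core_length = total_length - sum(lengths)``.
    """

    total_length: int
    removals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.removals = sorted(self.removals)
        prev_end = 0
        for start, length in self.removals:
            if length <= 0:
                raise ValidationError(f"removal at {start} has length {length}")
            if start <= prev_end:
                raise ValidationError(f"overlapping removals at total position {start}")
            end = start + length - 1
            if end > self.total_length:
                raise ValidationError(f"removal [{start},{end}] exceeds total length")
            prev_end = end
        # prefix sums of removed bases up to (and including) each removal
        self._starts = [s for s, _ in self.removals]
        cum = 0
        self._cum: list[int] = []
        for _, length in self.removals:
            cum += length
            self._cum.append(cum)

    @property
    def core_length(self) -> int:
        return self.total_length - (self._cum[-1] if self._cum else 0)

    def core_to_total(self, pos: int) -> int:
        if not 1 <= pos <= self.core_length:
            raise ValidationError(f"core position {pos} outside [1,{self.core_length}]")
        # binary search: smallest shift such that pos + shift is consistent
        shift = 0
        for (start, length), cum in zip(self.removals, self._cum):
            if pos + shift >= start:
                shift = cum
            else:
                break
        return pos + shift

    def total_to_core(self, pos: int) -> int:
        if not 1 <= pos <= self.total_length:
            raise ValidationError(f"total position {pos} outside [1,{self.total_length}]")
        i = bisect.bisect_right(self._starts, pos) - 1
        if i >= 0:
            start, length = self.removals[i]
            if pos <= start + length - 1:
                raise NoCoreImage(f"total position {pos} is inside removed [{start},{start + length - 1}]")
            return pos - self._cum[i]
        return pos


def core_to_total(pos: int, cmap: CoordinateMap) -> int:
    return cmap.core_to_total(pos)


def total_to_core(pos: int, cmap: CoordinateMap) -> int:
    return cmap.total_to_core(pos)


# -- tagged dialect --------------------------------------------------------


def parse_tagged_replicon(text: str) -> AnnotatedReplicon:
    """Parse the tagged-sequence dialect into an AnnotatedReplicon.

    Format::

        >chrom topology=circular strain=63-R2
        ACGT...
        >>MGE type=ISH2 tsd=ACGTACGT
        ACGTACGT<mge sequence...>ACGTACGT
        <<MGE
        ACGT...

    The sequence lines inside an MGE block include both TSD copies (when a
    tsd is declared); the block may span several lines.
    """
    lines = text.splitlines()
    header = None
    header_line = 0
    for ln, raw in enumerate(lines, 1):
        if raw.strip():
            header = raw.strip()
            header_line = ln
            break
    if header is None or not header.startswith(">") or header.startswith(">>"):
        raise TaggedParseError("expected a '>' header line", header_line or 1)
    fields = header[1:].split()
    rep_id = fields[0] if fields else ""
    attrs = dict(f.split("=", 1) for f in fields[1:] if "=" in f)

    seq_parts: list[str] = []
    segments: list[Segment] = []
    pos = 0  # 0-based length so far
    in_mge = False
    mge_type = ""
    mge_tsd = ""
    mge_start_line = 0
    block_parts: list[str] = []

    def close_unique(upto: int, frm: int) -> None:
        if upto > frm:
            segments.append(Segment(frm + 1, upto, "unique"))

    unique_from = 0
    for ln, raw in enumerate(lines[header_line:], header_line + 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">>MGE"):
            if in_mge:
                raise TaggedParseError("nested >>MGE block", ln)
            in_mge = True
            mge_start_line = ln
            block_parts = []
            kv = dict(f.split("=", 1) for f in line[5:].split() if "=" in f)
            mge_type = kv.get("type", "MGE")
            mge_tsd = kv.get("tsd", "").upper()
        elif line.startswith("<<MGE"):
            if not in_mge:
                raise TaggedParseError("<<MGE without matching >>MGE", ln)
            block = "".join(block_parts).upper()
            t = len(mge_tsd)
            if t:
                if len(block) < 2 * t + 1:
                    raise TaggedParseError(
                        f"MGE block shorter than its two {t} bp TSD copies", mge_start_line
                    )
                if block[:t] != mge_tsd or block[-t:] != mge_tsd:
                    raise ValidationError(
                        f"TSD pair mismatch for {mge_type} at sequence position {pos + 1}: "
                        f"declared {mge_tsd!r}, found {block[:t]!r}/{block[-t:]!r}"
                    )
            close_unique(pos, unique_from)
            seq_parts.append(block)
            if t:
                segments.append(Segment(pos + 1, pos + t, "tsd"))
                segments.append(
                    Segment(pos + t + 1, pos + len(block) - t, "mge", mge_type=mge_type)
                )
                segments.append(Segment(pos + len(block) - t + 1, pos + len(block), "tsd"))
            else:
                segments.append(Segment(pos + 1, pos + len(block), "mge", mge_type=mge_type))
            pos += len(block)
            unique_from = pos
            in_mge = False
        elif line.startswith(">"):
            raise TaggedParseError("unexpected header inside replicon body", ln)
        else:
            if in_mge:
                block_parts.append(line)
            else:
                seq_parts.append(line.upper())
                pos += len(line)
    if in_mge:
        raise TaggedParseError("unterminated >>MGE block", mge_start_line)
    close_unique(pos, unique_from)
    rep = AnnotatedReplicon(
        id=rep_id,
        sequence="".join(seq_parts),
        topology=attrs.get("topology", "linear"),
        segments=segments,
        strain=attrs.get("strain", ""),
    )
    rep.validate()
    return rep


def write_tagged_replicon(rep: AnnotatedReplicon, width: int = 70) -> str:
    """Serialise to the tagged dialect; parse(write(x)) round-trips."""
    out: list[str] = []
    hdr = f">{rep.id} topology={rep.topology}"
    if rep.strain:
        hdr += f" strain={rep.strain}"
    out.append(hdr)
    i = 0
    segs = rep.segments
    while i < len(segs):
        seg = segs[i]
        if seg.kind == "unique":
            s = rep.slice(seg.start, seg.end)
            out.extend(s[j : j + width] for j in range(0, len(s), width))
            i += 1
        elif seg.kind == "tsd":
            # tsd + mge + tsd triple
            mge = segs[i + 1]
            tsd_seq = rep.slice(seg.start, seg.end)
            block = rep.slice(seg.start, segs[i + 2].end)
            out.append(f">>MGE type={mge.mge_type} tsd={tsd_seq}")
            out.extend(block[j : j + width] for j in range(0, len(block), width))
            out.append("<<MGE")
            i += 3
        else:  # bare MGE without TSD
            block = rep.slice(seg.start, seg.end)
            out.append(f">>MGE type={seg.mge_type}")
            out.extend(block[j : j + width] for j in range(0, len(block), width))
            out.append("<<MGE")
            i += 1
    return "\n".join(out) + "\n"


# -- GFF3 ------------------------------------------------------------------

MGE_FEATURE = "mobile_genetic_element"
TSD_FEATURE = "target_site_duplication"


def replicon_to_gff3(rep: AnnotatedReplicon) -> str:
    """GFF3 with MGE features and their TSD copies linked via Parent."""
    lines = ["##gff-version 3", f"##sequence-region {rep.id} 1 {len(rep)}"]
    mge_serial = 0
    i = 0
    segs = rep.segments
    while i < len(segs):
        seg = segs[i]
        if seg.kind == "tsd":
            mge = segs[i + 1]
            right = segs[i + 2]
            mge_serial += 1
            mid = f"mge{mge_serial}"
            lines.append(
                _gff_line(rep.id, MGE_FEATURE, mge.start, mge.end,
                          f"ID={mid};mge_type={mge.mge_type}")
            )
            lines.append(
                _gff_line(rep.id, TSD_FEATURE, seg.start, seg.end, f"Parent={mid}")
            )
            lines.append(
                _gff_line(rep.id, TSD_FEATURE, right.start, right.end, f"Parent={mid}")
            )
            i += 3
        elif seg.kind == "mge":
            mge_serial += 1
            lines.append(
                _gff_line(rep.id, MGE_FEATURE, seg.start, seg.end,
                          f"ID=mge{mge_serial};mge_type={seg.mge_type}")
            )
            i += 1
        else:
            i += 1
    return "\n".join(lines) + "\n"


def _gff_line(seqid: str, ftype: str, start: int, end: int, attrs: str) -> str:
    return "\t".join([seqid, "mgecore", ftype, str(start), str(end), ".", "+", ".", attrs])


def replicon_from_gff3(rep_id: str, sequence: str, gff_text: str, *,
                       topology: str = "linear", strain: str = "") -> AnnotatedReplicon:
    """Build an AnnotatedReplicon from a plain sequence plus GFF3 features."""
    mges: dict[str, tuple[int, int, str]] = {}
    tsds: dict[str, list[tuple[int, int]]] = {}
    for raw in gff_text.splitlines():
        if not raw or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) < 9 or cols[0] != rep_id:
            continue
        ftype, start, end, attrs = cols[2], int(cols[3]), int(cols[4]), cols[8]
        kv = dict(a.split("=", 1) for a in attrs.split(";") if "=" in a)
        if ftype == MGE_FEATURE:
            mges[kv.get("ID", f"mge@{start}")] = (start, end, kv.get("mge_type", "MGE"))
        elif ftype == TSD_FEATURE and "Parent" in kv:
            tsds.setdefault(kv["Parent"], []).append((start, end))
    segments: list[Segment] = []
    for mid, (ms, me, mtype) in sorted(mges.items(), key=lambda kv: kv[1][0]):
        pair = sorted(tsds.get(mid, []))
        if pair and len(pair) != 2:
            raise ValidationError(f"{rep_id}: MGE {mid} has {len(pair)} TSD copies (need 0 or 2)")
        for ts, te in pair[:1]:
            segments.append(Segment(ts, te, "tsd"))
        segments.append(Segment(ms, me, "mge", mge_type=mtype))
        for ts, te in pair[1:]:
            segments.append(Segment(ts, te, "tsd"))
    segments.sort(key=lambda s: s.start)
    # fill unique gaps
    filled: list[Segment] = []
    pos = 1
    for seg in segments:
        if seg.start > pos:
            filled.append(Segment(pos, seg.start - 1, "unique"))
        filled.append(seg)
        pos = seg.end + 1
    if pos <= len(sequence):
        filled.append(Segment(pos, len(sequence), "unique"))
    rep = AnnotatedReplicon(
        id=rep_id, sequence=sequence.upper(), topology=topology,
        segments=filled, strain=strain,
    )
    rep.validate()
    return rep


# -- FASTA helpers ---------------------------------------------------------


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    seqio_write(recs, str(path), "fasta")


def read_fasta(path) -> Iterator[tuple[str, str]]:
    from Bio.SeqIO import parse as seqio_parse

    for rec in seqio_parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()
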