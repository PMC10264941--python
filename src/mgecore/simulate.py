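"""Strain-evolution simulator with exact ground truth.

Builds an ancestral multi-replicon genome (one ~2 Mb chromosome plus
circular plasmids with the repeat architecture typical of haloarchaeal
megaplasmids: a long inverted duplication, an inter-plasmid duplicated
block), derives strains through a vocabulary of structural events recorded
in an :class:`EventLog`, and samples long reads with per-read origin
records.  Every downstream stage of the pipeline — core building, HSP
tiling, break classification, subassembly walking — can therefore be tested
against exact planted truth without any external data.

Canonicalisation choices make the planted truth well defined; they are
applied when *sampling* event loci, never when interpreting events:

* insertion and replacement payloads have their terminal bases forced to
  mismatch the opposing junction context, and deletion/duplication
  endpoints are chosen without junction microhomology — otherwise any local
  aligner (ours, Smith-Waterman, BLAST alike) may extend a few lucky bases
  across a junction and the "true" break coordinate becomes ambiguous;
* MGE insertion sites are accepted only if the target-site duplication is
  recoverable exactly (the longest flanking direct repeat equals the
  planted TSD), so TSD-length recovery against the planting record is a
  sharp oracle rather than a probabilistic one.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from typing import Optional

from .breaks import BreakEvent, _make_event
from .replicon import AnnotatedReplicon, Segment, revcomp

BASES = "ACGT"


def _rand_seq(rng: random.Random, n: int, gc: float = 0.65) -> str:
    g = gc / 2
    a = (1 - gc) / 2
    return "".join(rng.choices("ACGT", weights=[a, g, g, a], k=n))


# -- events ----------------------------------------------------------------

EVENT_KINDS = {
    "point_mutation",
    "sequence_insert",
    "deletion",
    "deletion_coupled_insertion",
    "tandem_duplication",
    "mge_insert",
    "mge_excise",
    "repeat_mediated_deletion",
    "inverted_dup_create",
    "inverted_dup_extend",
    "plasmid_duplicate",
    "plasmid_concatenate",
    "plasmid_drop",
    "chromosomal_integration",
}


@dataclass
class Event:
    """One planted evolutionary operation.

    ``params`` use 1-based coordinates valid at application time (events are
    interpreted strictly in log order).
    """

    kind: str
    replicon: str
    params: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {"kind": self.kind, "replicon": self.replicon, "params": self.params}


@dataclass
class EventLog:
    events: list[Event] = field(default_factory=list)
    seed: Optional[int] = None

    def append(self, ev: Event) -> None:
        self.events.append(ev)

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "events": [e.to_json() for e in self.events]}, indent=1
        )

    @classmethod
    def from_json(cls, text: str) -> "EventLog":
        obj = json.loads(text)
        return cls(
            events=[Event(e["kind"], e["replicon"], e["params"]) for e in obj["events"]],
            seed=obj.get("seed"),
        )


class EventConflictError(ValueError):
    """An event touches coordinates altered/removed by an earlier event."""


@dataclass
class _Rep:
    """Mutable replicon state inside the interpreter."""

    sequence: str
    topology: str
    mges: list[tuple[int, int, int, str]] = field(default_factory=list)
    # (element_start, element_end, tsd_len, mge_type); TSD copies flank it

    def shift_annotations(self, pos: int, delta: int, source: str) -> None:
        out = []
        for ms, me, t, typ in self.mges:
            lo = ms - t
            hi = me + t
            if lo > pos:
                out.append((ms + delta, me + delta, t, typ))
            elif hi <= pos:
                out.append((ms, me, t, typ))
            else:
                raise EventConflictError(
                    f"event {source} cuts through MGE {typ} at [{ms},{me}]"
                )
        self.mges = out

    def check_span_free(self, start: int, end: int, source: str) -> None:
        for ms, me, t, typ in self.mges:
            if not (end < ms - t or start > me + t):
                raise EventConflictError(
                    f"event {source} overlaps MGE {typ} at [{ms},{me}]"
                )


def apply_events(
    genome: dict[str, AnnotatedReplicon],
    log: EventLog,
    strain: str = "",
) -> dict[str, AnnotatedReplicon]:
    """Replay an event log on a genome; a pure function of its inputs."""
    state: dict[str, _Rep] = {}
    for rid, rep in genome.items():
        mges = []
        segs = rep.segments
        for i, seg in enumerate(segs):
            if seg.kind == "mge":
                t = segs[i + 1].length if i + 1 < len(segs) and segs[i + 1].kind == "tsd" else 0
                mges.append((seg.start, seg.end, t, seg.mge_type or "MGE"))
        state[rid] = _Rep(rep.sequence, rep.topology, mges)
    for ev in log.events:
        _apply_one(state, ev)
    return {rid: _rep_to_annotated(rid, st, strain) for rid, st in state.items()}


def _rep_to_annotated(rid: str, st: _Rep, strain: str) -> AnnotatedReplicon:
    segments: list[Segment] = []
    pos = 1
    for ms, me, t, typ in sorted(st.mges):
        lo = ms - t
        if lo > pos:
            segments.append(Segment(pos, lo - 1, "unique"))
        if t:
            segments.append(Segment(lo, ms - 1, "tsd"))
        segments.append(Segment(ms, me, "mge", mge_type=typ))
        if t:
            segments.append(Segment(me + 1, me + t, "tsd"))
        pos = me + t + 1
    if pos <= len(st.sequence):
        segments.append(Segment(pos, len(st.sequence), "unique"))
    rep = AnnotatedReplicon(
        id=rid, sequence=st.sequence, topology=st.topology,
        segments=segments, strain=strain,
    )
    rep.validate()
    return rep


def _apply_one(state: dict[str, _Rep], ev: Event) -> None:
    kind, rid, p = ev.kind, ev.replicon, ev.params
    if kind not in EVENT_KINDS:
        raise ValueError(f"unknown event kind {kind!r}")
    src = f"{kind}@{rid}"
    if kind == "plasmid_duplicate":
        st = state[rid]
        state[p["new_name"]] = _Rep(st.sequence, st.topology, list(st.mges))
        return
    if kind == "plasmid_drop":
        del state[rid]
        return
    if kind == "plasmid_concatenate":
        a, b = state[rid], state[p["other"]]
        joined = _Rep(a.sequence + b.sequence, "circular", list(a.mges))
        off = len(a.sequence)
        joined.mges += [(ms + off, me + off, t, typ) for ms, me, t, typ in b.mges]
        state[p["new_name"]] = joined
        return
    if kind == "chromosomal_integration":
        chrom = state[p["target"]]
        plas = state[rid]
        pos = p["position"]
        chrom.check_span_free(pos, pos + 1, src)
        chrom.shift_annotations(pos, len(plas.sequence), src)
        chrom.sequence = chrom.sequence[:pos] + plas.sequence + chrom.sequence[pos:]
        chrom.mges += [(ms + pos, me + pos, t, typ) for ms, me, t, typ in plas.mges]
        del state[rid]
        return
    st = state[rid]
    seq = st.sequence
    if kind == "point_mutation":
        pos, base = p["position"], p["base"]
        if seq[pos - 1] == base:
            raise EventConflictError(f"{src}: position {pos} already {base}")
        st.sequence = seq[: pos - 1] + base + seq[pos:]
    elif kind == "sequence_insert":
        pos, payload = p["position"], p["payload"]
        st.check_span_free(pos, pos + 1, src)
        st.shift_annotations(pos, len(payload), src)
        st.sequence = seq[:pos] + payload + seq[pos:]
    elif kind == "deletion":
        start, end = p["start"], p["end"]
        st.check_span_free(start, end, src)
        st.shift_annotations(end, -(end - start + 1), src)
        st.sequence = seq[: start - 1] + seq[end:]
    elif kind == "deletion_coupled_insertion":
        start, end, payload = p["start"], p["end"], p["payload"]
        st.check_span_free(start, end, src)
        st.shift_annotations(end, len(payload) - (end - start + 1), src)
        st.sequence = seq[: start - 1] + payload + seq[end:]
    elif kind == "tandem_duplication":
        start, end = p["start"], p["end"]
        st.check_span_free(start, end, src)
        span = seq[start - 1 : end]
        st.shift_annotations(end, len(span), src)
        st.sequence = seq[:end] + span + seq[end:]
    elif kind == "mge_insert":
        pos, t = p["position"], p["tsd_len"]
        element, typ = p["element"], p["mge_type"]
        st.check_span_free(pos - t + 1, pos + 1, src)
        # duplicate the t target bases ending at pos; element sits between
        st.shift_annotations(pos, len(element) + t, src)
        tsd = seq[pos - t : pos]
        st.sequence = seq[:pos] + element + tsd + seq[pos:]
        st.mges.append((pos + 1, pos + len(element), t, typ))
        st.mges.sort()
    elif kind == "mge_excise":
        start, end = p["start"], p["end"]  # element interval
        hit = [u for u in st.mges if (u[0], u[1]) == (start, end)]
        if not hit:
            raise EventConflictError(f"{src}: no MGE annotated at [{start},{end}]")
        ms, me, t, typ = hit[0]
        st.mges.remove(hit[0])
        st.shift_annotations(me + t, -(me + t - ms + 1), src)
        st.sequence = seq[: ms - 1] + seq[me + t :]
    elif kind == "repeat_mediated_deletion":
        r1, r2 = p["repeat1_start"], p["repeat2_start"]
        rl = p["repeat_len"]
        if seq[r1 - 1 : r1 - 1 + rl] != seq[r2 - 1 : r2 - 1 + rl]:
            raise EventConflictError(f"{src}: repeat copies at {r1}/{r2} differ")
        st.check_span_free(r1, r2 - 1, src)
        st.shift_annotations(r2 - 1, -(r2 - r1), src)
        # remove the span between the two copy starts, leaving one copy
        st.sequence = seq[: r1 - 1] + seq[r2 - 1 :]
    elif kind in ("inverted_dup_create", "inverted_dup_extend"):
        s0, e0, after = p["src_start"], p["src_end"], p["insert_after"]
        payload = revcomp(seq[s0 - 1 : e0])
        st.check_span_free(after, after + 1, src)
        st.shift_annotations(after, len(payload), src)
        st.sequence = seq[:after] + payload + seq[after:]
    else:  # pragma: no cover
        raise AssertionError(kind)


# -- ancestor construction --------------------------------------------------


@dataclass
class AncestorSpec:
    """Parameters of the ancestral genome.

    Defaults follow the study conditions this generator emulates: one ~2 Mb
    chromosome at 65 % GC with a 61 kb AT-rich island, four plasmids between
    43 and 235 kb, a 16 kb block duplicated between two plasmids, and a long
    inverted duplication (32 kb core, extended to 40 kb arms) with the two
    repeat-bearing plasmids sharing one contiguous cassette.
    """

    chromosome_length: int = 2_000_000
    gc: float = 0.65
    at_island: Optional[tuple[int, int]] = (800_001, 61_000)  # (start, length)
    at_island_gc: float = 0.45
    inv_core: int = 32_000  # inverted-repeat core arm
    inv_extension: int = 8_000  # extension distinguishing the 40 kb arms
    shared_block: int = 16_000  # block duplicated across two plasmids
    p_a_length: int = 235_000
    p_a_unique1: int = 60_000  # pA region upstream of its copy of the block
    p_a_spacer: int = 5_000  # spacer between pA's core-length inverted arms
    p_c_unique: int = 60_000  # unique region of the 190 kb-class plasmid
    p_c_spacer: int = 50_000  # spacer between its arms (carries the block)
    p_b_unique: int = 99_000  # unique region of the 229 kb-class plasmid
    p_d_length: int = 43_000
    seed: int = 0


@dataclass
class Ancestor:
    genome: dict[str, AnnotatedReplicon]
    spec: AncestorSpec
    arm40: str = ""  # extended arm sequence (core + extension)
    cassette: str = ""  # contiguous duplication shared by pB and pC
    block16: str = ""  # inter-plasmid duplicated block
    landmarks: dict = field(default_factory=dict)


def make_ancestor(spec: Optional[AncestorSpec] = None) -> Ancestor:
    """Deterministically build the ancestral genome for a spec.

    The 190 kb-class plasmid (pC) is unique sequence followed by a cassette
    ``arm40 + spacer + revcomp(arm40)``; the 229 kb-class plasmid (pB)
    carries its own unique sequence followed by the *same* cassette, so the
    duplication shared between the two plasmids is one contiguous region —
    the configuration that blocks read assembly but allows in-silico
    completion from the sibling plasmid.
    """
    spec = spec or AncestorSpec()
    if min(
        spec.chromosome_length, spec.inv_core, spec.shared_block,
        spec.p_a_length, spec.p_c_unique, spec.p_c_spacer, spec.p_b_unique,
        spec.p_d_length,
    ) <= 0:
        raise ValueError("all lengths must be positive")
    if spec.shared_block >= spec.p_c_spacer:
        raise ValueError("shared block does not fit into the arm spacer")
    ua2 = (
        spec.p_a_length - spec.p_a_unique1 - spec.shared_block
        - 2 * spec.inv_core - spec.p_a_spacer
    )
    if ua2 < 2_000:
        raise ValueError("plasmid A cannot hold its block and inverted arms")
    rng = random.Random(spec.seed)
    chrom = _rand_seq(rng, spec.chromosome_length, spec.gc)
    if spec.at_island is not None:
        s0, ln = spec.at_island
        if s0 + ln - 1 > spec.chromosome_length:
            raise ValueError("AT island outside the chromosome")
        chrom = chrom[: s0 - 1] + _rand_seq(rng, ln, spec.at_island_gc) + chrom[s0 - 1 + ln :]
    core = _rand_seq(rng, spec.inv_core, spec.gc)
    ext = _rand_seq(rng, spec.inv_extension, spec.gc)
    arm40 = core + ext
    block16 = _rand_seq(rng, spec.shared_block, spec.gc)
    pad = (spec.p_c_spacer - spec.shared_block) // 2
    spacer = (
        _rand_seq(rng, pad, spec.gc)
        + block16
        + _rand_seq(rng, spec.p_c_spacer - spec.shared_block - pad, spec.gc)
    )
    # the planted arm length must be exact truth: a spacer whose first base
    # complements its last would extend the maximal inverted match by chance
    while spacer[0] == revcomp(spacer[-1]):
        spacer = _rand_seq(rng, 1, spec.gc) + spacer[1:]
    cassette = arm40 + spacer + revcomp(arm40)
    p_c = _rand_seq(rng, spec.p_c_unique, spec.gc) + cassette
    p_b = _rand_seq(rng, spec.p_b_unique, spec.gc) + cassette
    # pA carries one copy of the 16 kb block plus the *core-length* (32 kb
    # class) inverted pair — the unextended arm version of the family
    ua1 = spec.p_a_unique1
    pa_spacer = _rand_seq(rng, spec.p_a_spacer, spec.gc)
    while pa_spacer[0] == revcomp(pa_spacer[-1]):
        pa_spacer = _rand_seq(rng, 1, spec.gc) + pa_spacer[1:]
    p_a = (
        _rand_seq(rng, ua1, spec.gc)
        + block16
        + _rand_seq(rng, ua2, spec.gc)
        + core
        + pa_spacer
        + revcomp(core)
    )
    p_d = _rand_seq(rng, spec.p_d_length, spec.gc)
    genome = {
        "chromosome": AnnotatedReplicon(id="chromosome", sequence=chrom, topology="linear"),
        "pA": AnnotatedReplicon(id="pA", sequence=p_a, topology="circular"),
        "pB": AnnotatedReplicon(id="pB", sequence=p_b, topology="circular"),
        "pC": AnnotatedReplicon(id="pC", sequence=p_c, topology="circular"),
        "pD": AnnotatedReplicon(id="pD", sequence=p_d, topology="circular"),
    }
    landmarks = {
        "pC_cassette": (spec.p_c_unique + 1, len(p_c)),
        "pB_cassette": (spec.p_b_unique + 1, len(p_b)),
        "pC_arm1": (spec.p_c_unique + 1, spec.p_c_unique + len(arm40)),
        "pC_arm2": (len(p_c) - len(arm40) + 1, len(p_c)),
        "pB_arm1": (spec.p_b_unique + 1, spec.p_b_unique + len(arm40)),
        "pB_arm2": (len(p_b) - len(arm40) + 1, len(p_b)),
        "pA_block": (ua1 + 1, ua1 + spec.shared_block),
        "pA_arm1": (ua1 + spec.shared_block + ua2 + 1,
                    ua1 + spec.shared_block + ua2 + spec.inv_core),
        "pA_arm2": (len(p_a) - spec.inv_core + 1, len(p_a)),
    }
    return Ancestor(genome=genome, spec=spec, arm40=arm40, cassette=cassette,
                    block16=block16, landmarks=landmarks)


# -- MGE library -----------------------------------------------------------

MGE_LIBRARY = {
    "ISH2": 720,
    "ISH3B": 1_389,
    "ISH4": 1_450,
    "ISH8": 2_900,
}


def _longest_flanking_repeat(seq: str, ms: int, me: int, max_len: int = 25) -> int:
    best = 0
    for t in range(1, min(max_len, ms - 1, len(seq) - me) + 1):
        if seq[ms - 1 - t : ms - 1] == seq[me : me + t]:
            best = t
    return best


def _tsd_recoverable(anc: str, pos: int, elem: str, tsd: int) -> bool:
    """Would find_tsd recover exactly ``tsd`` at this planting site?"""
    w = 40
    lo = max(0, pos - tsd - w)
    local = anc[lo:pos] + elem + anc[pos - tsd : pos] + anc[pos : pos + w]
    ms = (pos - lo) + 1  # element start, 1-based within local
    me = ms + len(elem) - 1
    return _longest_flanking_repeat(local, ms, me + tsd) == 0 and _longest_flanking_repeat(
        local, ms, me
    ) == tsd


# -- strain derivation with exact truth -------------------------------------


@dataclass
class PlantedIndel:
    """A non-mobilome structural difference in ancestor coordinates."""

    strain: str
    replicon: str
    kind: str  # insertion | deletion | replacement | tandem_duplication
    anc_start: int  # insertion: base before the payload; else first base
    anc_end: int  # deletions/replacements/duplications: last affected base
    payload_len: int = 0

    @property
    def span(self) -> int:
        return self.anc_end - self.anc_start + 1

    @property
    def delta(self) -> int:
        if self.kind == "insertion":
            return self.payload_len
        if self.kind == "deletion":
            return -self.span
        if self.kind == "replacement":
            return self.payload_len - self.span
        if self.kind == "tandem_duplication":
            return self.span
        raise ValueError(self.kind)


@dataclass
class PlantedMge:
    strain: str
    replicon: str
    mge_type: str
    anc_position: int  # insertion point in ancestor coordinates
    element_len: int
    tsd_len: int
    final_interval: tuple[int, int] = (0, 0)  # element span in derived genome
    final_removal: tuple[int, int] = (0, 0)  # element + downstream TSD copy


@dataclass
class Scenario:
    """A derived strain panel with full ground truth."""

    ancestor: Ancestor
    strains: dict[str, dict[str, AnnotatedReplicon]]
    logs: dict[str, EventLog]
    mges: list[PlantedMge]
    indels: list[PlantedIndel]
    seed: int

    def expected_breaks(self, strain_q: str, strain_s: str,
                        replicon: str = "chromosome") -> list[BreakEvent]:
        ev_q = [i for i in self.indels if i.strain == strain_q and i.replicon == replicon]
        ev_s = [i for i in self.indels if i.strain == strain_s and i.replicon == replicon]
        return expected_pairwise_breaks(ev_q, ev_s)


def expected_pairwise_breaks(
    events_q: list[PlantedIndel], events_s: list[PlantedIndel]
) -> list[BreakEvent]:
    """Project planted indels of two strains into expected break events.

    Events must sit at disjoint ancestor loci.  Coordinates come out in the
    core frames of the two derived strains (ancestor plus own indels; MGEs
    are removed by core construction).  Pure interval arithmetic —
    independent of any alignment path.
    """
    tagged = [("q", e) for e in events_q] + [("s", e) for e in events_s]
    tagged.sort(key=lambda t: t[1].anc_start)
    qoff = soff = 0
    out: list[BreakEvent] = []
    for side, e in tagged:
        if e.kind == "insertion":
            own_g, oth_g = e.payload_len, 0
            own_prev, oth_prev = e.anc_start, e.anc_start
        elif e.kind == "deletion":
            own_g, oth_g = 0, e.span
            own_prev, oth_prev = e.anc_start - 1, e.anc_start - 1
        elif e.kind == "replacement":
            own_g, oth_g = e.payload_len, e.span
            own_prev, oth_prev = e.anc_start - 1, e.anc_start - 1
        elif e.kind == "tandem_duplication":
            # the aligner splits at the end of the first copy on the carrier
            # and re-enters at the copy start on the other genome (overlap)
            own_g, oth_g = 0, -e.span
            own_prev, oth_prev = e.anc_end, e.anc_end
        else:
            raise ValueError(e.kind)
        if side == "q":
            qg, sg = own_g, oth_g
            q_prev, s_prev = own_prev + qoff, oth_prev + soff
            qoff += e.delta
        else:
            qg, sg = oth_g, own_g
            q_prev, s_prev = oth_prev + qoff, own_prev + soff
            soff += e.delta
        out.append(
            _make_event(qg, sg, q_prev, q_prev + qg + 1, s_prev, s_prev + sg + 1, None)
        )
    return out


def _clean_payload(rng: random.Random, anc: str, left_last0: int, right_first0: int,
                   length: int, gc: float) -> str:
    """Random payload whose terminal bases mismatch the junction context.

    The payload replaces ``anc[left_last0:right_first0]`` (0-based, empty
    for a pure insertion).  Its first three bases must differ from what the
    *other* genome continues with at the left junction (the replaced span,
    or the retained right flank for an insertion), and its last three from
    what precedes the right junction — so no flanking HSP can extend into
    the payload and the break coordinates are exact.
    """
    payload = list(_rand_seq(rng, length, gc))
    left_opp = anc[left_last0:] if right_first0 > left_last0 else anc[right_first0:]
    right_opp = anc[:right_first0] if right_first0 > left_last0 else anc[:left_last0]
    for i in range(min(3, length)):
        while left_opp and i < len(left_opp) and payload[i] == left_opp[i]:
            payload[i] = rng.choice(BASES)
        if len(right_opp) > i:
            while payload[length - 1 - i] == right_opp[-1 - i]:
                payload[length - 1 - i] = rng.choice(BASES)
    return "".join(payload)


def _junction_clean(anc: str, left_last0: int, right_first0: int, k: int = 3) -> bool:
    """No k-bp microhomology at a deletion/duplication junction (0-based)."""
    for i in range(k):
        if right_first0 + i < len(anc) and left_last0 + i < len(anc):
            if anc[left_last0 + i] == anc[right_first0 + i]:
                return False
        if left_last0 - 1 - i >= 0 and right_first0 - 1 - i >= 0:
            if anc[left_last0 - 1 - i] == anc[right_first0 - 1 - i]:
                return False
    return True


def _derive_strain(
    strain: str,
    ancestor: Ancestor,
    indels: list[PlantedIndel],
    mge_plants: list[tuple[str, int, str, str, int]],
    payloads: dict,
) -> tuple[dict[str, AnnotatedReplicon], EventLog, list[PlantedMge]]:
    """Apply indels then MGE insertions sampled in ancestor coordinates.

    Events on one replicon are applied in descending coordinate order, so
    the recorded (application-time) coordinates equal ancestor coordinates
    for the indels; MGE positions are lifted over same-replicon indels.
    """
    log = EventLog(seed=0)

    def indel_shift(rid: str, anc_pos: int) -> int:
        return sum(i.delta for i in indels if i.replicon == rid and i.anc_start < anc_pos)

    for ind in sorted(indels, key=lambda i: -i.anc_start):
        if ind.kind == "insertion":
            log.append(Event("sequence_insert", ind.replicon, {
                "position": ind.anc_start,
                "payload": payloads[(strain, ind.replicon, ind.anc_start)],
            }))
        elif ind.kind == "deletion":
            log.append(Event("deletion", ind.replicon,
                             {"start": ind.anc_start, "end": ind.anc_end}))
        elif ind.kind == "replacement":
            log.append(Event("deletion_coupled_insertion", ind.replicon, {
                "start": ind.anc_start, "end": ind.anc_end,
                "payload": payloads[(strain, ind.replicon, ind.anc_start)],
            }))
        elif ind.kind == "tandem_duplication":
            log.append(Event("tandem_duplication", ind.replicon,
                             {"start": ind.anc_start, "end": ind.anc_end}))
        else:
            raise ValueError(ind.kind)
    planted: list[PlantedMge] = []
    for rid, anc_pos, typ, elem, tsd in sorted(mge_plants, key=lambda t: -t[1]):
        log.append(Event("mge_insert", rid, {
            "position": anc_pos + indel_shift(rid, anc_pos),
            "tsd_len": tsd, "element": elem, "mge_type": typ,
        }))
        planted.append(PlantedMge(
            strain=strain, replicon=rid, mge_type=typ, anc_position=anc_pos,
            element_len=len(elem), tsd_len=tsd,
        ))
    genome = apply_events(ancestor.genome, log, strain=strain)
    # final coordinates: ancestor position + shifts from indels and from
    # other MGE insertions of the same replicon at smaller positions
    for pm in planted:
        shift = indel_shift(pm.replicon, pm.anc_position)
        shift += sum(
            q.element_len + q.tsd_len
            for q in planted
            if q.replicon == pm.replicon and q.anc_position < pm.anc_position
        )
        start = pm.anc_position + shift + 1
        pm.final_interval = (start, start + pm.element_len - 1)
        pm.final_removal = (start, start + pm.element_len - 1 + pm.tsd_len)
    return genome, log, planted


# -- the default scenario ---------------------------------------------------

STRAINS = ("A", "B", "C")

# non-mobilome chromosomal differences planted per strain; sizes span the
# published break classes: the tens-of-bp duplication class, short (<2 kb),
# long (3.2-9.4 kb), and replacements including an isopositioned AT-island
# style swap (47 kb replaced by 61 kb)
INDEL_PLAN = {
    "A": [("insertion", 9_476), ("tandem_duplication", 38)],
    "B": [("deletion", 1_500), ("replacement", (2_300, 4_100))],
    "C": [("deletion", 423), ("insertion", 5_000), ("replacement", (47_000, 61_000))],
}

# chromosomal strain-specific insertions; two more are planted on plasmids
# (one on A/pA, one on B/pC) for 15 strain-specific MGEs in total
MGE_PLAN = {"A": 5, "B": 4, "C": 4}
POINT_MUTATIONS = 120  # per strain, chromosome


def figure4_scenario(seed: int = 0, spec: Optional[AncestorSpec] = None) -> Scenario:
    """Derive the default three-strain panel with full ground truth.

    Strain A plays the focal (ancestral-isolate) role; B and C the derived
    laboratory-twin roles.  Chromosomes differ by 15 strain-specific MGE
    insertions, point-mutation clouds and the planted indel plan; plasmids
    differ by MGEs only (one on A/pA, one on B/pC), so plasmid cores stay
    identical across strains — the single full-length HSP outcome class.
    """
    spec = spec or AncestorSpec(seed=seed)
    ancestor = make_ancestor(spec)
    rng = random.Random(seed * 1_000_003 + 17)
    anc_chrom = ancestor.genome["chromosome"].sequence
    n = len(anc_chrom)

    reserved: list[tuple[int, int]] = []  # event intervals, 1-based
    if spec.at_island:
        s0, ln = spec.at_island
        reserved.append((s0 - 5_000, s0 + ln + 5_000))

    def reserve(span: int, gap: int = 20_000) -> int:
        for _ in range(10_000):
            pos = rng.randrange(60_000, n - 60_000 - span)
            if all(pos - gap > hi or pos + span + gap < lo for lo, hi in reserved):
                reserved.append((pos, pos + span))
                return pos
        raise RuntimeError("could not place a locus")

    indels: list[PlantedIndel] = []
    payloads: dict = {}
    for strain in STRAINS:
        for kind, size in INDEL_PLAN[strain]:
            if kind == "insertion":
                pos = reserve(10)
                payload = _clean_payload(rng, anc_chrom, pos, pos, size, spec.gc)
                indels.append(PlantedIndel(strain, "chromosome", "insertion",
                                           pos, pos, size))
                payloads[(strain, "chromosome", pos)] = payload
            elif kind == "deletion":
                pos = reserve(size + 10)
                while not _junction_clean(anc_chrom, pos - 1, pos - 1 + size):
                    pos += 1
                indels.append(PlantedIndel(strain, "chromosome", "deletion",
                                           pos, pos + size - 1))
            elif kind == "replacement":
                del_len, ins_len = size
                pos = reserve(del_len + 10)
                payload = _clean_payload(rng, anc_chrom, pos - 1, pos - 1 + del_len,
                                         ins_len, spec.gc)
                indels.append(PlantedIndel(strain, "chromosome", "replacement",
                                           pos, pos + del_len - 1, ins_len))
                payloads[(strain, "chromosome", pos)] = payload
            elif kind == "tandem_duplication":
                pos = reserve(size + 10)
                while not _junction_clean(anc_chrom, pos - 1, pos - 1 + size):
                    pos += 1
                indels.append(PlantedIndel(strain, "chromosome", "tandem_duplication",
                                           pos, pos + size - 1))
            else:
                raise ValueError(kind)

    def plant_mge(rid: str, anc_seq: str, pos_sampler) -> tuple[str, int, str, str, int]:
        for _ in range(200):
            pos = pos_sampler()
            typ = rng.choice(sorted(MGE_LIBRARY))
            elem = _rand_seq(rng, MGE_LIBRARY[typ], spec.gc)
            tsd = rng.randint(4, 20)
            if _tsd_recoverable(anc_seq, pos, elem, tsd):
                return (rid, pos, typ, elem, tsd)
        raise RuntimeError("could not plant a recoverable MGE")

    mge_plants: dict[str, list] = {s: [] for s in STRAINS}
    for strain in STRAINS:
        for _ in range(MGE_PLAN[strain]):
            mge_plants[strain].append(
                plant_mge("chromosome", anc_chrom, lambda: reserve(30))
            )
    # one plasmid MGE each for A (pA) and B (pC), placed in unique regions
    # well away from duplicated blocks and arm boundaries
    blk = ancestor.landmarks["pA_block"]
    mge_plants["A"].append(plant_mge(
        "pA", ancestor.genome["pA"].sequence,
        lambda: rng.randrange(5_000, blk[0] - 10_000),
    ))
    mge_plants["B"].append(plant_mge(
        "pC", ancestor.genome["pC"].sequence,
        lambda: rng.randrange(5_000, spec.p_c_unique - 10_000),
    ))

    strains: dict[str, dict[str, AnnotatedReplicon]] = {}
    logs: dict[str, EventLog] = {}
    planted_mges: list[PlantedMge] = []
    for strain in STRAINS:
        own = [i for i in indels if i.strain == strain]
        genome, log, planted = _derive_strain(
            strain, ancestor, own, mge_plants[strain], payloads
        )
        log.seed = seed
        # point mutations: anywhere on the chromosome at least 2 kb from any
        # reserved event interval (mutual closeness is harmless — they are
        # plain mismatches inside HSPs)
        muts = []
        used: set[int] = set()
        while len(muts) < POINT_MUTATIONS:
            pos = rng.randrange(10_000, n - 10_000)
            if pos in used:
                continue
            if any(lo - 2_000 < pos < hi + 2_000 for lo, hi in reserved):
                continue
            used.add(pos)
            shift = sum(i.delta for i in own if i.anc_start < pos)
            shift += sum(
                pm.element_len + pm.tsd_len
                for pm in planted
                if pm.replicon == "chromosome" and pm.anc_position < pos
            )
            seq = genome["chromosome"].sequence
            base = seq[pos + shift - 1]
            muts.append(Event("point_mutation", "chromosome",
                              {"position": pos + shift, "base": rng.choice(
                                  [b for b in BASES if b != base])}))
        mut_log = EventLog(events=muts, seed=seed)
        genome = apply_events(genome, mut_log, strain=strain)
        log.events.extend(muts)
        strains[strain] = genome
        logs[strain] = log
        planted_mges.extend(planted)
    return Scenario(
        ancestor=ancestor, strains=strains, logs=logs,
        mges=planted_mges, indels=indels, seed=seed,
    )


# -- read simulation --------------------------------------------------------


@dataclass
class ReadOrigin:
    read_id: str
    replicon: str
    start: int  # 1-based start on the forward strand
    length: int
    strand: str


@dataclass
class SimulatedReads:
    reads: list[tuple[str, str]]
    origins: list[ReadOrigin]


def simulate_reads(
    genome: dict[str, AnnotatedReplicon],
    mean_len: int = 3_000,
    len_sd: float = 0.0,
    depth: float = 20.0,
    error_rate: float = 0.0,
    seed: int = 0,
    replicons: Optional[list[str]] = None,
) -> SimulatedReads:
    """Sample long reads with recorded origins.

    Read lengths are log-normal truncated to [500, 25,000]; ``len_sd`` is
    the standard deviation in bp (0 gives constant-length reads).  Circular
    replicons are sampled across the origin.  ``error_rate`` applies uniform
    substitutions; 0 gives exact substrings of the truth.
    """
    rng = random.Random(seed)
    reads: list[tuple[str, str]] = []
    origins: list[ReadOrigin] = []
    if depth < 1:
        raise ValueError("depth must be >= 1")
    for rid in sorted(replicons or genome):
        rep = genome[rid]
        L = len(rep)
        if mean_len >= L:
            raise ValueError(f"mean read length {mean_len} >= replicon {rid} ({L} bp)")
        n_reads = max(1, round(depth * L / mean_len))
        doubled = rep.sequence + rep.sequence if rep.topology == "circular" else rep.sequence
        for k in range(n_reads):
            if len_sd > 0:
                sigma2 = math.log(1 + (len_sd / mean_len) ** 2)
                mu = math.log(mean_len) - sigma2 / 2
                ln = int(rng.lognormvariate(mu, math.sqrt(sigma2)))
                ln = max(500, min(25_000, ln, L - 1))
            else:
                ln = mean_len
            if rep.topology == "circular":
                start0 = rng.randrange(L)
            else:
                start0 = rng.randrange(L - ln + 1)
            seq = doubled[start0 : start0 + ln]
            strand = rng.choice("+-")
            if strand == "-":
                seq = revcomp(seq)
            if error_rate > 0:
                chars = list(seq)
                for i in range(len(chars)):
                    if rng.random() < error_rate:
                        chars[i] = rng.choice([b for b in BASES if b != chars[i]])
                seq = "".join(chars)
            read_id = f"{rid}_r{k}"
            reads.append((read_id, seq))
            origins.append(ReadOrigin(read_id, rid, start0 + 1, ln, strand))
    return SimulatedReads(reads=reads, origins=origins)
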