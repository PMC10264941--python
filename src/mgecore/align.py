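"""Internal pairwise HSP engine.

Implements BLASTn-style gapped local alignment blocks (HSPs) for pairs of
near-identical replicons via seed -> chain -> extend:

1. exact k-mer seed matches are found with a vectorised hash index,
2. seeds on compatible diagonals are merged into maximal exact segments and
   chained when separated by at most ``max_gap`` on both sequences,
3. inter-segment regions are aligned with an affine-gap (Gotoh) DP fill and
   chain ends are extended with a banded x-drop DP, keeping the
   maximum-scoring endpoint.

Scoring is megablast-like: match +1, mismatch -2, gap open -5 (surcharge per
gap event), gap extension -2 per gap column.  Identity display follows the
convention of the published comparison tables these genomes are described
with: the percentage is *truncated* (not rounded) at two decimals, so
506,862/506,880 prints as 99.99 and only a perfect block prints 100.00.
The aggregate over a whole comparison is a summary statistic and uses
conventional half-up rounding (1,844,079/1,850,787 -> 99.64).

Both strands are searched; minus-strand HSPs carry subject coordinates on the
forward strand with ``strand == "-"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .replicon import revcomp

# -- identity bookkeeping --------------------------------------------------


def identity_display(match_bases: int, total_columns: int) -> float:
    """Percent identity truncated (floored) at two decimals.

    Truncation is deliberate: it reproduces printed cells that rounding
    contradicts (e.g. 48,433/48,453 -> 99.95, not 99.96) and guarantees that
    100.00 is shown iff every column matches.
    """
    if total_columns <= 0:
        raise ValueError("total_columns must be positive")
    if not 0 <= match_bases <= total_columns:
        raise ValueError("need 0 <= match_bases <= total_columns")
    return (match_bases * 10_000 // total_columns) / 100.0


def hsp_stats(match_bases: int, total_columns: int, gap_chars: int = 0) -> float:
    """Identity display for one HSP (gap columns count toward the total)."""
    if gap_chars < 0 or gap_chars > total_columns:
        raise ValueError("gap_chars out of range")
    return identity_display(match_bases, total_columns)


def aggregate_identity(hsps: list["HSP"]) -> tuple[int, int, float]:
    """Sum HSP columns and matches; return (total_bp, identical_bp, display).

    The overall display is rounded half-up at two decimals (a summary figure,
    unlike the per-HSP truncated cells).
    """
    if not hsps:
        raise ValueError("aggregate over an empty HSP list")
    total = sum(h.total_columns for h in hsps)
    match = sum(h.match_bases for h in hsps)
    import decimal

    pct = decimal.Decimal(match * 100) / decimal.Decimal(total)
    display = float(pct.quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP))
    return total, match, display


@dataclass
class HSP:
    """One gapped local alignment block, 1-based inclusive intervals."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str  # "+" or "-"
    match_bases: int
    total_columns: int
    gap_chars: int
    gap_events: int = 0

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start + 1

    @property
    def s_span(self) -> int:
        return self.s_end - self.s_start + 1

    @property
    def mismatches(self) -> int:
        return self.total_columns - self.match_bases - self.gap_chars

    @property
    def identity(self) -> float:
        return identity_display(self.match_bases, self.total_columns)

    def score(self, p: "AlignParams") -> int:
        return (
            p.match * self.match_bases
            - p.mismatch * self.mismatches
            - p.gap_open * self.gap_events
            - p.gap_extend * self.gap_chars
        )


@dataclass
class AlignParams:
    """Tunable parameters of the HSP engine (costs are positive numbers)."""

    match: int = 1
    mismatch: int = 2
    gap_open: int = 5
    gap_extend: int = 2
    seed_k: int = 20
    min_hsp_len: int = 100
    # x_drop must stay below the cost of a (max_gap + 1)-column gap
    # (5 + 2*31 = 67 by default), so that indels larger than max_gap split
    # HSPs at the extension stage too, mirroring the published tables where
    # even a 38 bp duplication produces two overlapping HSPs
    x_drop: int = 60
    max_gap: int = 30  # largest indel kept inside one HSP; larger ones split
    rep_cap: int = 16  # seeds occurring more often than this are skipped
    band_pad: int = 32
    # exact runs at least this long are trusted as fixed anchors; shorter
    # seeds are dissolved into the DP fill (a short run flanked by opposing
    # indels can be profitably bypassed by the optimal alignment)
    solid_min: int = 100


# -- sequence encoding and seeding ----------------------------------------

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 hashes of all k-mers plus validity (no N) flags."""
    n = len(codes)
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    h = np.zeros(m, dtype=np.uint64)
    valid = np.ones(m, dtype=bool)
    for i in range(k):
        c = codes[i : m + i]
        h = h * np.uint64(4) + (c & np.uint8(3)).astype(np.uint64)
        valid &= c != 4
    return h, valid


def _seed_pairs(query: str, subject: str, k: int, rep_cap: int) -> tuple[np.ndarray, np.ndarray]:
    """All (q_pos0, s_pos0) exact k-mer matches, repeat-capped per query k-mer."""
    qh, qv = _kmer_hashes(_encode(query), k)
    sh, sv = _kmer_hashes(_encode(subject), k)
    spos = np.nonzero(sv)[0]
    shv = sh[spos]
    order = np.argsort(shv, kind="stable")
    sh_sorted = shv[order]
    spos_sorted = spos[order]
    left = np.searchsorted(sh_sorted, qh, side="left")
    right = np.searchsorted(sh_sorted, qh, side="right")
    cnt = right - left
    keep = qv & (cnt > 0) & (cnt <= rep_cap)
    qpos = np.nonzero(keep)[0]
    reps = cnt[keep]
    if len(qpos) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    total = int(reps.sum())
    starts = left[keep]
    base = np.repeat(starts, reps)
    csum = np.cumsum(reps) - reps
    offsets = np.arange(total, dtype=np.int64) - np.repeat(csum, reps)
    sidx = spos_sorted[base + offsets]
    qidx = np.repeat(qpos, reps)
    return qidx.astype(np.int64), sidx.astype(np.int64)


def _merge_runs(qidx: np.ndarray, sidx: np.ndarray, k: int) -> list[tuple[int, int, int]]:
    """Merge same-diagonal overlapping seed hits into exact segments.

    Returns 0-based (q0, s0, length) triples, sorted by (diag, q0).
    """
    if len(qidx) == 0:
        return []
    diag = qidx - sidx
    order = np.lexsort((qidx, diag))
    q = qidx[order]
    d = diag[order]
    # break points: new diagonal or gap larger than k-1 (not guaranteed exact)
    dq = np.diff(q)
    dd = np.diff(d)
    brk = np.nonzero((dd != 0) | (dq > k - 1))[0] + 1
    bounds = np.concatenate(([0], brk, [len(q)]))
    segs = []
    for i in range(len(bounds) - 1):
        a, b = bounds[i], bounds[i + 1]
        q0 = int(q[a])
        qlast = int(q[b - 1])
        segs.append((q0, q0 - int(d[a]), qlast - q0 + k))
    return segs


# -- chaining --------------------------------------------------------------


@dataclass
class _Chain:
    segs: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def q_end0(self) -> int:  # 0-based exclusive
        q0, _, ln = self.segs[-1]
        return q0 + ln

    @property
    def s_end0(self) -> int:
        _, s0, ln = self.segs[-1]
        return s0 + ln

    @property
    def q_start0(self) -> int:
        return self.segs[0][0]

    @property
    def s_start0(self) -> int:
        return self.segs[0][1]

    @property
    def anchor_len(self) -> int:
        return sum(s[2] for s in self.segs)


def _chain_segments(segs: list[tuple[int, int, int]], max_gap: int, k: int) -> list[_Chain]:
    """Greedy colinear chaining of exact segments (sorted by q start)."""
    segs = sorted(segs, key=lambda t: (t[0], t[1]))
    chains: list[_Chain] = []
    open_chains: list[_Chain] = []
    for seg in segs:
        q0, s0, ln = seg
        attached = False
        for chain in reversed(open_chains[-64:]):
            dq = q0 - chain.q_end0
            ds = s0 - chain.s_end0
            if dq > max_gap + k:
                continue
            if -(ln) < dq <= max_gap and -(ln) < ds <= max_gap and abs(dq - ds) <= max_gap:
                trim = max(0, -min(dq, ds))
                if trim:
                    q0t, s0t, lnt = q0 + trim, s0 + trim, ln - trim
                    if lnt <= 0:
                        attached = True
                        break
                    # only attach trimmed segment if it still advances the chain
                    if q0t < chain.q_end0 or s0t < chain.s_end0:
                        attached = True
                        break
                    chain.segs.append((q0t, s0t, lnt))
                else:
                    chain.segs.append(seg)
                attached = True
                break
        if not attached:
            c = _Chain([seg])
            chains.append(c)
            open_chains.append(c)
        # keep the scan list short: drop chains that can no longer be extended
        if len(open_chains) > 256:
            open_chains = [c for c in open_chains if q0 - c.q_end0 <= max_gap + k]
    return chains


# -- DP pieces -------------------------------------------------------------

_NEG = -(10**9)


def _gotoh_global(u: str, v: str, p: AlignParams) -> tuple[int, int, int, int]:
    """Global affine alignment of two (short) strings.

    Returns (match, mismatch, gap_chars, gap_events).  Traceback prefers
    diagonal moves, which both minimises gap characters among co-optimal
    alignments and keeps the result deterministic.
    """
    n, m = len(u), len(v)
    if n == 0 and m == 0:
        return 0, 0, 0, 0
    if n == 0 or m == 0:
        return 0, 0, n + m, 1
    go, ge, ma, mi = p.gap_open, p.gap_extend, p.match, p.mismatch
    # Large problems get a diagonal band (the optimal path cannot profitably
    # wander far off-diagonal under affine costs); storage is per-row slices
    # so memory stays O(n * bandwidth).
    if n * m > 1_000_000:
        b_lo = 64 + max(0, n - m)
        b_hi = 64 + max(0, m - n)
    else:
        b_lo = b_hi = n + m  # effectively unbanded
    los = [max(0, i - b_lo) for i in range(n + 1)]
    his = [min(m, i + b_hi) for i in range(n + 1)]
    M = [[_NEG] * (his[i] - los[i] + 1) for i in range(n + 1)]
    X = [[_NEG] * (his[i] - los[i] + 1) for i in range(n + 1)]
    Y = [[_NEG] * (his[i] - los[i] + 1) for i in range(n + 1)]

    def g(A: list[list[int]], i: int, j: int) -> int:
        if i < 0 or j < los[i] or j > his[i]:
            return _NEG
        return A[i][j - los[i]]

    M[0][0] = 0
    for i in range(1, n + 1):
        if los[i] == 0:
            X[i][0] = -go - ge * i
    for j in range(1, his[0] + 1):
        Y[0][j] = -go - ge * j
    for i in range(1, n + 1):
        ui = u[i - 1]
        lo, hi = los[i], his[i]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        for j in range(max(1, lo), hi + 1):
            sub = ma if ui == v[j - 1] else -mi
            Mi[j - lo] = max(g(M, i - 1, j - 1), g(X, i - 1, j - 1), g(Y, i - 1, j - 1)) + sub
            Xi[j - lo] = max(
                g(M, i - 1, j) - go - ge, g(X, i - 1, j) - ge, g(Y, i - 1, j) - go - ge
            )
            Yi[j - lo] = max(
                g(M, i, j - 1) - go - ge, g(Y, i, j - 1) - ge, g(X, i, j - 1) - go - ge
            )
    i, j = n, m
    final = max(g(M, i, j), g(X, i, j), g(Y, i, j))
    state = "M" if g(M, i, j) == final else ("X" if g(X, i, j) == final else "Y")
    ops: list[str] = []
    match = mismatch = 0
    while i > 0 or j > 0:
        ops.append(state)
        if state == "M":
            eq = u[i - 1] == v[j - 1]
            if eq:
                match += 1
            else:
                mismatch += 1
            tgt = g(M, i, j) - (ma if eq else -mi)
            i, j = i - 1, j - 1
            if g(M, i, j) == tgt:
                state = "M"
            elif g(X, i, j) == tgt:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            val = g(X, i, j)
            i -= 1
            if g(X, i, j) - ge == val:
                state = "X"
            elif g(M, i, j) - go - ge == val:
                state = "M"
            else:
                state = "Y"
        else:  # Y
            val = g(Y, i, j)
            j -= 1
            if g(Y, i, j) - ge == val:
                state = "Y"
            elif g(M, i, j) - go - ge == val:
                state = "M"
            else:
                state = "X"
    gap_chars = sum(1 for o in ops if o != "M")
    gap_events = sum(
        1 for k, o in enumerate(ops) if o != "M" and (k == 0 or ops[k - 1] != o)
    )
    return match, mismatch, gap_chars, gap_events


def _extend_local(u: str, v: str, p: AlignParams) -> tuple[int, int, int, int, int, int]:
    """Banded x-drop extension of prefixes of u against v.

    Finds the prefix pair (i, j) maximising the affine global score of
    u[:i] vs v[:j]; returns (i, j, match, mismatch, gap_chars, gap_events)
    for the best endpoint (all zeros when no positive extension exists).
    Rows whose every cell falls x_drop below the running best are abandoned.
    """
    if not u or not v:
        return 0, 0, 0, 0, 0, 0
    go, ge, ma, mi = p.gap_open, p.gap_extend, p.match, p.mismatch
    band = p.x_drop // ge + p.band_pad
    n, m = len(u), len(v)
    best_score = 0
    best = (0, 0)
    Mprev: dict[int, int] = {0: 0}
    Xprev: dict[int, int] = {}
    Yprev: dict[int, int] = {0: _NEG}
    # seed row 0 horizontal gaps (leading gap in u)
    acc = 0
    for j in range(1, min(m, band) + 1):
        acc = -go - ge * j
        if acc < best_score - p.x_drop:
            break
        Yprev[j] = acc
    for i in range(1, n + 1):
        Mcur: dict[int, int] = {}
        Xcur: dict[int, int] = {}
        Ycur: dict[int, int] = {}
        lo = max(0, i - band)
        hi = min(m, i + band)
        ui = u[i - 1]
        cutoff = best_score - p.x_drop
        for j in range(lo, hi + 1):
            # X: vertical gap (consumes u)
            xc = _NEG
            mp = Mprev.get(j, _NEG)
            xp = Xprev.get(j, _NEG)
            yp = Yprev.get(j, _NEG)
            xc = max(mp - go - ge, xp - ge, yp - go - ge)
            if xc >= cutoff:
                Xcur[j] = xc
            if j > 0:
                mp1 = Mprev.get(j - 1, _NEG)
                xp1 = Xprev.get(j - 1, _NEG)
                yp1 = Yprev.get(j - 1, _NEG)
                base = max(mp1, xp1, yp1)
                if base > _NEG // 2:
                    sub = ma if ui == v[j - 1] else -mi
                    mval = base + sub
                    if mval >= cutoff:
                        Mcur[j] = mval
                        if mval > best_score:
                            best_score = mval
                            best = (i, j)
                            cutoff = best_score - p.x_drop
                # Y: horizontal gap (consumes v), depends on current row
                yc = max(
                    Mcur.get(j - 1, _NEG) - go - ge,
                    Ycur.get(j - 1, _NEG) - ge,
                    Xcur.get(j - 1, _NEG) - go - ge,
                )
                if yc >= cutoff:
                    Ycur[j] = yc
        if not Mcur and not Xcur and not Ycur:
            break
        Mprev, Xprev, Yprev = Mcur, Xcur, Ycur
    bi, bj = best
    if best_score <= 0:
        return 0, 0, 0, 0, 0, 0
    match, mismatch, gap_chars, gap_events = _gotoh_global(u[:bi], v[:bj], p)
    return bi, bj, match, mismatch, gap_chars, gap_events


# -- HSP construction ------------------------------------------------------


def _chain_to_hsp(chain: _Chain, query: str, subject: str, p: AlignParams) -> Optional[HSP]:
    all_segs = sorted(chain.segs)
    # Only long exact runs are trusted as fixed anchors; short seeds between
    # them (which may sit on a locally suboptimal diagonal) are dissolved and
    # re-aligned by the DP fill, keeping the block optimal under the scoring.
    solid_min = max(2 * p.seed_k, p.solid_min)
    segs = [s for s in all_segs if s[2] >= solid_min]
    if not segs:
        segs = [max(all_segs, key=lambda s: s[2])]
    match = 0
    mismatch = 0
    gap_chars = 0
    gap_events = 0
    for idx, (q0, s0, ln) in enumerate(segs):
        match += ln
        if idx + 1 < len(segs):
            nq0, ns0, _ = segs[idx + 1]
            u = query[q0 + ln : nq0]
            v = subject[s0 + ln : ns0]
            fm, fx, fg, fe = _gotoh_global(u, v, p)
            match += fm
            mismatch += fx
            gap_chars += fg
            gap_events += fe
    # extend left
    q_start0 = segs[0][0]
    s_start0 = segs[0][1]
    u = query[:q_start0][::-1]
    v = subject[:s_start0][::-1]
    bi, bj, em, ex, eg, ee = _extend_local(u, v, p)
    q_start0 -= bi
    s_start0 -= bj
    match += em
    mismatch += ex
    gap_chars += eg
    gap_events += ee
    # extend right
    q_end0 = segs[-1][0] + segs[-1][2]  # exclusive
    s_end0 = segs[-1][1] + segs[-1][2]
    bi, bj, em, ex, eg, ee = _extend_local(query[q_end0:], subject[s_end0:], p)
    q_end0 += bi
    s_end0 += bj
    match += em
    mismatch += ex
    gap_chars += eg
    gap_events += ee
    total = match + mismatch + gap_chars
    if total < p.min_hsp_len:
        return None
    return HSP(
        q_start=q_start0 + 1,
        q_end=q_end0,
        s_start=s_start0 + 1,
        s_end=s_end0,
        strand="+",
        match_bases=match,
        total_columns=total,
        gap_chars=gap_chars,
        gap_events=gap_events,
    )


def _dedupe(hsps: list[HSP]) -> list[HSP]:
    seen = set()
    out = []
    for h in sorted(hsps, key=lambda h: (-h.total_columns, h.q_start, h.s_start)):
        key = (h.q_start, h.q_end, h.s_start, h.s_end, h.strand)
        if key in seen:
            continue
        contained = False
        for g in out:
            if (
                g.strand == h.strand
                and g.q_start <= h.q_start
                and h.q_end <= g.q_end
                and g.s_start <= h.s_start
                and h.s_end <= g.s_end
            ):
                contained = True
                break
        if contained:
            continue
        seen.add(key)
        out.append(h)
    return sorted(out, key=lambda h: (h.q_start, h.s_start))


def align_hsps(query: str, subject: str, params: Optional[AlignParams] = None) -> list[HSP]:
    """Find all HSPs between two sequences, both strands.

    Deterministic for fixed parameters.  Sequences with more than 50 % N are
    refused (ambiguity would dominate the seed index).
    """
    p = params or AlignParams()
    if not query or not subject:
        raise ValueError("empty sequence")
    for name, s in (("query", query), ("subject", subject)):
        if s.count("N") * 2 > len(s):
            raise ValueError(f"{name} is more than 50% N; refusing to align")
    out: list[HSP] = []
    for strand in "+-":
        subj = subject if strand == "+" else revcomp(subject)
        qidx, sidx = _seed_pairs(query, subj, p.seed_k, p.rep_cap)
        segs = _merge_runs(qidx, sidx, p.seed_k)
        chains = _chain_segments(segs, p.max_gap, p.seed_k)
        for chain in chains:
            if chain.anchor_len < min(p.min_hsp_len, p.seed_k * 2) and len(chains) > 1:
                # tiny orphan chains are usually split fragments; still try to
                # build them, the min_hsp_len filter decides
                pass
            h = _chain_to_hsp(chain, query, subj, p)
            if h is None:
                continue
            if strand == "-":
                n = len(subject)
                h = HSP(
                    q_start=h.q_start,
                    q_end=h.q_end,
                    s_start=n - h.s_end + 1,
                    s_end=n - h.s_start + 1,
                    strand="-",
                    match_bases=h.match_bases,
                    total_columns=h.total_columns,
                    gap_chars=h.gap_chars,
                    gap_events=h.gap_events,
                )
            out.append(h)
    return _dedupe(out)


# -- maximal exact matches (dotplot substrate) -----------------------------


def find_maximal_matches(
    a: str, b: str, min_len: int = 20, rep_cap: int = 100
) -> list[tuple[int, int, int, str]]:
    """All maximal exact matches >= min_len between a and b, both strands.

    Returns 1-based (a_pos, b_pos, length, strand) with b_pos the forward
    strand start of the matched region in b.  Self comparisons (``a is b``)
    include the trivial full-length identity on the plus strand.
    """
    if min_len < 12:
        raise ValueError("min_len must be >= 12")
    k = min(min_len, 31)
    results: list[tuple[int, int, int, str]] = []
    for strand in "+-":
        bb = b if strand == "+" else revcomp(b)
        qidx, sidx = _seed_pairs(a, bb, k, rep_cap)
        segs = _merge_runs(qidx, sidx, k)
        seen: set[tuple[int, int]] = set()
        for q0, s0, ln in segs:
            # extend to maximality (run merging can fragment across capped
            # seeds); stop at N which never matches
            while q0 > 0 and s0 > 0 and a[q0 - 1] == bb[s0 - 1] != "N":
                q0 -= 1
                s0 -= 1
                ln += 1
            while q0 + ln < len(a) and s0 + ln < len(bb) and a[q0 + ln] == bb[s0 + ln] != "N":
                ln += 1
            if ln < min_len:
                continue
            key = (q0 - s0, q0)
            if key in seen:
                continue
            seen.add(key)
            if strand == "+":
                results.append((q0 + 1, s0 + 1, ln, "+"))
            else:
                results.append((q0 + 1, len(b) - (s0 + ln) + 1, ln, "-"))
    return sorted(set(results))
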