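"""HSP engine: identity display, alignment blocks, maximal matches."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mgecore.align import (
    AlignParams,
    aggregate_identity,
    align_hsps,
    find_maximal_matches,
    hsp_stats,
    identity_display,
)
from mgecore.published import CHROMOSOME_63R2_VS_91R6_SUMS
from mgecore.replicon import revcomp

from .conftest import random_seq


class TestIdentityDisplay:
    @pytest.mark.parametrize(
        "match,total,expected",
        [
            # printed cells where truncation and rounding disagree
            (506_862, 506_880, 99.99),
            (48_433, 48_453, 99.95),
            # perfect block and the degenerate floor
            (210_501, 210_501, 100.00),
            (0, 1, 0.00),
            # further printed cells
            (170_772, 170_773, 99.99),
            (39_440, 39_483, 99.89),
            (183_597, 183_605, 99.99),
        ],
    )
    def test_printed_cells(self, match, total, expected):
        assert hsp_stats(match, total) == expected

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            hsp_stats(0, 0)

    @given(st.integers(1, 10**7), st.data())
    def test_truncation_guarantee(self, total, data):
        match = data.draw(st.integers(0, total))
        disp = identity_display(match, total)
        # 100.00 iff perfect; truncation never rounds up
        assert (disp == 100.00) == (match == total)
        assert disp <= match / total * 100 < disp + 0.01 + 1e-9

    def test_aggregate_rounds_the_summary(self):
        total, match = CHROMOSOME_63R2_VS_91R6_SUMS
        from mgecore.align import HSP

        hsps = [HSP(1, 1, 1, 1, "+", match, total, 0)]
        assert aggregate_identity(hsps) == (total, match, 99.64)
        # per-HSP truncation would print 99.63 for the same counts
        assert hsp_stats(match, total) == 99.63

    def test_aggregate_equals_stats_of_sums(self, rng):
        from mgecore.align import HSP

        hsps = []
        for _ in range(10):
            total = rng.randrange(1_000, 50_000)
            match = rng.randrange(total // 2, total + 1)
            hsps.append(HSP(1, 1, 1, 1, "+", match, total, 0))
        tot, mat, _disp = aggregate_identity(hsps)
        assert tot == sum(h.total_columns for h in hsps)
        assert mat == sum(h.match_bases for h in hsps)


class TestAlignHsps:
    def test_identical_sequences_single_perfect_hsp(self, rng):
        q = random_seq(rng, 10_000)
        (h,) = align_hsps(q, q)
        assert (h.q_start, h.q_end, h.s_start, h.s_end) == (1, 10_000, 1, 10_000)
        assert h.identity == 100.00 and h.strand == "+"

    def test_reverse_complement_single_minus_hsp(self, rng):
        q = random_seq(rng, 8_000)
        (h,) = align_hsps(q, revcomp(q))
        assert h.strand == "-"
        assert (h.q_start, h.q_end, h.s_start, h.s_end) == (1, 8_000, 1, 8_000)

    def test_small_insertion_stays_inside_one_gapped_hsp(self, rng):
        q = random_seq(rng, 10_000)
        s = q[:5_000] + random_seq(rng, 10) + q[5_000:]
        (h,) = align_hsps(q, s)
        assert h.gap_chars == 10
        assert (h.q_start, h.q_end, h.s_start, h.s_end) == (1, 10_000, 1, 10_010)

    def test_large_insertion_splits_into_two_hsps(self, rng):
        q = random_seq(rng, 10_000)
        ins = list(random_seq(rng, 500))
        # junction-clean payload so the break coordinates are unambiguous
        for i in range(3):
            while ins[i] == q[5_000 + i]:
                ins[i] = rng.choice("ACGT")
            while ins[-1 - i] == q[4_999 - i]:
                ins[-1 - i] = rng.choice("ACGT")
        s = q[:5_000] + "".join(ins) + q[5_000:]
        hsps = align_hsps(q, s)
        assert [(h.q_start, h.q_end, h.s_start, h.s_end) for h in hsps] == [
            (1, 5_000, 1, 5_000),
            (5_001, 10_000, 5_501, 10_500),
        ]

    def test_strand_symmetry(self, rng):
        q = random_seq(rng, 6_000)
        s = q[:3_000] + random_seq(rng, 200) + q[3_000:]
        fwd = align_hsps(q, s)
        rev = align_hsps(q, revcomp(s))
        assert len(fwd) == len(rev)
        n = len(s)
        mirrored = sorted(
            (h.q_start, h.q_end, n - h.s_end + 1, n - h.s_start + 1) for h in rev
        )
        assert mirrored == sorted((h.q_start, h.q_end, h.s_start, h.s_end) for h in fwd)

    def test_mostly_n_sequence_refused(self):
        with pytest.raises(ValueError, match="N"):
            align_hsps("N" * 300 + "ACGT" * 10, "ACGT" * 100)

    def test_deterministic_for_fixed_params(self, rng):
        q = random_seq(rng, 5_000)
        s = q[:2_000] + random_seq(rng, 60) + q[2_500:]
        assert align_hsps(q, s) == align_hsps(q, s)

    def test_counts_match_dp_oracle_on_mutated_pairs(self):
        """Spot-check engine optimality against C Smith-Waterman (more pairs
        run in the acceptance suite)."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -2
        aligner.open_gap_score = -7
        aligner.extend_gap_score = -2
        rng = random.Random(42)
        p = AlignParams(max_gap=2_000, min_hsp_len=50)
        for _ in range(20):
            a = random_seq(rng, rng.randrange(400, 1_500))
            b = mutate_interior(rng, a)
            h = max(align_hsps(a, b, p), key=lambda h: h.score(p))
            counts = aligner.align(a, b)[0].counts()
            assert h.score(p) == aligner.score(a, b)
            assert h.match_bases == counts.identities
            assert h.total_columns == counts.identities + counts.mismatches + counts.gaps


def mutate_interior(rng, s, sub=0.01, nindel=2, max_indel=30, margin=150):
    """Mutated copy with intact terminal margins (the engine's regime is
    end-to-end near-identical core sequences; end trimming of divergent
    termini is where x-drop heuristics legitimately differ from full DP)."""
    chars = list(s)
    for i in range(margin, len(chars) - margin):
        if rng.random() < sub:
            chars[i] = rng.choice([c for c in "ACGT" if c != chars[i]])
    s = "".join(chars)
    for _ in range(nindel):
        pos = rng.randrange(margin, len(s) - margin - max_indel)
        ln = rng.randrange(1, max_indel + 1)
        if rng.random() < 0.5:
            s = s[:pos] + s[pos + ln :]
        else:
            s = s[:pos] + random_seq(rng, ln) + s[pos:]
    return s


class TestMaximalMatches:
    def test_self_match_full_length(self, rng):
        a = random_seq(rng, 2_000)
        matches = find_maximal_matches(a, a, min_len=20)
        assert (1, 1, 2_000, "+") in matches

    def test_revcomp_full_minus_match(self, rng):
        a = random_seq(rng, 2_000)
        matches = find_maximal_matches(a, revcomp(a), min_len=20)
        assert (1, 1, 2_000, "-") in matches

    def test_planted_blocks_match_quadratic_oracle(self, rng):
        a = random_seq(rng, 4_000)
        b = random_seq(rng, 4_000)
        blocks = []
        for k in range(5):
            ln = rng.randrange(30, 80)
            ap = 200 + k * 700
            bp = 350 + k * 650
            b = b[:bp] + a[ap : ap + ln] + b[bp + ln :]
            blocks.append((ap + 1, bp + 1, ln))
        found = find_maximal_matches(a, b, min_len=25)
        oracle = quadratic_maximal_matches(a, b, 25)
        assert set(m for m in found if m[3] == "+") >= set(oracle)
        for ap, bp, ln in blocks:
            assert any(
                m[0] <= ap and m[1] <= bp and m[0] + m[2] >= ap + ln for m in found
            ), (ap, bp, ln)

    def test_min_len_floor(self):
        with pytest.raises(ValueError):
            find_maximal_matches("ACGT" * 10, "ACGT" * 10, min_len=5)


def quadratic_maximal_matches(a, b, min_len):
    """Brute-force plus-strand maximal exact matches for small instances."""
    out = []
    for diag in range(-len(b) + 1, len(a)):
        i = max(0, diag)
        j = i - diag
        run = 0
        while i < len(a) and j < len(b):
            if a[i] == b[j] != "N":
                run += 1
            else:
                if run >= min_len:
                    out.append((i - run + 1, j - run + 1, run, "+"))
                run = 0
            i += 1
            j += 1
        if run >= min_len:
            out.append((i - run + 1, j - run + 1, run, "+"))
    return out
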