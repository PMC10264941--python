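"""Break tiling, classification, deduplication, inverted duplications."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mgecore import published as pub
from mgecore.align import HSP
from mgecore.breaks import (
    bin_break_sizes,
    classify_replacement,
    colinear_chain,
    dedupe_events,
    detect_inverted_duplication,
    tile_and_break,
    tiling_conservation,
)
from mgecore.replicon import revcomp

from .conftest import random_seq


def hsp(qs, qe, ss, se, strand="+"):
    return HSP(qs, qe, ss, se, strand, qe - qs + 1, qe - qs + 1, 0)


class TestTileAndBreak:
    def test_identical_sequences_zero_breaks(self):
        events = tile_and_break([hsp(1, 10_000, 1, 10_000)], 10_000, 10_000)
        assert events == []

    def test_published_insertion_with_overlap(self):
        """The 9,476 bp insertion opposite an 8 bp overlap."""
        events = tile_and_break(
            pub.as_hsps(pub.CHROMOSOME_63R2_VS_R1[:2]), 589_134, 579_649
        )
        (ev,) = events
        assert ev.category == "insertion_in_q"
        assert ev.q_gap == (170_774, 180_249)
        assert ev.primary_length == 9_476
        assert ev.s_overlap == 8

    def test_published_deletion_including_overlap(self):
        """The 104 bp gap + 29 bp overlap printed as a 133 bp deletion."""
        events = tile_and_break(
            pub.as_hsps(pub.CHROMOSOME_63R2_VS_R1[3:5]), 1_997_337, 1_987_747
        )
        (ev,) = [e for e in events if not e.terminal]
        assert ev.q_gap == (1_861_459, 1_861_562)
        assert ev.primary_length == 104
        assert ev.s_overlap == 29
        assert ev.combined_length == 133

    def test_published_extra_bases(self):
        """164 extra bases opposite a 259 bp overlap (423 bp deletion)."""
        events = tile_and_break(
            pub.as_hsps(pub.CHROMOSOME_63R2_VS_NRC1[2:4]), 1_997_337, 1_996_939
        )
        (ev,) = [e for e in events if not e.terminal]
        assert ev.primary_length == 164
        assert ev.combined_length == 423

    def test_minus_strand_input_refused(self):
        with pytest.raises(ValueError, match="inversion"):
            tile_and_break([hsp(1, 100, 1, 100, "-")], 100, 100)

    def test_non_colinear_input_refused(self):
        with pytest.raises(ValueError):
            tile_and_break([hsp(1, 100, 500, 599), hsp(200, 300, 1, 100)], 300, 599)

    def test_terminal_breaks_cover_replicon_ends(self):
        events = tile_and_break([hsp(1_001, 2_000, 1, 1_000)], 2_500, 1_200)
        assert len(events) == 2
        assert events[0].terminal and events[0].q_gap == (1, 1_000)
        assert events[1].terminal and events[1].q_gap == (2_001, 2_500)
        assert events[1].s_gap == (1_001, 1_200)

    @given(st.data())
    def test_tiling_conservation_property(self, data):
        """sum(spans) + sum(gaps) - sum(overlaps) equals replicon length."""
        n = data.draw(st.integers(1, 6))
        q_pos = s_pos = 1
        hsps = []
        for _ in range(n):
            q_gap = data.draw(st.integers(-20, 500))
            s_gap = data.draw(st.integers(-20, 500))
            span = data.draw(st.integers(200, 2_000))
            qs = max(q_pos + q_gap, q_pos - span // 2, 1)
            ss = max(s_pos + s_gap, s_pos - span // 2, 1)
            if hsps and (qs + span - 1 <= hsps[-1].q_end or ss + span - 1 <= hsps[-1].s_end):
                continue
            hsps.append(hsp(qs, qs + span - 1, ss, ss + span - 1))
            q_pos, s_pos = qs + span, ss + span
        if not hsps:
            return
        q_len = hsps[-1].q_end + data.draw(st.integers(0, 100))
        s_len = hsps[-1].s_end + data.draw(st.integers(0, 100))
        events = tile_and_break(hsps, q_len, s_len)
        assert tiling_conservation(hsps, events, q_len, s_len)

    def test_swap_symmetry(self):
        hsps = pub.as_hsps(pub.CHROMOSOME_63R2_VS_R1)
        events = tile_and_break(hsps, *pub.LEN_63R2_CORE_R)
        swapped_hsps = [
            HSP(h.s_start, h.s_end, h.q_start, h.q_end, "+",
                h.match_bases, h.total_columns, h.gap_chars)
            for h in hsps
        ]
        swapped = tile_and_break(swapped_hsps, *pub.LEN_63R2_CORE_R[::-1])
        mapping = {"insertion_in_q": "insertion_in_s",
                   "insertion_in_s": "insertion_in_q"}
        for a, b in zip(events, swapped):
            assert b.category == mapping.get(a.category, a.category)
            assert (b.q_gap, b.s_gap) == (a.s_gap, a.q_gap)
            assert b.combined_length == a.combined_length


class TestDedupe:
    def test_published_cross_comparison_count_is_five(self):
        ev_r = tile_and_break(pub.as_hsps(pub.CHROMOSOME_63R2_VS_R1),
                              *pub.LEN_63R2_CORE_R)
        ev_n = tile_and_break(pub.as_hsps(pub.CHROMOSOME_63R2_VS_NRC1),
                              *pub.LEN_63R2_CORE_N)
        distinct = dedupe_events({"R1": ev_r, "NRC1": ev_n})
        assert len(ev_r) == 4 and len(ev_n) == 3
        assert len(distinct) == 5
        shared = [d for d in distinct if len(d.members) == 2]
        assert len(shared) == 2

    def test_single_comparison_dedupe_is_identity(self):
        ev = tile_and_break(pub.as_hsps(pub.CHROMOSOME_63R2_VS_R1),
                            *pub.LEN_63R2_CORE_R)
        distinct = dedupe_events({"only": ev})
        assert len(distinct) == len(ev)


class TestReplacement:
    def test_isopositioned_island_swap_is_replacement(self):
        ev = tile_and_break(
            [hsp(1, 1_000, 1, 1_000), hsp(62_001, 70_000, 48_001, 56_000)],
            70_000, 56_000,
        )[0]
        ev = classify_replacement(ev)
        assert ev.category == "replacement"
        assert "61000 bp" in ev.annotation and "47000 bp" in ev.annotation

    def test_extreme_asymmetry_still_replacement(self):
        ev = tile_and_break(
            [hsp(1, 500, 1, 500), hsp(2_801, 3_300, 164_701, 165_200)],
            3_300, 165_200,
        )[0]
        assert classify_replacement(ev).category == "replacement"

    def test_pure_insertion_is_not_replacement(self):
        ev = tile_and_break(
            [hsp(1, 500, 1, 500), hsp(1_501, 2_000, 501, 1_000)], 2_000, 1_000
        )[0]
        assert classify_replacement(ev).category == "insertion_in_q"


class TestInvertedDuplication:
    def test_repeat_free_sequence_empty(self, rng):
        assert detect_inverted_duplication(random_seq(rng, 30_000), min_arm=1_000) == []

    def test_planted_arms_recovered_exactly(self, rng):
        arm = random_seq(rng, 5_000)
        seq = (random_seq(rng, 8_000) + arm + random_seq(rng, 4_000)
               + revcomp(arm) + random_seq(rng, 6_000))
        (dup,) = detect_inverted_duplication(seq, min_arm=2_000)
        assert dup.arm_len == 5_000
        assert dup.arm1 == (8_001, 13_000)
        assert dup.arm2 == (17_001, 22_000)
        assert dup.spacer == 4_000

    def test_many_random_plantings_recovered(self):
        rng = random.Random(21)
        for trial in range(25):
            arm_len = rng.randrange(2_000, 8_000)
            left = rng.randrange(3_000, 6_000)
            spacer = rng.randrange(1_000, 5_000)
            arm = random_seq(rng, arm_len)
            seq = (random_seq(rng, left) + arm + random_seq(rng, spacer)
                   + revcomp(arm) + random_seq(rng, 3_000))
            dups = detect_inverted_duplication(seq, min_arm=1_500)
            # a maximal match may extend a few bases past the planted arm by
            # flanking coincidence; it must contain the arm and not exceed it
            # by more than that chance slack
            assert any(
                d.arm1[0] <= left + 1
                and d.arm1[1] >= left + arm_len
                and d.arm_len - arm_len <= 12
                for d in dups
            ), trial


class TestBins:
    def test_empty_event_list_all_zero(self):
        assert bin_break_sizes([]) == {"short": 0, "medium": 0, "long": 0,
                                       "very_long": 0}

    def test_bin_edges(self):
        def ev(primary):
            e = tile_and_break(
                [hsp(1, 100, 1, 100),
                 hsp(101 + primary, 200 + primary, 101, 200)],
                200 + primary, 200,
            )[0]
            return e
        events = [ev(1_500), ev(5_000), ev(60_000)]
        assert bin_break_sizes(events) == {"short": 1, "medium": 0, "long": 1,
                                           "very_long": 1}


class TestColinearChain:
    def test_repeat_hsps_excluded_from_chain(self):
        main = [hsp(1, 1_000, 1, 1_000), hsp(1_101, 2_000, 1_101, 2_000)]
        repeat = hsp(200, 400, 1_500, 1_700)  # off-diagonal repeat block
        minus = hsp(300, 500, 600, 800, "-")
        chain = colinear_chain(main + [repeat, minus])
        assert chain == main
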