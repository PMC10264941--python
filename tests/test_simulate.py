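"""Simulator: event interpreter, ancestor architecture, reads, truth."""

import pytest

from mgecore.replicon import AnnotatedReplicon, revcomp
from mgecore.simulate import (
    AncestorSpec,
    Event,
    EventConflictError,
    EventLog,
    apply_events,
    expected_pairwise_breaks,
    make_ancestor,
    PlantedIndel,
    simulate_reads,
)

from .conftest import random_seq

SMALL = AncestorSpec(
    chromosome_length=120_000,
    at_island=(40_001, 6_000),
    inv_core=5_000,
    inv_extension=1_200,
    shared_block=3_000,
    p_a_length=40_000,
    p_a_unique1=10_000,
    p_a_spacer=1_500,
    p_c_unique=10_000,
    p_c_spacer=8_000,
    p_b_unique=15_000,
    p_d_length=9_000,
    seed=3,
)


class TestMakeAncestor:
    def test_same_seed_twice_identical(self):
        a1 = make_ancestor(SMALL)
        a2 = make_ancestor(SMALL)
        assert all(
            a1.genome[r].sequence == a2.genome[r].sequence for r in a1.genome
        )

    def test_architecture_lengths(self):
        anc = make_ancestor(SMALL)
        g = anc.genome
        assert len(g["chromosome"]) == 120_000
        assert len(g["pA"]) == 40_000
        assert len(g["pD"]) == 9_000
        arm = anc.arm40
        assert len(arm) == 6_200  # core + extension
        # the two repeat-bearing plasmids share one contiguous cassette
        assert g["pC"].sequence.endswith(anc.cassette)
        assert g["pB"].sequence.endswith(anc.cassette)
        assert anc.cassette == arm + anc.cassette[len(arm):-len(arm)] + revcomp(arm)
        # the 16 kb-class block occurs in pA and inside the cassette
        assert anc.block16 in g["pA"].sequence
        assert anc.block16 in anc.cassette

    def test_minimal_spec_single_replicon(self):
        spec = AncestorSpec(chromosome_length=10_000, at_island=None, seed=1)
        anc = make_ancestor(spec)
        assert len(anc.genome["chromosome"]) == 10_000

    def test_unrealizable_spec_refused_before_emitting(self):
        with pytest.raises(ValueError):
            make_ancestor(AncestorSpec(shared_block=60_000, p_c_spacer=50_000))


class TestEventInterpreter:
    def setup_method(self):
        self.anc = make_ancestor(SMALL)

    def test_empty_log_is_identity(self):
        out = apply_events(self.anc.genome, EventLog())
        assert out["chromosome"].sequence == self.anc.genome["chromosome"].sequence

    def test_mge_insert_writes_tsd_pair(self, rng):
        elem = random_seq(rng, 800)
        log = EventLog([Event("mge_insert", "chromosome", {
            "position": 50_000, "tsd_len": 8, "element": elem, "mge_type": "ISH2",
        })])
        out = apply_events(self.anc.genome, log)["chromosome"]
        kinds = [s.kind for s in out.segments]
        assert kinds == ["unique", "tsd", "mge", "tsd", "unique"]
        out.validate()  # TSD pair equality enforced
        assert len(out) == 120_000 + 808

    def test_replay_is_deterministic(self, rng):
        log = EventLog([
            Event("deletion", "chromosome", {"start": 10_000, "end": 10_499}),
            Event("sequence_insert", "chromosome",
                  {"position": 5_000, "payload": random_seq(rng, 300)}),
        ])
        g1 = apply_events(self.anc.genome, log)
        g2 = apply_events(self.anc.genome, log)
        assert g1["chromosome"].sequence == g2["chromosome"].sequence

    def test_repeat_mediated_deletion_leaves_one_copy(self, rng):
        seq = self.anc.genome["chromosome"].sequence
        rep_unit = seq[20_000:20_008]  # pretend 8 bp direct repeat
        # make a genome with two copies: insert a second copy downstream
        log = EventLog([
            Event("sequence_insert", "chromosome",
                  {"position": 25_000, "payload": rep_unit}),
        ])
        g = apply_events(self.anc.genome, log)
        log2 = EventLog([
            Event("repeat_mediated_deletion", "chromosome", {
                "repeat1_start": 20_001, "repeat2_start": 25_001, "repeat_len": 8,
            }),
        ])
        out = apply_events(g, log2)["chromosome"]
        # span between the copy starts removed, one copy left
        expected = g["chromosome"].sequence[:20_000] + g["chromosome"].sequence[25_000:]
        assert out.sequence == expected
        assert out.sequence[20_000:20_008] == rep_unit

    def test_event_on_mge_coordinates_is_an_error(self, rng):
        log = EventLog([
            Event("mge_insert", "chromosome", {
                "position": 30_000, "tsd_len": 6,
                "element": random_seq(rng, 500), "mge_type": "ISH4",
            }),
            Event("deletion", "chromosome", {"start": 30_100, "end": 30_200}),
        ])
        with pytest.raises(EventConflictError, match="ISH4"):
            apply_events(self.anc.genome, log)

    def test_mge_excise_restores_empty_site(self, rng):
        elem = random_seq(rng, 700)
        ins = EventLog([Event("mge_insert", "chromosome", {
            "position": 44_000, "tsd_len": 5, "element": elem, "mge_type": "ISH2",
        })])
        g = apply_events(self.anc.genome, ins)
        mge = next(s for s in g["chromosome"].segments if s.kind == "mge")
        exc = EventLog([Event("mge_excise", "chromosome",
                              {"start": mge.start, "end": mge.end})])
        out = apply_events(g, exc)["chromosome"]
        assert out.sequence == self.anc.genome["chromosome"].sequence

    def test_plasmid_duplicate_and_drop(self):
        log = EventLog([
            Event("plasmid_duplicate", "pD", {"new_name": "pD2"}),
            Event("plasmid_drop", "pD", {}),
        ])
        out = apply_events(self.anc.genome, log)
        assert "pD" not in out and out["pD2"].sequence == self.anc.genome["pD"].sequence

    def test_chromosomal_integration(self):
        log = EventLog([
            Event("chromosomal_integration", "pD",
                  {"target": "chromosome", "position": 60_000}),
        ])
        out = apply_events(self.anc.genome, log)
        assert "pD" not in out
        chrom = out["chromosome"].sequence
        assert len(chrom) == 120_000 + 9_000
        assert chrom[60_000:69_000] == self.anc.genome["pD"].sequence


class TestExpectedBreaks:
    def test_single_insertion_projection(self):
        ev = expected_pairwise_breaks(
            [PlantedIndel("A", "chromosome", "insertion", 1_000, 1_000, 250)], []
        )
        (b,) = ev
        assert b.category == "insertion_in_q"
        assert b.q_gap == (1_001, 1_250)
        assert b.s_gap is None

    def test_offsets_accumulate_across_events(self):
        ev = expected_pairwise_breaks(
            [PlantedIndel("A", "chromosome", "insertion", 1_000, 1_000, 250)],
            [PlantedIndel("B", "chromosome", "deletion", 5_000, 5_099)],
        )
        assert ev[0].q_gap == (1_001, 1_250)
        b = ev[1]
        # B's deletion: unique interval appears in A (query side), shifted by
        # A's earlier 250 bp insertion
        assert b.category == "insertion_in_q"
        assert b.q_gap == (5_250, 5_349)

    def test_tandem_duplication_projection(self):
        (b,) = expected_pairwise_breaks(
            [PlantedIndel("A", "chromosome", "tandem_duplication", 2_000, 2_037)], []
        )
        assert b.category == "insertion_in_q"
        assert b.q_relation == "directly_adjacent"
        assert b.s_overlap == 38
        assert b.combined_length == 38


class TestReads:
    def test_depth_one_linear_tiles_replicon(self):
        genome = {"r": AnnotatedReplicon(id="r", sequence="ACGT" * 2_500)}
        reads = simulate_reads(genome, mean_len=1_000, depth=3, seed=0)
        assert all(len(s) == 1_000 for _rid, s in reads.reads)
        assert len(reads.reads) == 30

    def test_error_free_reads_are_exact_substrings(self, rng):
        seq = random_seq(rng, 20_000)
        genome = {"p": AnnotatedReplicon(id="p", sequence=seq, topology="circular")}
        reads = simulate_reads(genome, mean_len=2_000, depth=5, seed=1)
        doubled = seq + seq
        for (rid, s), origin in zip(reads.reads, reads.origins):
            sub = doubled[origin.start - 1 : origin.start - 1 + origin.length]
            assert s == (sub if origin.strand == "+" else revcomp(sub)), rid

    def test_fixed_seed_reproducible(self, rng):
        genome = {"p": AnnotatedReplicon(id="p", sequence=random_seq(rng, 30_000),
                                         topology="circular")}
        r1 = simulate_reads(genome, seed=7, mean_len=3_000, depth=4)
        r2 = simulate_reads(genome, seed=7, mean_len=3_000, depth=4)
        assert r1.reads == r2.reads

    def test_lognormal_lengths_truncated(self, rng):
        genome = {"p": AnnotatedReplicon(id="p", sequence=random_seq(rng, 50_000),
                                         topology="circular")}
        reads = simulate_reads(genome, mean_len=3_000, len_sd=1_500, depth=5, seed=2)
        lengths = [len(s) for _r, s in reads.reads]
        assert all(500 <= ln <= 25_000 for ln in lengths)
        assert len(set(lengths)) > 10

    def test_mean_len_must_fit_replicon(self):
        genome = {"p": AnnotatedReplicon(id="p", sequence="ACGT" * 100)}
        with pytest.raises(ValueError):
            simulate_reads(genome, mean_len=1_000, depth=2)
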