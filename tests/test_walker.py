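"""Subassembly walking, guide resolution, in-silico completion."""

import pytest

from mgecore.replicon import AnnotatedReplicon, revcomp, rotate_to_anchor
from mgecore.simulate import simulate_reads
from mgecore.walker import (
    HeterogeneityConflict,
    WalkParams,
    detect_heterogeneity,
    insilico_complete,
    resolve_with_guide,
    select_reads,
    walk,
)

from .conftest import random_seq


def canon(seq):
    rep = AnnotatedReplicon(id="x", sequence=seq, topology="circular")
    return rotate_to_anchor(rep).sequence


def circular_reads(seq, mean_len=3_000, depth=20, seed=0, name="p"):
    genome = {name: AnnotatedReplicon(id=name, sequence=seq, topology="circular")}
    return simulate_reads(genome, mean_len=mean_len, depth=depth, seed=seed)


class TestSelectReads:
    def test_absent_anchor_gives_empty_with_diagnostic(self, rng):
        reads = [("r1", random_seq(rng, 2_000)), ("r2", random_seq(rng, 2_000))]
        rs = select_reads(reads, random_seq(rng, 500))
        assert rs.reads == [] and "absent" in rs.diagnostic

    def test_selection_matches_origin_record(self, rng):
        seq = random_seq(rng, 60_000)
        sim = circular_reads(seq, depth=12, seed=4)
        a0 = 30_000
        anchor = seq[a0 : a0 + 2_000]
        rs = select_reads(sim.reads, anchor, min_match=300)
        picked = {rid for rid, _ in rs.reads}
        doubled_len = len(seq)
        expected = set()
        for origin in sim.origins:
            # overlap of the read with the anchor locus, circularly
            start = origin.start - 1
            end = start + origin.length
            for shift in (0, doubled_len):
                lo = max(start, a0 + shift)
                hi = min(end, a0 + 2_000 + shift)
                if hi - lo >= 300:
                    expected.add(origin.read_id)
        assert picked == expected

    def test_variant_subpopulation_only(self, rng):
        base = random_seq(rng, 20_000)
        variant = base[:10_000] + random_seq(rng, 1_300) + base[10_000:]
        r1 = circular_reads(base, depth=8, seed=1, name="w").reads
        r2 = circular_reads(variant, depth=8, seed=2, name="v").reads
        anchor = variant[10_200:10_900]  # inside the variant-only insert
        rs = select_reads(r1 + r2, anchor, min_match=300)
        assert rs.reads and all(rid.startswith("v") for rid, _ in rs.reads)


class TestWalk:
    def test_repeat_free_circle_exact_reconstruction(self, rng):
        truth = random_seq(rng, 30_000)
        sim = circular_reads(truth, depth=20, seed=3)
        contig = walk(sim.reads, truth[5_000:6_000], compute_support=True)
        assert contig.circular
        assert canon(contig.sequence) == canon(truth)
        assert min(contig.support) >= 1

    def test_walk_blocks_at_long_duplication(self, rng):
        """A 10 kb block shared by two plasmids blocks 3 kb-read walks at
        both entries, with established repeat length >= read length."""
        dup = random_seq(rng, 10_000)
        p1 = random_seq(rng, 25_000) + dup
        p2 = random_seq(rng, 18_000) + dup
        reads = (circular_reads(p1, depth=20, seed=5, name="p1").reads
                 + circular_reads(p2, depth=20, seed=6, name="p2").reads)
        contig = walk(reads, p1[10_000:11_000])
        assert contig.left.status == "repeat_blocked"
        assert contig.right.status == "repeat_blocked"
        assert contig.left.repeat_min >= 3_000
        assert contig.right.repeat_min >= 3_000
        # the unique region is fully covered
        assert p1[:25_000] in ("X" + contig.sequence + "X")[1:-1] or p1[:25_000] in contig.sequence

    def test_seed_below_depth_refused(self, rng):
        reads = [("r", random_seq(rng, 3_000))]
        with pytest.raises(ValueError, match="min_depth"):
            walk(reads, random_seq(rng, 800))

    def test_optional_mge_locus_reports_two_variants(self, rng):
        """Half the reads carry an element, half the empty site."""
        base = random_seq(rng, 24_000)
        with_mge = base[:12_000] + random_seq(rng, 1_400) + base[12_000:]
        reads = (circular_reads(base, depth=14, seed=7, name="empty").reads
                 + circular_reads(with_mge, depth=14, seed=8, name="mge").reads)
        contig = walk(reads, base[6_000:7_000])
        statuses = {contig.left.status, contig.right.status}
        assert "variant_fork" in statuses
        fork = contig.left if contig.left.status == "variant_fork" else contig.right
        assert len(fork.variants) == 2
        counts = sorted(c for _ctx, c in fork.variants)
        assert counts[0] >= 5  # both branches well supported at depth 14

    def test_monotonicity_more_reads_never_shorten(self, rng):
        truth = random_seq(rng, 40_000)
        sim1 = circular_reads(truth, depth=6, seed=9)
        sim2 = circular_reads(truth, depth=6, seed=10)
        seed_seq = truth[2_000:3_000]
        len1 = len(walk(sim1.reads, seed_seq).sequence)
        len2 = len(walk(sim1.reads + sim2.reads, seed_seq).sequence)
        assert len2 >= min(len1, 40_000)


class TestHeterogeneity:
    def test_homogeneous_reads_one_variant(self, rng):
        seq = random_seq(rng, 20_000)
        sim = circular_reads(seq, depth=10, seed=11)
        rep = detect_heterogeneity(sim.reads, seq[8_000:8_400])
        assert rep.status == "ok"
        assert len(rep.variants) == 1

    def test_fifty_fifty_mix_two_variants(self, rng):
        base = random_seq(rng, 20_000)
        variant = base[:10_000] + random_seq(rng, 1_300) + base[10_000:]
        reads = (circular_reads(base, depth=15, seed=12, name="a").reads
                 + circular_reads(variant, depth=15, seed=13, name="b").reads)
        rep = detect_heterogeneity(reads, base[9_500:9_990])
        assert rep.status == "ok"
        assert len(rep.variants) == 2
        counts = sorted(c for _v, c in rep.variants)
        assert counts[0] / sum(counts) > 0.25  # roughly the mix ratio

    def test_low_depth_is_undecidable(self, rng):
        seq = random_seq(rng, 10_000)
        reads = [("r1", seq[1_000:3_000])]
        rep = detect_heterogeneity(reads, seq[1_500:1_900])
        assert rep.status == "undecidable"


class TestGuideResolution:
    def make_arm_plasmid(self, rng):
        """Circular plasmid: unique1 + armF + unique2 + armR (arms 8 kb)."""
        arm = random_seq(rng, 8_000)
        u1, u2 = random_seq(rng, 15_000), random_seq(rng, 12_000)
        return u1 + arm + u2 + revcomp(arm), u1, u2, arm

    def test_contigs_joined_across_arms(self, rng):
        truth, u1, u2, arm = self.make_arm_plasmid(rng)
        sim = circular_reads(truth, depth=20, seed=14)
        c1 = walk(sim.reads, u1[6_000:7_000])
        c2 = walk(sim.reads, u2[5_000:6_000])
        assert c1.right.status == "repeat_blocked"
        res = resolve_with_guide([c1, c2], truth)  # guide: sibling strain copy
        assert not res.unresolved
        assert res.junctions_resolved == 2
        assert canon(res.sequence) == canon(truth)
        sources = {m.source for m in res.mask}
        assert sources == {"read", "guide"}
        covered = sum(m.end - m.start + 1 for m in res.mask)
        assert covered == len(res.sequence)  # provenance partitions exactly

    def test_single_matching_contig_identity(self, rng):
        truth, u1, _u2, _arm = self.make_arm_plasmid(rng)
        res = resolve_with_guide([truth], truth)
        assert res.sequence == truth
        assert [m.source for m in res.mask] == ["read"]

    def test_wrong_guide_resolves_nothing(self, rng):
        truth, u1, u2, _arm = self.make_arm_plasmid(rng)
        sim = circular_reads(truth, depth=20, seed=15)
        c1 = walk(sim.reads, u1[6_000:7_000])
        res = resolve_with_guide([c1], random_seq(rng, 40_000))
        assert res.junctions_resolved == 0
        assert res.unresolved


class TestCompletion:
    def test_zero_gap_returns_partial(self, rng):
        donor = random_seq(rng, 30_000)
        comp = insilico_complete(donor, donor)
        assert comp.sequence == donor and comp.transferred == 0

    def test_partial_completed_from_donor_exactly(self, rng):
        """Partial assembly with both termini inside a shared duplication."""
        shared = random_seq(rng, 20_000)
        uniq_b = random_seq(rng, 40_000)
        uniq_c = random_seq(rng, 25_000)
        p_b = uniq_b + shared  # truth to reconstruct
        donor = uniq_c + shared
        # partial: unique part plus 2 kb into the duplication at both ends
        partial = shared[-2_000:] + uniq_b + shared[:2_000]
        sim = circular_reads(p_b, depth=20, seed=16, name="pb")
        comp = insilico_complete(partial, donor, reads=sim.reads)
        assert comp.transferred == 16_000
        assert canon(comp.sequence) == canon(p_b)
        assert [m.source for m in comp.mask] == ["read", "donor"]

    def test_donor_mismatch_inside_duplication_refused(self, rng):
        shared = random_seq(rng, 20_000)
        uniq_b = random_seq(rng, 40_000)
        p_b = uniq_b + shared
        donor_bad = list(random_seq(rng, 25_000) + shared)
        donor_bad[25_000 + 10_000] = {"A": "C", "C": "G", "G": "T", "T": "A"}[
            donor_bad[25_000 + 10_000]
        ]
        partial = shared[-2_000:] + uniq_b + shared[:2_000]
        sim = circular_reads(p_b, depth=20, seed=17, name="pb")
        with pytest.raises(HeterogeneityConflict) as err:
            insilico_complete(partial, "".join(donor_bad), reads=sim.reads)
        assert err.value.positions
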