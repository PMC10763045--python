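"""Repair operations: extension, merging, splitting, local fixes.

Fixers are exercised with hand-crafted signatures so each contract is
checked in isolation; end-to-end behaviour is covered by the pipeline and
acceptance tests.
"""

import pytest

from strefine._seq import revcomp
from strefine.core import (Assembly, Contig, CoverageBreak, InternalClipSite,
                           OverlapHit, Parameters, SoftClipCluster)
from strefine.fixers import (extend_with_clips, extend_with_orphans,
                             fix_missing_sequence,
                             fix_translocation_inversion,
                             merge_fragments_by_clip,
                             merge_fragments_by_islands,
                             remove_unsupported_insertion,
                             resolve_adjacency_move, split_chimera_at_clip,
                             split_chimera_at_coverage,
                             split_chimera_at_crisscross)

from conftest import random_seq


def _cluster(contig_id, position, direction, n=5):
    return SoftClipCluster(contig_id=contig_id, position=position,
                           direction=direction, n_reads=n,
                           support_fraction=1.0,
                           fragments=[(0, "ACGT")] * n)


class TestClipExtension:
    def test_left_consensus_prepended(self):
        contig = Contig("c", "ACGTACGT")
        new, gain = extend_with_clips(contig, _cluster("c", 0, "left"), "TTG")
        assert new.sequence == "TTGACGTACGT" and gain == 3

    def test_right_consensus_appended(self, rng):
        contig = Contig("c", random_seq(rng, 500))
        cons = random_seq(rng, 30)
        new, gain = extend_with_clips(
            contig, _cluster("c", 500, "right"), cons)
        assert gain == 30 and new.sequence == contig.sequence + cons

    def test_off_boundary_cluster_replaces_unsupported_tail(self):
        contig = Contig("c", "ACGTACGT")
        new, gain = extend_with_clips(contig, _cluster("c", 6, "right"),
                                      "TTTTT")
        assert new.sequence == "ACGTAC" + "TTTTT"


class TestOrphanExtension:
    def test_overlapping_block_stitched_when_gain_sufficient(self, rng):
        source = random_seq(rng, 700)
        contig = Contig("c", source[:400])
        # mates spanning [360, 560): 40-base overlap, 160-base gain
        mates = [source[i:i + 100] for i in range(360, 461, 20)]
        out = extend_with_orphans(contig, "right", mates, read_length=100)
        assert out.contig is not None
        assert out.contig.sequence == source[:560]
        assert out.gain == 160

    def test_small_gain_rejected(self, rng):
        source = random_seq(rng, 500)
        contig = Contig("c", source[:400])
        mates = [source[i:i + 100] for i in range(320, 341, 10)]  # gain 40
        out = extend_with_orphans(contig, "right", mates, read_length=100)
        assert out.contig is None and out.pending_block is None

    def test_disjoint_block_returned_as_pending(self, rng):
        contig = Contig("c", random_seq(rng, 400))
        far = random_seq(rng, 250)
        mates = [far[i:i + 100] for i in range(0, 151, 25)]
        out = extend_with_orphans(contig, "right", mates, read_length=100)
        assert out.contig is None
        assert out.pending_block is not None
        assert len(out.pending_block) == 250


class TestClipMerge:
    def test_extension_landing_on_partner_merges(self, rng):
        source = random_seq(rng, 1200)
        # piece A extended 60 bases into B's territory; B intact
        a = Contig("a", source[:660])
        b = Contig("b", source[600:])
        asm = Assembly([a, b])
        out = merge_fragments_by_clip(asm, "a", "right")
        assert out is not None
        assert out.merged.sequence == source
        assert (out.left_id, out.right_id) == ("a", "b")

    def test_imperfect_seed_blocks_merge(self, rng):
        source = random_seq(rng, 1200)
        ext = list(source[600:660])
        ext[-5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[ext[-5]]
        a = Contig("a", source[:600] + "".join(ext))
        b = Contig("b", source[600:])
        asm = Assembly([a, b])
        assert merge_fragments_by_clip(asm, "a", "right") is None

    def test_best_scoring_partner_chosen(self, rng):
        source = random_seq(rng, 900)
        a = Contig("a", source[:500])           # ends with seed region
        exact = Contig("b", source[475:])       # full 25-base seed match
        partial = Contig("d", source[487:512] + random_seq(rng, 400))
        asm = Assembly([a, exact, partial])
        out = merge_fragments_by_clip(asm, "a", "right")
        assert out is not None and out.right_id == "b"


class TestIslandMerge:
    class _Island:
        def __init__(self, cid, edge, partner, p_edge):
            self.contig_id, self.edge = cid, edge
            self.partner_contig_id, self.partner_edge = partner, p_edge

    def test_terminal_overlap_merged(self, rng):
        source = random_seq(rng, 900)
        a = Contig("a", source[:500])
        b = Contig("b", source[475:])
        asm = Assembly([a, b])
        out = merge_fragments_by_islands(
            asm, self._Island("a", "right", "b", "left"), read_length=100)
        assert out is not None and out.merged.sequence == source
        assert out.overlap == 25

    def test_overlap_below_ten_bases_rejected(self, rng):
        source = random_seq(rng, 900)
        a = Contig("a", source[:483])
        b = Contig("b", source[475:])
        asm = Assembly([a, b])
        out = merge_fragments_by_islands(
            asm, self._Island("a", "right", "b", "left"), read_length=100)
        assert out is None


class TestChimeraSplits:
    def _one_sided(self, pos, consensus, kind="one_sided_right"):
        return InternalClipSite(contig_id="x", kind=kind, positions=(pos,),
                                right_consensus=consensus, n_reads=10,
                                support_fraction=1.0)

    def test_fusion_split_into_two_pieces(self, rng):
        p1, p2 = random_seq(rng, 800), random_seq(rng, 900)
        contig = Contig("x", p1 + p2)
        # clip consensus = continuation absent from the contig
        site = self._one_sided(800, random_seq(rng, 40))
        out = split_chimera_at_clip(contig, site)
        assert out.kind == "chimera-split-clip"
        assert [c.sequence for c in out.contigs_out] == [p1, p2]

    def test_small_split_piece_discarded(self, rng):
        p1, p2 = random_seq(rng, 150), random_seq(rng, 900)
        contig = Contig("x", p1 + p2)
        site = self._one_sided(150, random_seq(rng, 40), "one_sided_left")
        site = InternalClipSite(contig_id="x", kind="one_sided_left",
                                positions=(150,),
                                left_consensus=random_seq(rng, 40),
                                n_reads=10, support_fraction=1.0)
        out = split_chimera_at_clip(contig, site)
        assert out.kind == "discarded"
        assert [c.sequence for c in out.contigs_out] == [p2]
        assert out.removed == [p1]

    def test_internal_repeat_excised_and_flanks_rejoined(self, rng):
        """A duplicated block whose clip consensus re-occurs in the contig
        is removed and the flanks joined across their exact overlap."""
        left = random_seq(rng, 400)
        dup = random_seq(rng, 150)
        right = random_seq(rng, 400)
        contig = Contig("x", left + dup + dup + right)
        site = self._one_sided(400 + 150, dup[:60])
        out = split_chimera_at_clip(contig, site, read_length=100)
        assert out.kind == "self-chimera-removed"
        # one duplicate copy excised
        assert out.contigs_out[0].sequence == left + dup + right

    def test_crisscross_fusion_keeps_overlap_bases_on_both_pieces(self, rng):
        p1, p2 = random_seq(rng, 700), random_seq(rng, 800)
        contig = Contig("x", p1 + p2)
        site = InternalClipSite(
            contig_id="x", kind="crisscross", positions=(703, 699),
            left_consensus=random_seq(rng, 40),
            right_consensus=random_seq(rng, 40), n_reads=12,
            support_fraction=1.0)
        out = split_chimera_at_crisscross(contig, site)
        pieces = [c.sequence for c in out.contigs_out]
        assert pieces[0] == (p1 + p2)[:703]
        assert pieces[1] == (p1 + p2)[699:]
        assert p1 in pieces[0] and p2 in pieces[1]

    def test_coverage_break_split(self, rng):
        p1, p2 = random_seq(rng, 600), random_seq(rng, 1000)
        contig = Contig("x", p1 + p2)
        out = split_chimera_at_coverage(
            contig, CoverageBreak("x", 600, 100.0, 10.0))
        assert out.kind == "chimera-split-coverage"
        assert [c.sequence for c in out.contigs_out] == [p1, p2]


class TestLocalFixes:
    def test_missing_sequence_restored_by_bridge(self, rng):
        original = random_seq(rng, 1000)
        missing = original[500:560]
        contig = Contig("x", original[:500] + original[560:])
        site = InternalClipSite(
            contig_id="x", kind="crisscross", positions=(500, 500),
            right_consensus=missing + original[560:590],  # runs into flank
            left_consensus=original[470:500] + missing,
            n_reads=10, support_fraction=1.0)
        out = fix_missing_sequence(contig, site)
        assert out is not None and out.kind == "missing-inserted"
        assert out.contig.sequence == original

    def test_missing_sequence_concat_when_unbridged(self, rng):
        original = random_seq(rng, 1000)
        missing = original[500:700]  # longer than both consensi
        contig = Contig("x", original[:500] + original[700:])
        site = InternalClipSite(
            contig_id="x", kind="crisscross", positions=(500, 500),
            right_consensus=missing[:50], left_consensus=missing[-50:],
            n_reads=10, support_fraction=1.0)
        out = fix_missing_sequence(contig, site)
        assert out.contig.sequence == \
            original[:500] + missing[:50] + missing[-50:] + original[700:]
        assert fix_missing_sequence(contig, site, allow_concat=False) is None

    def _hit(self, s0, s1, strand="+"):
        return OverlapHit(query_range=(0, s1 - s0), subject_contig_id="x",
                          subject_range=(s0, s1), strand=strand,
                          identity_pct=100.0, n_gaps=0, score=100.0)

    def test_translocation_round_trip(self, rng):
        original = random_seq(rng, 1500)
        block = original[400:600]  # moved 500 bases downstream
        mutated = original[:400] + original[600:1100] + block + original[1100:]
        contig = Contig("x", mutated)
        site = InternalClipSite(contig_id="x", kind="crisscross",
                                positions=(400, 400),
                                left_consensus=block[-40:],
                                right_consensus=block[:40],
                                n_reads=10, support_fraction=1.0)
        out = fix_translocation_inversion(
            contig, site, self._hit(900 + 160, 900 + 200),
            self._hit(900, 900 + 40))
        assert out.kind == "translocation-fixed"
        assert out.contig.sequence == original
        assert len(out.contig.sequence) == len(mutated)

    def test_inversion_round_trip(self, rng):
        original = random_seq(rng, 1200)
        block = original[300:500]
        mutated = original[:300] + original[500:800] + revcomp(block) + \
            original[800:]
        contig = Contig("x", mutated)
        # reverse-strand hits bound the inverted copy at [600, 800)
        site = InternalClipSite(contig_id="x", kind="crisscross",
                                positions=(300, 300),
                                left_consensus=block[-40:],
                                right_consensus=block[:40],
                                n_reads=10, support_fraction=1.0)
        out = fix_translocation_inversion(
            contig, site, self._hit(600, 640, "-"), self._hit(760, 800, "-"))
        assert out.kind == "inversion-fixed"
        assert out.contig.sequence == original

    def test_adjacency_pair_resolves_inversion(self, rng):
        """The split-signature form: a bypass site plus a reverse-strand
        destination site jointly identify the moved block."""
        original = random_seq(rng, 1200)
        block = original[300:500]
        mutated = original[:300] + revcomp(block) + original[500:]
        # here the inverted copy sits in place: craft the moved layout
        mutated = original[:200] + revcomp(block) + original[200:300] + \
            original[500:]
        contig = Contig("x", mutated)
        sited = [
            ("left", 400, self._hit(160, 200)),          # bypass [200, 400)
            ("right", 500, self._hit(200, 400, "-")),    # destination
        ]
        out = resolve_adjacency_move(contig, sited)
        assert out is not None and out.kind == "inversion-fixed"
        assert out.contig.sequence == \
            original[:200] + original[200:300] + block + original[500:]

    def test_insertion_removed_exactly(self, rng):
        original = random_seq(rng, 1000)
        ins = random_seq(rng, 70)
        contig = Contig("x", original[:500] + ins + original[500:])
        site = InternalClipSite(
            contig_id="x", kind="facing", positions=(500, 570),
            right_consensus=original[500:550],
            left_consensus=original[460:500],
            n_reads=10, support_fraction=1.0)
        out = remove_unsupported_insertion(contig, site)
        assert out.kind == "insertion-removed"
        assert out.contig.sequence == original
        assert len(out.seq_delta) == 70  # deleted length = clip distance

    def test_insertion_with_overshot_clip_points(self, rng):
        """Clip points that extended into the insert by chance matches are
        recovered by the shift probe."""
        original = random_seq(rng, 1000)
        ins = random_seq(rng, 60)
        contig = Contig("x", original[:500] + ins + original[500:])
        # observed clip points 2 bases into the insert on the left side
        site = InternalClipSite(
            contig_id="x", kind="facing", positions=(502, 560),
            right_consensus=original[502:552],
            left_consensus=original[460:500],
            n_reads=10, support_fraction=1.0)
        out = remove_unsupported_insertion(contig, site)
        assert out is not None and out.contig.sequence == original

    def test_cross_mapping_precondition_guards(self, rng):
        original = random_seq(rng, 1000)
        contig = Contig("x", original)
        site = InternalClipSite(
            contig_id="x", kind="facing", positions=(500, 570),
            right_consensus=random_seq(rng, 50),
            left_consensus=random_seq(rng, 40),
            n_reads=10, support_fraction=1.0)
        assert remove_unsupported_insertion(contig, site) is None
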