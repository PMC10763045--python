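"""Signature detection: edge clips, orphan clusters, internal sites,
mate islands and coverage breaks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strefine.core import Assembly, Contig, CoverageProfile, Parameters
from strefine.signatures import (find_abrupt_breaks, find_edge_clip_clusters,
                                 find_gradual_breaks, find_internal_clip_sites,
                                 find_mate_islands, find_orphan_mate_clusters)

from conftest import make_record, random_seq


def _contig(n=2000):
    return Contig("c", "A" * n)


class TestEdgeClipClusters:
    def test_left_clips_at_origin_full_support(self):
        recs = [make_record("c", 0, "10S90M", seq="G" * 10 + "A" * 90,
                            read_id=f"r{i}") for i in range(4)]
        (cl,) = find_edge_clip_clusters(recs, _contig())
        assert cl.position == 0 and cl.direction == "left"
        assert cl.n_reads == 4 and cl.support_fraction == 1.0
        assert all(f == "G" * 10 for _, f in cl.fragments)

    def test_two_reads_below_minimum(self):
        recs = [make_record("c", 0, "10S90M") for _ in range(2)]
        assert find_edge_clip_clusters(recs, _contig()) == []

    def test_spanning_reads_defeat_support(self):
        contig = Contig("c", "A" * 2000)
        clipped = [make_record("c", 20, "10S80M", read_id=f"c{i}")
                   for i in range(3)]
        spanning = [make_record("c", 5, "100M", read_id=f"s{i}")
                    for i in range(3)]
        assert find_edge_clip_clusters(clipped + spanning, contig) == []
        # without the spanning reads the cluster qualifies
        assert len(find_edge_clip_clusters(clipped, contig)) == 1

    def test_inward_clips_not_edge_signature(self):
        # right-clips near the left boundary point inward
        recs = [make_record("c", 0, "20M80S") for _ in range(4)]
        assert find_edge_clip_clusters(recs, _contig()) == []

    def test_one_base_overhang_at_boundary_counts(self):
        recs = [make_record("c", 1900, "99M1S", read_id=f"r{i}")
                for i in range(5)]
        (cl,) = find_edge_clip_clusters(recs, _contig(1999))
        assert cl.direction == "right" and cl.position == 1999


class TestOrphanClusters:
    def _anchor(self, i, clip="0", strand="+", start=1850):
        cigar = "100M" if clip == "0" else f"70M30S"
        return make_record("c", start, cigar, strand=strand,
                           orientation="mate-unmapped", read_id=f"r{i}")

    def test_three_outward_unclipped_anchors_cluster(self):
        recs = [self._anchor(i) for i in range(3)]
        (cl,) = find_orphan_mate_clusters(recs, _contig())
        assert cl.edge == "right" and cl.n_reads == 3

    def test_heavily_clipped_anchors_rejected(self):
        recs = [self._anchor(i, clip="30") for i in range(3)]
        assert find_orphan_mate_clusters(recs, _contig()) == []

    def test_inward_pointing_reads_ignored(self):
        recs = [self._anchor(i, strand="-") for i in range(3)]
        assert find_orphan_mate_clusters(recs, _contig()) == []


class TestInternalClipSites:
    def _one_sided(self, pos=500, n=10):
        seq = "A" * 60 + "G" * 40
        return [make_record("c", pos - 60, "60M40S", seq=seq,
                            read_id=f"r{i}") for i in range(n)]

    def test_one_sided_right_site(self):
        sites = find_internal_clip_sites(self._one_sided(), _contig())
        (site,) = sites
        assert site.kind == "one_sided_right"
        assert site.positions == (500,)
        assert len(site.right_consensus) == 40

    def test_junction_position_excluded(self):
        sites = find_internal_clip_sites(
            self._one_sided(), _contig(), junctions={"c": {500}})
        assert sites == []

    def test_short_consensus_rejected(self):
        recs = [make_record("c", 440, "60M8S", seq="A" * 60 + "G" * 8,
                            read_id=f"r{i}") for i in range(10)]
        assert find_internal_clip_sites(recs, _contig()) == []

    def test_crisscross_and_facing_classification(self):
        # right-clips at 500 and left-clips at 500 -> crisscross
        right = self._one_sided(500, 6)
        left = [make_record("c", 500, "40S60M", seq="G" * 40 + "A" * 60,
                            read_id=f"l{i}") for i in range(6)]
        sites = find_internal_clip_sites(right + left, _contig())
        assert [s.kind for s in sites] == ["crisscross"]
        # right-clips at 500, left-clips at 560 -> facing
        left2 = [make_record("c", 560, "40S60M", seq="G" * 40 + "A" * 60,
                             read_id=f"l{i}") for i in range(6)]
        sites = find_internal_clip_sites(right + left2, _contig())
        assert [s.kind for s in sites] == ["facing"]
        assert sites[0].positions == (500, 560)


class TestMateIslands:
    def _pair(self, i, n_contig="c2"):
        a = make_record("c1", 1900, "100M", strand="+", orientation="cross",
                        read_id=f"p{i}", mate_contig_id=n_contig, mate_start=5)
        b = make_record(n_contig, 5, "100M", strand="-", orientation="cross",
                        read_id=f"p{i}", mate_contig_id="c1", mate_start=1900)
        return [a, b]

    def _assembly(self):
        return Assembly([Contig("c1", "A" * 2000), Contig("c2", "C" * 1500),
                         Contig("c3", "G" * 1500), Contig("c4", "T" * 1500)])

    def test_five_linked_reads_form_island_pair(self):
        recs = [r for i in range(5) for r in self._pair(i)]
        (isl,) = find_mate_islands(recs, self._assembly())
        assert isl.contig_id == "c1" and isl.partner_contig_id == "c2"
        assert isl.edge == "right" and isl.partner_edge == "left"
        assert len(isl.read_ids) == 5

    def test_four_reads_below_threshold(self):
        recs = [r for i in range(4) for r in self._pair(i)]
        assert find_mate_islands(recs, self._assembly()) == []

    def test_mates_scattered_over_contigs_rejected(self):
        recs = []
        for i, partner in enumerate(["c2", "c2", "c3", "c3", "c4", "c4"]):
            recs.extend(self._pair(i, partner))
        assert find_mate_islands(recs, self._assembly()) == []


class TestCoverageBreaks:
    def _profile(self, depths):
        d = np.asarray(depths, dtype=np.int64)
        return CoverageProfile("c", d)

    def test_abrupt_drop_of_84_pct_detected(self):
        depth = [50] * 200 + [8] * 200
        (brk,) = find_abrupt_breaks(self._profile(depth), read_length=100)
        assert brk.position == 200
        assert brk.left_depth == 50 and brk.right_depth == 8

    def test_ten_pct_change_ignored(self):
        depth = [50] * 200 + [45] * 200
        assert find_abrupt_breaks(self._profile(depth), read_length=100) == []

    def test_end_ignore_zone_suppresses_calls(self):
        depth = [50] * 30 + [8] * 370  # break at 30, inside end-ignore
        assert find_abrupt_breaks(self._profile(depth), read_length=100) == []

    def test_zero_coverage_run_breaks_both_ends(self):
        depth = [40] * 200 + [0] * 50 + [40] * 200
        brks = find_abrupt_breaks(self._profile(depth), read_length=100)
        assert [b.position for b in brks] == [200, 250]

    @given(st.integers(min_value=2, max_value=20))
    @settings(deadline=None, max_examples=10)
    def test_scale_invariance(self, factor):
        depth = [50] * 150 + [7] * 150 + [50] * 150
        base = find_abrupt_breaks(self._profile(depth), read_length=100)
        scaled = find_abrupt_breaks(
            self._profile([d * factor for d in depth]), read_length=100)
        assert [b.position for b in base] == [b.position for b in scaled]

    def test_gradual_off_by_default(self):
        ramp = [50] * 250 + list(range(50, 4, -3)) + [5] * 250
        assert find_gradual_breaks(self._profile(ramp), read_length=100) == []

    def test_gradual_ramp_detected_when_enabled(self):
        ramp = [50] * 250 + list(np.linspace(50, 5, 20).astype(int)) + [5] * 250
        params = Parameters(gradual_check=True)
        brks = find_gradual_breaks(self._profile(ramp), params,
                                   read_length=100)
        assert len(brks) == 1
        assert abs(brks[0].position - 260) < 30
        # no single-step change reaches the abrupt threshold
        assert find_abrupt_breaks(self._profile(ramp), read_length=100) == []

    def test_flat_profile_no_gradual_calls(self):
        params = Parameters(gradual_check=True)
        assert find_gradual_breaks(self._profile([30] * 600), params,
                                   read_length=100) == []
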