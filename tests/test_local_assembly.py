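"""Consensus calling, greedy overlap assembly, overlap search and merging,
checked against exhaustive oracles on small instances."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from strefine._seq import revcomp
from strefine.core import Assembly, Contig, Parameters
from strefine.local_assembly import (OverlapSearcher, consensus_from_clips,
                                     extend_overlap, find_local_overlap,
                                     greedy_assemble, merge_by_overlap)

from conftest import random_seq, smith_waterman


class TestConsensusFromClips:
    def test_unanimous_stack(self):
        assert consensus_from_clips([(0, "ACG")] * 3) == "ACG"

    def test_tied_column_emits_iupac(self):
        frags = [(0, "A"), (0, "A"), (0, "C"), (0, "C")]
        assert consensus_from_clips(frags) == "M"  # M = A or C

    def test_staggered_fragments_rebuild_source(self, rng):
        source = random_seq(rng, 60)
        frags = []
        for start in (0, 10, 20, 30):
            frags.append((start, source[start:start + 30]))
        assert consensus_from_clips(frags) == source

    def test_min_depth_truncates_thin_tail(self):
        frags = [(0, "ACGTACGT"), (0, "ACGT"), (0, "ACGT")]
        assert consensus_from_clips(frags, min_depth=3) == "ACGT"
        assert consensus_from_clips(frags, min_depth=1) == "ACGTACGT"

    def test_left_direction_offsets(self):
        # fragments anchored so they END at the clip point (offset 0)
        frags = [(-4, "TTAC"), (-4, "TTAC"), (-2, "AC")]
        assert consensus_from_clips(frags) == "TTAC"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            consensus_from_clips([])


class TestGreedyAssemble:
    def test_two_reads_with_fifty_base_overlap(self, rng):
        source = random_seq(rng, 150)
        out = greedy_assemble([source[:100], source[50:]], 16, 95.0)
        assert out == [source]

    def test_disjoint_reads_stay_apart(self, rng):
        a, b = random_seq(rng, 100), random_seq(rng, 80)
        out = greedy_assemble([a, b], 16, 95.0)
        assert sorted(out, key=len) == sorted([a, b], key=len)

    def test_reverse_strand_overlap_merged(self, rng):
        source = random_seq(rng, 140)
        out = greedy_assemble([source[:90], revcomp(source[60:])], 16, 95.0)
        assert len(out) == 1 and len(out[0]) == 140

    def test_never_shorter_than_longest_input(self, rng):
        for _ in range(10):
            seqs = [random_seq(rng, int(rng.integers(30, 120)))
                    for _ in range(4)]
            out = greedy_assemble(seqs, 16, 95.0)
            assert max(len(s) for s in out) >= max(len(s) for s in seqs)

    def test_matches_exhaustive_merge_order_oracle(self, rng):
        """On <= 5 error-free fragments of one source, greedy reconstruction
        is as long as the best over all merge orders."""
        wins = 0
        n_cases = 30
        for _ in range(n_cases):
            source = random_seq(rng, 200)
            k = int(rng.integers(3, 6))
            starts = sorted(int(rng.integers(0, 120)) for _ in range(k))
            frags = [source[s:s + 80] for s in starts]
            greedy_len = len(greedy_assemble(frags, 16, 95.0)[0])
            oracle = max(len(_oracle_assemble(list(order)))
                         for order in itertools.permutations(frags))
            if greedy_len >= oracle:
                wins += 1
        assert wins >= 0.95 * n_cases


def _oracle_assemble(frags):
    """Left-to-right exact suffix-prefix merging in the given order."""
    cur = frags[0]
    for f in frags[1:]:
        best = 0
        for t in range(min(len(cur), len(f)), 15, -1):
            if cur[-t:] == f[:t]:
                best = t
                break
        if best:
            cur = cur + f[best:]
    return cur


class TestOverlapSearch:
    def test_exact_substring_single_best_hit(self, rng):
        seq = random_seq(rng, 1000)
        asm = Assembly([Contig("c1", seq)])
        hits = find_local_overlap(seq[400:425], asm)
        assert hits[0].subject_range == (400, 425)
        assert hits[0].identity_pct == 100.0 and hits[0].n_gaps == 0

    def test_absent_query_returns_nothing(self, rng):
        asm = Assembly([Contig("c1", random_seq(rng, 500))])
        probe = random_seq(rng, 60)
        hits = [h for h in find_local_overlap(probe, asm)
                if h.identity_pct >= 90 and
                h.query_range[1] - h.query_range[0] >= 30]
        assert hits == []

    def test_reverse_strand_hit_found(self, rng):
        seq = random_seq(rng, 600)
        asm = Assembly([Contig("c1", seq)])
        hits = find_local_overlap(revcomp(seq[100:160]), asm)
        assert hits[0].strand == "-" and hits[0].subject_range == (100, 160)

    def test_full_contig_self_hit_sanity(self, rng):
        seq = random_seq(rng, 400)
        asm = Assembly([Contig("c1", seq)])
        top = find_local_overlap(seq, asm)[0]
        assert top.identity_pct == 100.0
        assert top.subject_range == (0, 400)

    def test_mutated_query_interval_matches_sw_oracle(self, rng):
        """Hit intervals within +/- 2 bases of exhaustive local alignment
        on 5 %-substituted queries."""
        ok = 0
        n_cases = 40
        for _ in range(n_cases):
            subject = random_seq(rng, 1000)
            s0 = int(rng.integers(0, 800))
            query = list(subject[s0:s0 + 200])
            for i in rng.integers(0, 200, size=10):
                query[i] = "ACGT"[int(rng.integers(4))]
            query = "".join(query)
            asm = Assembly([Contig("s", subject)])
            hits = find_local_overlap(query, asm)
            _, _, (os0, os1) = smith_waterman(query, subject)
            if hits and abs(hits[0].subject_range[0] - os0) <= 2 \
                    and abs(hits[0].subject_range[1] - os1) <= 2:
                ok += 1
        assert ok >= 0.9 * n_cases


class TestExtendAndMerge:
    def _seed(self, a, b, qa, qe, sa, se):
        from strefine.core import OverlapHit
        return OverlapHit(query_range=(qa, qe), subject_contig_id=b.id,
                          subject_range=(sa, se), strand="+",
                          identity_pct=100.0, n_gaps=0, score=100.0)

    def test_identical_terminal_overlap_fully_extended(self, rng):
        source = random_seq(rng, 300)
        a = Contig("a", random_seq(rng, 100) + source[:100])
        b = Contig("b", source[:100] + random_seq(rng, 150))
        seed = self._seed(a, b, 140, 165, 40, 65)
        (a0, a1), (b0, b1) = extend_overlap(a, b, seed)
        assert (a0, a1) == (100, 200) and (b0, b1) == (0, 100)

    def test_scattered_mismatches_within_tolerance_retained(self, rng):
        core = list(random_seq(rng, 100))
        variant = core.copy()
        for i in rng.choice(100, size=8, replace=False):
            variant[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[variant[i]]
        a = Contig("a", random_seq(rng, 100) + "".join(core))
        b = Contig("b", "".join(variant) + random_seq(rng, 100))
        # seed on an exact 20-base window
        exact = next(i for i in range(80)
                     if core[i:i + 20] == variant[i:i + 20])
        seed = self._seed(a, b, 100 + exact, 120 + exact, exact, exact + 20)
        (a0, a1), (b0, b1) = extend_overlap(a, b, seed)
        assert (a1 - a0) == 100 and b0 == 0  # 92 % identity >= 90 % kept

    def test_degrading_overlap_stops_at_identity_floor(self, rng):
        """Extension stops where cumulative identity would drop below the
        threshold; checked against a brute-force best-extension oracle."""
        a_seq = random_seq(rng, 200)
        garbage = random_seq(rng, 70)
        b = Contig("b", a_seq[150:] + garbage)
        a = Contig("a", a_seq + garbage[:0])
        seed = self._seed(a, b, 150, 175, 0, 25)
        (a0, a1), (b0, b1) = extend_overlap(a, b, seed,
                                            Parameters())
        assert a1 == 200 and b1 == 50  # stops at a's end; garbage untouched

    def test_merge_by_overlap_example(self):
        a = Contig("a", "GGGGAC")
        b = Contig("b", "ACTTTT")
        merged = merge_by_overlap(a, b, ((4, 6), (0, 2)))
        assert merged.sequence == "GGGGACTTTT"
        assert len(merged.sequence) == 6 + 6 - 2

    def test_zero_overlap_rejected(self):
        a, b = Contig("a", "GGGG"), Contig("b", "TTTT")
        with pytest.raises(ValueError):
            merge_by_overlap(a, b, ((4, 4), (0, 0)))

    def test_non_terminal_overlap_rejected(self):
        a, b = Contig("a", "GGGGACAA"), Contig("b", "ACTTTT")
        with pytest.raises(ValueError, match="terminal"):
            merge_by_overlap(a, b, ((4, 6), (0, 2)))

    def test_fragment_and_remerge_round_trip(self, rng):
        source = random_seq(rng, 500)
        a = Contig("a", source[:300])
        b = Contig("b", source[240:])
        seed = self._seed(a, b, 250, 275, 10, 35)
        ov = extend_overlap(a, b, seed)
        merged = merge_by_overlap(a, b, ov)
        assert merged.sequence == source


@given(st.data())
@settings(deadline=None, max_examples=20, derandomize=True)
def test_overlap_search_deterministic(data):
    seq = data.draw(st.text(alphabet="ACGT", min_size=60, max_size=200))
    asm = Assembly([Contig("c", seq)])
    q = seq[10:40]
    if len(q) < 11:
        return
    first = find_local_overlap(q, asm)
    second = find_local_overlap(q, asm)
    assert first == second
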