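"""Read alignment: built-in aligner, filtering, coverage, junctions,
edge-read selection.

The built-in aligner places each mate at its best gapless location by
exact k-mer seeding (k=15) and maximum-scoring-segment extension, with
soft-clips at unextendable ends and a mapq that reflects placement
uniqueness (40 x (1 - second_best/best), capped at 60). When alignments
are supplied as SAM the built-in aligner is bypassed for that pass.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence

import numpy as np

from . import _kernels
from ._seq import encode_code2, encode_mask4, revcomp
from .core import (AlignmentRecord, Assembly, Contig, CoverageProfile,
                   Parameters)
from .io import ReadPair, classify_pair

K = 15
MAPQ_CAP = 60
MIN_CLIP = 3  # clipped tails shorter than this are alignment jitter


class ReadStore:
    """All read pairs of a run, encoded once for repeated realignment.

    Mates are stored in sequencing orientation; slot ``2*i`` is mate 1 of
    pair ``i`` and slot ``2*i + 1`` is mate 2.
    """

    def __init__(self, pairs: Iterable[ReadPair]):
        self.ids: List[str] = []
        self.seqs: List[str] = []
        for p in pairs:
            self.ids.append(p.read_id)
            self.seqs.append(p.seq1)
            self.seqs.append(p.seq2)
        if not self.ids:
            raise ValueError("no read pairs supplied")
        n = len(self.seqs)
        lens = np.fromiter((len(s) for s in self.seqs), dtype=np.int64, count=n)
        self.offsets = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(lens, out=self.offsets[1:])
        total = int(self.offsets[-1])
        self.mask_f = np.empty(total, dtype=np.uint8)
        self.mask_r = np.empty(total, dtype=np.uint8)
        self.code_f = np.empty(total, dtype=np.uint8)
        self.code_r = np.empty(total, dtype=np.uint8)
        for i, s in enumerate(self.seqs):
            a, b = self.offsets[i], self.offsets[i + 1]
            self.mask_f[a:b] = encode_mask4(s)
            self.code_f[a:b] = encode_code2(s)
            rc = revcomp(s)
            self.mask_r[a:b] = encode_mask4(rc)
            self.code_r[a:b] = encode_code2(rc)
        self.read_length = int(round(float(np.mean(lens))))

    @property
    def n_pairs(self) -> int:
        return len(self.ids)

    @property
    def n_reads(self) -> int:
        return len(self.seqs)

    def seq_of(self, slot: int, strand: str) -> str:
        s = self.seqs[slot]
        return s if strand == "+" else revcomp(s)


class ReferenceIndex:
    """Concatenated, separator-delimited encoding of an assembly plus a
    sorted exact k-mer index for seeding."""

    def __init__(self, assembly: Assembly, k: int = K):
        self.k = k
        self.contig_ids = assembly.ids
        seqs = [assembly[cid].sequence for cid in self.contig_ids]
        starts = []
        parts = []
        pos = 0
        for s in seqs:
            starts.append(pos)
            parts.append(s)
            pos += len(s) + 1  # +1 for an N separator
            parts.append("N")
        cat = "".join(parts)
        self.ref_mask = encode_mask4(cat)
        code = encode_code2(cat)
        self.contig_starts = np.asarray(starts, dtype=np.int64)
        self.contig_ends = self.contig_starts + np.asarray(
            [len(s) for s in seqs], dtype=np.int64)
        n = len(code) - k + 1
        if n <= 0:
            self.sorted_hash = np.empty(0, dtype=np.uint64)
            self.sorted_pos = np.empty(0, dtype=np.int64)
            return
        h = np.zeros(n, dtype=np.uint64)
        valid = np.ones(n, dtype=bool)
        for i in range(k):
            c = code[i:i + n]
            h = h * np.uint64(4) + c
            valid &= c < 4
        positions = np.nonzero(valid)[0].astype(np.int64)
        hashes = h[valid]
        order = np.argsort(hashes, kind="stable")
        self.sorted_hash = hashes[order]
        self.sorted_pos = positions[order]


class Aligner:
    """Seed-and-extend gapless aligner of a ReadStore against an assembly."""

    def __init__(self, assembly: Assembly, params: Optional[Parameters] = None):
        self.assembly = assembly
        self.params = params or Parameters()
        self.index = ReferenceIndex(assembly)

    def align(self, store: ReadStore,
              pair_subset: Optional[Sequence[int]] = None) -> List[AlignmentRecord]:
        """Align the given pairs (all by default); returns one record per
        mapped mate with mate linkage and orientation classes filled in."""
        if pair_subset is None:
            pairs = np.arange(store.n_pairs, dtype=np.int64)
        else:
            pairs = np.asarray(pair_subset, dtype=np.int64)
        which = np.empty(2 * len(pairs), dtype=np.int64)
        which[0::2] = 2 * pairs
        which[1::2] = 2 * pairs + 1
        idx = self.index
        out = _kernels.align_batch(
            which, store.mask_f, store.mask_r, store.code_f, store.code_r,
            store.offsets, idx.ref_mask, idx.contig_starts, idx.contig_ends,
            idx.sorted_hash, idx.sorted_pos, K)
        mapped, gstart, seg_s, seg_e, strand, contig, score, second = out

        records: List[AlignmentRecord] = []
        for j in range(0, len(which), 2):
            pi = which[j] // 2
            recs = [None, None]
            for m in (0, 1):
                t = j + m
                if not mapped[t]:
                    continue
                slot = which[t]
                L = int(store.offsets[slot + 1] - store.offsets[slot])
                ci = int(contig[t])
                cid = idx.contig_ids[ci]
                cstart = int(idx.contig_starts[ci])
                cend = int(idx.contig_ends[ci])
                s0, e0 = int(seg_s[t]), int(seg_e[t])
                g0 = int(gstart[t]) - s0  # global position of read base 0
                # absorb jitter clips (< MIN_CLIP) when the contig has room
                if 0 < s0 < MIN_CLIP and g0 >= cstart:
                    s0 = 0
                if 0 < L - e0 < MIN_CLIP and g0 + L <= cend:
                    e0 = L
                cigar = []
                if s0:
                    cigar.append(("S", s0))
                cigar.append(("M", e0 - s0))
                if L - e0:
                    cigar.append(("S", L - e0))
                st = "+" if strand[t] == 0 else "-"
                mapq = MAPQ_CAP
                if score[t] > 0 and second[t] > 0:
                    mapq = min(MAPQ_CAP,
                               int(40.0 * (1.0 - second[t] / score[t])))
                    mapq = max(mapq, 0)
                rec = AlignmentRecord(
                    read_id=store.ids[pi],
                    mate_index=m + 1,
                    contig_id=cid,
                    start=(g0 + s0) - cstart,
                    cigar=cigar,
                    strand=st,
                    mapq=mapq,
                    seq=store.seq_of(slot, st),
                    read_index=int(pi),
                )
                recs[m] = rec
            classify_pair(recs[0], recs[1])
            records.extend(r for r in recs if r is not None)
        return records


def align_read_pairs(pairs, assembly: Assembly,
                     params: Optional[Parameters] = None) -> List[AlignmentRecord]:
    """Align an iterable of ReadPair against the assembly (convenience
    wrapper building a one-shot ReadStore)."""
    store = pairs if isinstance(pairs, ReadStore) else ReadStore(pairs)
    return Aligner(assembly, params).align(store)


# ---------------------------------------------------------------------------
# filtering

_BAD_ORIENTATIONS = frozenset(("F1F2", "R1R2", "RF"))


def filter_alignments(records: List[AlignmentRecord],
                      params: Optional[Parameters] = None) -> List[AlignmentRecord]:
    """Drop low-mapq records and both mates of improperly oriented pairs.

    Proper FR pairs, pairs split across contigs and reads with unmapped
    mates are kept — the latter two are error signatures, not noise.
    Idempotent: a filtered set passes through unchanged.
    """
    params = params or Parameters()
    return [r for r in records
            if r.mapq >= params.min_mapq
            and r.orientation not in _BAD_ORIENTATIONS]


# ---------------------------------------------------------------------------
# coverage and junctions


def compute_coverage(records: Iterable[AlignmentRecord],
                     contig: Contig) -> CoverageProfile:
    """Per-base depth of M ops; S and I contribute nothing, D and N span."""
    L = len(contig)
    delta = np.zeros(L + 1, dtype=np.int64)
    for rec in records:
        if rec.contig_id != contig.id:
            continue
        for a, b in rec.m_spans():
            delta[max(a, 0)] += 1
            delta[min(b, L)] -= 1
    return CoverageProfile(contig.id, np.cumsum(delta[:L]))


def detect_junctions(records: Iterable[AlignmentRecord]) -> dict:
    """Splice-junction boundary positions per contig, from N ops in spliced
    alignments. The built-in aligner emits no N ops (supertranscripts carry
    no introns), so this is only populated from ingested SAM."""
    junctions: dict = {}
    for rec in records:
        pos = rec.start
        for op, n in rec.cigar:
            if op == "N":
                s = junctions.setdefault(rec.contig_id, set())
                s.add(pos)
                s.add(pos + n)
            if op in ("M", "D", "N"):
                pos += n
    return junctions


def select_edge_reads(records: Iterable[AlignmentRecord], contig: Contig,
                      params: Optional[Parameters] = None) -> List[AlignmentRecord]:
    """Records whose alignment starts or ends within the edge window
    (default 2 x read length) of either contig boundary."""
    params = params or Parameters()
    out = []
    L = len(contig)
    for rec in records:
        if rec.contig_id != contig.id:
            continue
        w = params.edge_window(rec.read_length)
        if rec.start < w or rec.end > L - w:
            out.append(rec)
    return out
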