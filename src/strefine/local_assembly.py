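"""Sequence-building primitives: consensus from clipped fragments, greedy
overlap assembly of orphan mates, seed-and-extend overlap search across the
assembly, and overlap-based contig merging.

These stand in for the external consensus/search tools a correction
pipeline would traditionally shell out to, so the whole corrector is a
single in-process library.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from ._seq import (MASK_IUPAC, encode_mask4, iupac_from_bases, revcomp)
from .core import Assembly, Contig, OverlapHit, Parameters

WORD_SIZE = 11          # exact-word seed for the overlap search
_BASE_ORDER = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASE_ORDER)}


# ---------------------------------------------------------------------------
# consensus from anchored clip stacks


def consensus_from_clips(fragments: Sequence[Tuple[int, str]],
                         params: Optional[Parameters] = None,
                         min_depth: int = 1) -> str:
    """Column-majority consensus over clip fragments anchored at a shared
    clip point (offset 0).

    Fragments all start at known offsets relative to the clip point, so
    their layout is already determined; the consensus is the per-column
    base of highest frequency, with the covering IUPAC code at tied
    columns. Columns with fewer than ``min_depth`` covering fragments
    terminate the consensus (walking outward from the clip point).
    """
    if not fragments:
        raise ValueError("no clip fragments supplied")
    lo = min(off for off, _ in fragments)
    hi = max(off + len(seq) for off, seq in fragments)
    width = hi - lo
    counts = np.zeros((width, 4), dtype=np.int32)
    other = np.zeros(width, dtype=np.int32)  # N / IUPAC in input fragments
    for off, seq in fragments:
        for j, b in enumerate(seq):
            i = off - lo + j
            bi = _BASE_IDX.get(b)
            if bi is None:
                other[i] += 1
            else:
                counts[i, bi] += 1
    depth = counts.sum(axis=1) + other

    def call(i: int) -> str:
        row = counts[i]
        m = row.max()
        if m == 0:
            return "N"
        tied = [b for b, c in zip(_BASE_ORDER, row) if c == m]
        return tied[0] if len(tied) == 1 else iupac_from_bases(tied)

    anchor = -lo  # column index of offset 0
    out_right = []
    for i in range(anchor, width):
        if depth[i] < min_depth:
            break
        out_right.append(call(i))
    out_left = []
    for i in range(anchor - 1, -1, -1):
        if depth[i] < min_depth:
            break
        out_left.append(call(i))
    return "".join(reversed(out_left)) + "".join(out_right)


# ---------------------------------------------------------------------------
# greedy overlap assembly (orphan-mate re-assembly)


# IUPAC character for each 4-bit base set (A=1, C=2, G=4, T=8); index 0
# means no information -> N
_MASKV_CHARS = np.frombuffer(
    b"N" + "".join(MASK_IUPAC[m] for m in range(1, 16)).encode(),
    dtype=np.uint8)


class _Layout:
    """A growing consensus layout: per-column base counts."""

    __slots__ = ("counts", "order")

    def __init__(self, seq: str, order: int):
        from ._seq import encode_code2
        codes = encode_code2(seq)
        counts = np.zeros((len(seq), 4), dtype=np.int32)
        ok = codes < 4
        counts[np.nonzero(ok)[0], codes[ok]] = 1
        self.counts = counts
        self.order = order

    def __len__(self) -> int:
        return len(self.counts)

    def consensus(self) -> str:
        counts = self.counts
        m = counts.max(axis=1)
        is_max = (counts == m[:, None]) & (m[:, None] > 0)
        maskv = (is_max * np.array([1, 2, 4, 8], dtype=np.int32)).sum(axis=1)
        return _MASKV_CHARS[maskv].tobytes().decode("ascii")

    def mask(self) -> np.ndarray:
        return encode_mask4(self.consensus())

    def rc(self) -> "_Layout":
        new = _Layout.__new__(_Layout)
        new.counts = self.counts[::-1, ::-1].copy()
        new.order = self.order
        return new

    def merge(self, other: "_Layout", shift: int) -> "_Layout":
        """Place ``other`` at column offset ``shift`` (>=0) and add counts."""
        width = max(len(self), shift + len(other))
        counts = np.zeros((width, 4), dtype=np.int32)
        counts[:len(self)] += self.counts
        counts[shift:shift + len(other)] += other.counts
        new = _Layout.__new__(_Layout)
        new.counts = counts
        new.order = min(self.order, other.order)
        return new


def _overlap_candidates(ma: np.ndarray, mb: np.ndarray,
                        word: int = WORD_SIZE) -> List[int]:
    """Candidate shifts of b relative to a from shared exact words of the
    two consensus masks (ambiguity-free words only)."""
    def words(m):
        d: Dict[bytes, List[int]] = {}
        b = m.tobytes()
        for i in range(len(m) - word + 1):
            w = b[i:i + word]
            d.setdefault(w, []).append(i)
        return d

    wa = words(ma)
    shifts = set()
    b = mb.tobytes()
    for i in range(len(mb) - word + 1):
        w = b[i:i + word]
        for pa in wa.get(w, ()):
            shifts.add(pa - i)
    return sorted(shifts)


def _score_shift(ma: np.ndarray, mb: np.ndarray, shift: int) -> Tuple[int, float]:
    """(overlap length, identity %) of placing b at ``shift`` in a coords."""
    a0, a1 = max(0, shift), min(len(ma), shift + len(mb))
    if a1 <= a0:
        return 0, 0.0
    seg_a = ma[a0:a1]
    seg_b = mb[a0 - shift:a1 - shift]
    matches = int(np.count_nonzero(seg_a & seg_b))
    length = a1 - a0
    return length, 100.0 * matches / length


def greedy_assemble(seqs: Sequence[str], min_overlap: int = 16,
                    min_identity_pct: float = 95.0) -> List[str]:
    """Greedy overlap-layout-consensus assembly of short sequences.

    Repeatedly merges the pair with the longest qualifying suffix-prefix
    overlap (>= ``min_overlap`` bases at >= ``min_identity_pct`` identity,
    either strand), accumulating per-column base counts so the merged
    consensus is a majority vote rather than first-sequence-wins. Returns
    the remaining consensus sequences longest-first.
    """
    if not seqs:
        raise ValueError("no sequences supplied")
    items: List[_Layout] = [_Layout(s.upper(), i) for i, s in enumerate(seqs)]
    while len(items) > 1:
        masks = [it.mask() for it in items]
        best = None  # (ovlen, identity, i, j, strand, shift)
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                for strand in ("+", "-"):
                    mb = masks[j] if strand == "+" else \
                        encode_mask4(revcomp(items[j].consensus()))
                    for shift in _overlap_candidates(masks[i], mb):
                        ov, ident = _score_shift(masks[i], mb, shift)
                        if ov < min_overlap or ident < min_identity_pct:
                            continue
                        key = (ov, ident, -i, -j, strand == "+")
                        if best is None or key > best[0]:
                            best = (key, i, j, strand, shift)
        if best is None:
            break
        _, i, j, strand, shift = best
        other = items[j] if strand == "+" else items[j].rc()
        if shift >= 0:
            merged = items[i].merge(other, shift)
        else:
            merged = other.merge(items[i], -shift)
        items = [it for k, it in enumerate(items) if k not in (i, j)]
        items.append(merged)
    items.sort(key=lambda it: (-len(it), it.order))
    return [it.consensus() for it in items]


# ---------------------------------------------------------------------------
# overlap search (the within-assembly homology search)


class OverlapSearcher:
    """Exact-word seeded, gapless local search of queries against a target
    assembly (word size 11, both strands).

    Hits are maximum-scoring gapless segments (match +1 / mismatch -2) on
    a candidate diagonal; with the default of zero allowed gaps this is
    the full search model, so no gapped extension is attempted.
    """

    def __init__(self, targets: Union[Assembly, Contig], word: int = WORD_SIZE):
        if isinstance(targets, Contig):
            targets = Assembly([Contig(targets.id, targets.sequence)],
                               read_length=100)
        self.assembly = targets
        self.word = word
        self.contig_ids = targets.ids
        parts = []
        starts = []
        pos = 0
        for cid in self.contig_ids:
            s = targets[cid].sequence
            starts.append(pos)
            parts.append(s)
            parts.append("\0")
            pos += len(s) + 1
        self.cat = "".join(parts)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = self.starts + np.asarray(
            [len(targets[cid]) for cid in self.contig_ids], dtype=np.int64)
        self.mask = encode_mask4(self.cat)
        self._index: Dict[str, List[int]] = {}
        for i in range(len(self.cat) - word + 1):
            w = self.cat[i:i + word]
            if "\0" in w:
                continue
            self._index.setdefault(w, []).append(i)

    def _contig_of(self, gpos: int) -> int:
        return int(np.searchsorted(self.starts, gpos, side="right")) - 1

    def search(self, query: str, min_identity_pct: float = 0.0,
               min_len: Optional[int] = None) -> List[OverlapHit]:
        """All qualifying hits, best score first (ties: leftmost subject)."""
        query = query.upper()
        if len(query) < self.word:
            raise ValueError("query shorter than the seed word size")
        min_len = min_len if min_len is not None else self.word
        hits: List[OverlapHit] = []
        for strand in ("+", "-"):
            q = query if strand == "+" else revcomp(query)
            qmask = encode_mask4(q)
            diags = set()
            for i in range(len(q) - self.word + 1):
                for p in self._index.get(q[i:i + self.word], ()):
                    diags.add(p - i)
            for d in sorted(diags):
                ci = self._contig_of(d + len(q) // 2)
                if ci < 0:
                    ci = 0
                for cj in (ci, ci + 1):
                    if cj >= len(self.starts):
                        continue
                    hit = self._eval_diag(q, qmask, d, cj, strand,
                                          len(query), min_identity_pct,
                                          min_len)
                    if hit is not None:
                        hits.append(hit)
        # dedupe identical intervals found from adjacent contig probes
        seen = set()
        uniq = []
        for h in hits:
            key = (h.subject_contig_id, h.subject_range, h.strand, h.query_range)
            if key not in seen:
                seen.add(key)
                uniq.append(h)

        def raw(h):
            cols = h.query_range[1] - h.query_range[0]
            matches = h.identity_pct / 100.0 * cols
            return matches - 2.0 * (cols - matches)

        # primary order: raw segment score (a long, near-perfect hit beats
        # a short chance-perfect word); composite score breaks ties
        uniq.sort(key=lambda h: (-raw(h), -h.score, h.subject_contig_id,
                                 h.subject_range[0], h.strand))
        return uniq

    def _eval_diag(self, q, qmask, d, cj, strand, qlen_orig,
                   min_identity_pct, min_len):
        cstart, cend = int(self.starts[cj]), int(self.ends[cj])
        lo = max(0, cstart - d)
        hi = min(len(q), cend - d)
        if hi - lo < min_len:
            return None
        best, run, rs = -1, 0, lo
        bs = be = lo
        for i in range(lo, hi):
            sc = 1 if (self.mask[d + i] & qmask[i]) else -2
            if run <= 0:
                run, rs = sc, i
            else:
                run += sc
            if run > best:
                best, bs, be = run, rs, i + 1
        if best <= 0 or be - bs < min_len:
            return None
        seg_a = self.mask[d + bs:d + be]
        seg_q = qmask[bs:be]
        matches = int(np.count_nonzero(seg_a & seg_q))
        identity = 100.0 * matches / (be - bs)
        if identity < min_identity_pct:
            return None
        # map reverse-strand query coords back to the original query
        if strand == "+":
            qrange = (bs, be)
        else:
            qrange = (len(q) - be, len(q) - bs)
        return OverlapHit(
            query_range=qrange,
            subject_contig_id=self.contig_ids[cj],
            subject_range=(d + bs - cstart, d + be - cstart),
            strand=strand,
            identity_pct=identity,
            n_gaps=0,
            score=identity / qlen_orig * 100.0,
        )


def find_local_overlap(query: str, targets: Union[Assembly, Contig],
                       params: Optional[Parameters] = None,
                       min_identity_pct: float = 0.0) -> List[OverlapHit]:
    """Search ``query`` against the target assembly or contig; hits with
    more than ``params.max_gaps`` gaps are dropped (the default of zero
    makes the search gapless outright)."""
    searcher = targets if isinstance(targets, OverlapSearcher) \
        else OverlapSearcher(targets)
    params = params or Parameters()
    hits = searcher.search(query, min_identity_pct=min_identity_pct)
    return [h for h in hits if h.n_gaps <= params.max_gaps]


# ---------------------------------------------------------------------------
# overlap extension and merging


def extend_overlap(a: Contig, b: Contig, seed: OverlapHit,
                   params: Optional[Parameters] = None
                   ) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Grow a seed overlap between contig ``a`` (query side) and contig
    ``b`` (subject side) base-by-base toward the contig ends while the
    cumulative identity of the overlap stays at or above
    ``extend_identity_pct``. Returns the maximal ((a_start, a_end),
    (b_start, b_end)) interval pair. Forward-strand seeds only."""
    if seed.strand != "+":
        raise ValueError("extend_overlap requires a forward-strand seed")
    params = params or Parameters()
    thr = params.extend_identity_pct / 100.0
    ma = encode_mask4(a.sequence)
    mb = encode_mask4(b.sequence)
    qa, qe = seed.query_range
    sa, se = seed.subject_range
    matches = int(np.count_nonzero(ma[qa:qe] & mb[sa:se]))
    total = qe - qa

    # rightward: furthest extension keeping cumulative identity >= thr
    n_right = min(len(a.sequence) - qe, len(b.sequence) - se)
    best_right, m, t = 0, matches, total
    for i in range(n_right):
        t += 1
        if ma[qe + i] & mb[se + i]:
            m += 1
        if m / t >= thr:
            best_right = i + 1
    m_r = int(np.count_nonzero(ma[qe:qe + best_right] & mb[se:se + best_right]))
    matches += m_r
    total += best_right
    qe += best_right
    se += best_right

    n_left = min(qa, sa)
    best_left, m, t = 0, matches, total
    for i in range(1, n_left + 1):
        t += 1
        if ma[qa - i] & mb[sa - i]:
            m += 1
        if m / t >= thr:
            best_left = i
    qa -= best_left
    sa -= best_left
    return (qa, qe), (sa, se)


def _resolve_base(ba: str, bb: str) -> str:
    """Overlap-column resolution: prefer the more specific base; on a
    disagreement or tie keep the subject (pre-existing) base."""
    if ba == bb:
        return ba
    from ._seq import IUPAC_MASK
    ma, mb = IUPAC_MASK.get(ba, 0), IUPAC_MASK.get(bb, 0)
    if ma & mb:
        return ba if bin(ma).count("1") < bin(mb).count("1") else bb
    return bb


def merge_by_overlap(a: Contig, b: Contig,
                     overlap: Tuple[Tuple[int, int], Tuple[int, int]]) -> Contig:
    """Merge two contigs across a terminal overlap: ``a``'s overlap region
    must run to its right end and ``b``'s must start at its left end.
    Overlap columns disagreeing between the two contigs resolve toward the
    more specific base, keeping ``b``'s on ties. The merged contig keeps
    ``a``'s id; length = |a| + |b| - overlap."""
    (qa, qe), (sa, se) = overlap
    ov = qe - qa
    if ov <= 0:
        raise ValueError("zero-length overlap")
    if qe - qa != se - sa:
        raise ValueError("overlap interval lengths differ")
    if qe != len(a.sequence) or sa != 0:
        raise ValueError("overlap is not terminal on the joining ends")
    mid = "".join(_resolve_base(a.sequence[qa + i], b.sequence[sa + i])
                  for i in range(ov))
    seq = a.sequence[:qa] + mid + b.sequence[se:]
    assert len(seq) == len(a.sequence) + len(b.sequence) - ov
    return Contig(a.id, seq, tags=a.tags | b.tags)
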