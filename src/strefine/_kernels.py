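"""Numba kernels for the built-in read aligner.

The aligner is seed-anchored and gapless: exact 15-mer seeds nominate
candidate diagonals, and each diagonal is scored with a maximum-scoring
segment scan (match +1, mismatch -2), which is Smith-Waterman restricted
to a single diagonal. Unextendable read ends fall out of the maximal
segment and become soft-clips. Substitutions dominate Illumina error, so
a gapless placement is the correct model for read-to-contig alignment
here; gap handling lives in the contig-vs-contig overlap search instead.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -2
MIN_SEG_SCORE = 20       # below this the mate is reported unmapped
MAX_HITS_PER_SEED = 32   # seeds hitting more positions are repetitive
MAX_CANDIDATES = 64


@njit(cache=True)
def _bisect_right(a, x):
    lo, hi = 0, len(a)
    while lo < hi:
        mid = (lo + hi) // 2
        if x < a[mid]:
            hi = mid
        else:
            lo = mid + 1
    return lo


@njit(cache=True)
def _kadane_diag(ref_mask, read_mask, roff, L, d, cstart, cend):
    """Best-scoring segment of read [0,L) placed at global diagonal d
    (read base i sits on reference position d+i), clamped to one contig.

    Returns (score, seg_start, seg_end) in read coordinates.
    """
    lo = 0
    if cstart - d > 0:
        lo = cstart - d
    hi = L
    if cend - d < L:
        hi = cend - d
    best = -1
    bs = 0
    be = 0
    run = 0
    rs = lo
    for i in range(lo, hi):
        if ref_mask[d + i] & read_mask[roff + i]:
            sc = MATCH
        else:
            sc = MISMATCH
        if run <= 0:
            run = sc
            rs = i
        else:
            run += sc
        if run > best:
            best = run
            bs = rs
            be = i + 1
    return best, bs, be


@njit(cache=True)
def align_batch(which,
                reads_mask_f, reads_mask_r, reads_code_f, reads_code_r,
                read_offsets,
                ref_mask, contig_starts, contig_ends,
                sorted_hash, sorted_pos, k):
    """Align the reads indexed by ``which``.

    Output arrays (one slot per entry of ``which``): mapped flag, global
    reference start of the aligned segment, read-segment bounds, strand
    (0 forward / 1 reverse, in read coordinates of the *aligned
    orientation*), contig index, segment score and runner-up score for
    the mapq uniqueness estimate.
    """
    n = len(which)
    mapped = np.zeros(n, np.uint8)
    gstart = np.zeros(n, np.int64)
    seg_s = np.zeros(n, np.int32)
    seg_e = np.zeros(n, np.int32)
    strand = np.zeros(n, np.int8)
    contig = np.full(n, -1, np.int64)
    score = np.zeros(n, np.int32)
    second = np.zeros(n, np.int32)

    cand_diag = np.zeros(MAX_CANDIDATES, np.int64)
    cand_str = np.zeros(MAX_CANDIDATES, np.int8)

    for t in range(n):
        r = which[t]
        roff = read_offsets[r]
        L = read_offsets[r + 1] - roff
        if L < k:
            continue
        ncand = 0
        # ---- seeding on both strands
        step = (L - k) // 5
        if step < 1:
            step = 1
        for st in range(2):
            codes = reads_code_f if st == 0 else reads_code_r
            s = 0
            while s <= L - k:
                h = np.uint64(0)
                ok = True
                for j in range(k):
                    c = codes[roff + s + j]
                    if c > 3:
                        ok = False
                        break
                    h = h * np.uint64(4) + np.uint64(c)
                if ok:
                    lo = np.searchsorted(sorted_hash, h, side='left')
                    hi = np.searchsorted(sorted_hash, h, side='right')
                    if hi - lo <= MAX_HITS_PER_SEED:
                        for j in range(lo, hi):
                            d = sorted_pos[j] - s
                            dup = False
                            for q in range(ncand):
                                if cand_diag[q] == d and cand_str[q] == st:
                                    dup = True
                                    break
                            if not dup and ncand < MAX_CANDIDATES:
                                cand_diag[ncand] = d
                                cand_str[ncand] = st
                                ncand += 1
                if s == L - k:
                    break
                s += step
                if s > L - k:
                    s = L - k
        if ncand == 0:
            continue
        # ---- deterministic candidate order: by (strand, diagonal)
        for a in range(1, ncand):
            db = cand_diag[a]
            sb = cand_str[a]
            b = a - 1
            while b >= 0 and (cand_str[b] > sb or
                             (cand_str[b] == sb and cand_diag[b] > db)):
                cand_diag[b + 1] = cand_diag[b]
                cand_str[b + 1] = cand_str[b]
                b -= 1
            cand_diag[b + 1] = db
            cand_str[b + 1] = sb
        # ---- evaluate candidates
        best_sc = -1
        best_bs = 0
        best_be = 0
        best_d = 0
        best_st = np.int8(0)
        best_c = -1
        sec_sc = 0
        for q in range(ncand):
            d = cand_diag[q]
            st = cand_str[q]
            rm = reads_mask_f if st == 0 else reads_mask_r
            # the contig owning the seed region of this diagonal
            ci = _bisect_right(contig_starts, d + (L // 2))
            if ci > 0:
                ci -= 1
            # the diagonal may fall before this contig; probe neighbours
            sc = -1
            bs = 0
            be = 0
            cbest = ci
            for cj in range(ci, min(ci + 2, len(contig_starts))):
                s2, b2, e2 = _kadane_diag(ref_mask, rm, roff, L, d,
                                          contig_starts[cj], contig_ends[cj])
                if s2 > sc:
                    sc = s2
                    bs = b2
                    be = e2
                    cbest = cj
            if sc <= 0:
                continue
            if sc > best_sc:
                # previous best becomes runner-up if placements compete
                if best_sc > 0 and _segments_compete(best_bs, best_be, bs, be):
                    if best_sc > sec_sc:
                        sec_sc = best_sc
                best_sc = sc
                best_bs = bs
                best_be = be
                best_d = d
                best_st = st
                best_c = cbest
            else:
                if _segments_compete(best_bs, best_be, bs, be) and sc > sec_sc:
                    sec_sc = sc
        if best_sc < MIN_SEG_SCORE:
            continue
        mapped[t] = 1
        gstart[t] = best_d + best_bs
        seg_s[t] = best_bs
        seg_e[t] = best_be
        strand[t] = best_st
        contig[t] = best_c
        score[t] = best_sc
        second[t] = sec_sc
    return mapped, gstart, seg_s, seg_e, strand, contig, score, second


@njit(cache=True)
def _segments_compete(s1, e1, s2, e2):
    """Two placements compete for the same read bases when their read
    segments overlap by at least half of the shorter segment; split
    placements over disjoint read halves do not lower mapq."""
    ov = min(e1, e2) - max(s1, s2)
    if ov <= 0:
        return False
    short = min(e1 - s1, e2 - s2)
    return ov * 2 >= short


@njit(cache=True)
def identity_on_diagonal(a_mask, b_mask, a_start, b_start, length):
    """Matches (IUPAC-compatible) over a gapless pairing of two sequences."""
    m = 0
    for i in range(length):
        if a_mask[a_start + i] & b_mask[b_start + i]:
            m += 1
    return m
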