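"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import re

import numpy as np
import pytest

from strefine.core import AlignmentRecord, Assembly, Contig

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, n))


def parse_mini_cigar(cigar: str):
    return [(op, int(n)) for n, op in re.findall(r"(\d+)([MSIDN])", cigar)]


def make_record(contig_id: str, start: int, cigar: str, strand: str = "+",
                mapq: int = 60, seq: str = "", read_id: str = "r",
                mate_index: int = 1, orientation: str = "FR",
                mate_contig_id=None, mate_start=None,
                read_index: int = -1) -> AlignmentRecord:
    ops = parse_mini_cigar(cigar)
    if not seq:
        seq = "A" * sum(n for op, n in ops if op in "MSI")
    return AlignmentRecord(
        read_id=read_id, mate_index=mate_index, contig_id=contig_id,
        start=start, cigar=ops, strand=strand, mapq=mapq,
        mate_mapped=mate_contig_id is not None,
        mate_contig_id=mate_contig_id, mate_start=mate_start,
        orientation=orientation, seq=seq, read_index=read_index)


# ---------------------------------------------------------------------------
# independent alignment oracle (full Smith-Waterman, affine-free)


def smith_waterman(query: str, subject: str, match: int = 1,
                   mismatch: int = -2, gap: int = -3):
    """Exhaustive local alignment; returns (score, (q0, q1), (s0, s1)) of
    the best-scoring local alignment (first encountered on ties, scanning
    row-major). Independent of the package's aligner."""
    n, m = len(query), len(subject)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    best = (0, 0, 0)
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            sc = match if qi == subject[j - 1] else mismatch
            h = max(0, H[i - 1, j - 1] + sc, H[i - 1, j] + gap,
                    H[i, j - 1] + gap)
            H[i, j] = h
            if h > best[0]:
                best = (h, i, j)
    score, ei, ej = best
    if score == 0:
        return 0, (0, 0), (0, 0)
    # traceback for segment bounds
    i, j = ei, ej
    while H[i, j] > 0:
        sc = match if query[i - 1] == subject[j - 1] else mismatch
        if H[i, j] == H[i - 1, j - 1] + sc:
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    return int(score), (i, ei), (j, ej)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def small_assembly(rng):
    return Assembly([Contig("c1", random_seq(rng, 2000)),
                     Contig("c2", random_seq(rng, 1500))])
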