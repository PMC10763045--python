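"""Benchmark harness: synthetic supertranscriptome generation, injection
of the seven assembly-error types, paired-end read simulation, and the
per-type recovery scorer.

The generator emulates the study conditions a corrector faces on real
data: contigs of 1-3 kb (always > 500 bp, mutually dissimilar), 100 bp
FR read pairs with fragment sizes 250-500 and a small substitution rate,
and one injected error per contig with the canonical size ranges —
terminal truncations of 10-30 % per side, fragmentation cuts at 40-60 %
of length, chimeric fusions of two contigs, internal deletions/insertions
of 30-70 % of read length, and moved (translocation) or moved-and-
reverse-complemented (inversion) blocks of 20-30 % of contig length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._seq import revcomp, seqs_compatible
from .core import Assembly, Contig, ContigMap
from .io import ReadPair

ERROR_TYPES = ("incomplete", "fragmented", "chimera", "missing_seq",
               "unsupported_insertion", "translocation", "inversion")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# reference generation


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return _BASES[codes].tobytes().decode("ascii")


def _sketch(seq: str, k: int = 15) -> set:
    return {seq[i:i + k] for i in range(0, len(seq) - k + 1, 4)}


def generate_supertranscriptome(n_contigs: int,
                                length_range: Tuple[int, int] = (1000, 3000),
                                gc: float = 0.5,
                                seed: int = 0) -> Assembly:
    """I.i.d. random contigs at the given GC, lengths uniform over
    ``length_range``, mutually dissimilar (pairwise identity < 95 %,
    enforced by rejection against a shared-k-mer sketch). Deterministic
    per seed."""
    lo, hi = length_range
    if lo <= 500:
        raise ValueError("contig lengths must exceed 500 bp")
    if not (0.0 < gc < 1.0):
        raise ValueError("GC fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    contigs = []
    sketches: List[set] = []
    attempts = 0
    while len(contigs) < n_contigs:
        attempts += 1
        if attempts > 20 * n_contigs:
            raise ValueError("cannot generate enough dissimilar contigs")
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length, gc)
        sk = _sketch(seq)
        if any(len(sk & other) > 0.5 * min(len(sk), len(other))
               for other in sketches):
            continue
        sketches.append(sk)
        contigs.append(Contig(f"st{len(contigs) + 1:04d}", seq))
    return Assembly(contigs)


# ---------------------------------------------------------------------------
# error injection


@dataclass
class ErrorTruth:
    """Ground truth for one injected error, consumed by the scorer."""

    error_type: str
    err_ids: Tuple[str, ...]            # ids in the erroneous assembly
    ref_ids: Tuple[str, ...]            # ids of the original contigs
    original_seqs: Tuple[str, ...]
    coords: Tuple[Tuple[int, int], ...] = ()
    removed_seqs: Tuple[str, ...] = ()
    added_seq: str = ""

    def __post_init__(self):
        if self.error_type not in ERROR_TYPES:
            raise ValueError(f"unknown error type {self.error_type!r}")


def inject_errors(assembly: Assembly,
                  counts: Optional[Dict[str, int]] = None,
                  seed: int = 0,
                  read_length: int = 100
                  ) -> Tuple[Assembly, List[ErrorTruth]]:
    """Inject the requested number of errors of each type, one error per
    contig (a chimera consumes two). Returns the erroneous assembly and
    the ground-truth list."""
    counts = dict(counts or {t: 1 for t in ERROR_TYPES})
    for t in counts:
        if t not in ERROR_TYPES:
            raise ValueError(f"unknown error type {t!r}")
    need = sum(counts.values()) + counts.get("chimera", 0)
    ids = assembly.ids
    if need > len(ids):
        raise ValueError(
            f"{need} contigs needed for requested errors, have {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    cursor = 0

    def take(n: int) -> List[str]:
        nonlocal cursor
        out = order[cursor:cursor + n]
        cursor += n
        return out

    truths: List[ErrorTruth] = []
    out = Assembly(read_length=assembly.read_length)
    edited: Dict[str, List[Contig]] = {}

    def put(cid: str, contigs: List[Contig]):
        edited[cid] = contigs

    for cid in take(counts.get("incomplete", 0)):
        seq = assembly[cid].sequence
        L = len(seq)
        side = ("left", "right", "both")[int(rng.integers(3))]
        cut_l = int(rng.uniform(0.10, 0.30) * L) if side in ("left", "both") else 0
        cut_r = int(rng.uniform(0.10, 0.30) * L) if side in ("right", "both") else 0
        removed = tuple(s for s in (seq[:cut_l], seq[L - cut_r:] if cut_r else "")
                        if s)
        put(cid, [Contig(cid, seq[cut_l:L - cut_r or L])])
        truths.append(ErrorTruth(
            "incomplete", (cid,), (cid,), (seq,),
            coords=((0, cut_l), (L - cut_r, L)), removed_seqs=removed))

    for cid in take(counts.get("fragmented", 0)):
        seq = assembly[cid].sequence
        cut = int(rng.uniform(0.40, 0.60) * len(seq))
        p1, p2 = f"{cid}_p1", f"{cid}_p2"
        put(cid, [Contig(p1, seq[:cut]), Contig(p2, seq[cut:])])
        truths.append(ErrorTruth(
            "fragmented", (p1, p2), (cid,), (seq,), coords=((cut, cut),)))

    chim_ids = take(2 * counts.get("chimera", 0))
    for k in range(counts.get("chimera", 0)):
        c1, c2 = chim_ids[2 * k], chim_ids[2 * k + 1]
        s1, s2 = assembly[c1].sequence, assembly[c2].sequence
        # both constituents are broken: the prefix of one transcript fused
        # to the suffix of another; the truth records the two fused pieces
        cut1 = int(rng.uniform(0.40, 0.60) * len(s1))
        cut2 = int(rng.uniform(0.40, 0.60) * len(s2))
        pa, pb = s1[:cut1], s2[cut2:]
        coords = ((cut1, cut1),)
        cid = f"chim{k + 1:03d}_{c1}_{c2}"
        put(c1, [Contig(cid, pa + pb)])
        put(c2, [])
        truths.append(ErrorTruth(
            "chimera", (cid,), (c1, c2), (pa, pb), coords=coords))

    for cid in take(counts.get("missing_seq", 0)):
        seq = assembly[cid].sequence
        L = len(seq)
        size = int(rng.uniform(0.30, 0.70) * read_length)
        pos = int(rng.integers(2 * read_length, L - 2 * read_length - size))
        put(cid, [Contig(cid, seq[:pos] + seq[pos + size:])])
        truths.append(ErrorTruth(
            "missing_seq", (cid,), (cid,), (seq,),
            coords=((pos, pos + size),),
            removed_seqs=(seq[pos:pos + size],)))

    for cid in take(counts.get("unsupported_insertion", 0)):
        seq = assembly[cid].sequence
        L = len(seq)
        size = int(rng.uniform(0.30, 0.70) * read_length)
        pos = int(rng.integers(2 * read_length, L - 2 * read_length))
        ins = _random_seq(rng, size, 0.5)
        put(cid, [Contig(cid, seq[:pos] + ins + seq[pos:])])
        truths.append(ErrorTruth(
            "unsupported_insertion", (cid,), (cid,), (seq,),
            coords=((pos, pos + size),), added_seq=ins))

    for etype in ("translocation", "inversion"):
        for cid in take(counts.get(etype, 0)):
            seq = assembly[cid].sequence
            L = len(seq)
            size = int(rng.uniform(0.20, 0.30) * L)
            margin = 2 * read_length
            src = int(rng.integers(margin, L - margin - size))
            frag = seq[src:src + size]
            rest = seq[:src] + seq[src + size:]
            # destination far enough from the source junction that the two
            # signatures stay distinct
            while True:
                dst = int(rng.integers(margin, len(rest) - margin))
                if abs(dst - src) >= 2 * read_length:
                    break
            moved = frag if etype == "translocation" else revcomp(frag)
            put(cid, [Contig(cid, rest[:dst] + moved + rest[dst:])])
            truths.append(ErrorTruth(
                etype, (cid,), (cid,), (seq,),
                coords=((src, src + size), (dst, dst)),
                removed_seqs=(frag,)))

    for cid in ids:  # preserve assembly order
        if cid in edited:
            for c in edited[cid]:
                out.add(c)
        else:
            out.add(Contig(cid, assembly[cid].sequence))
    return out, truths


# ---------------------------------------------------------------------------
# read simulation


def simulate_read_pairs(assembly: Assembly, n_pairs: int,
                        read_len: int = 100,
                        frag_range: Tuple[int, int] = (250, 500),
                        subst_rate: float = 0.005,
                        seed: int = 0,
                        abundance: Optional[Dict[str, float]] = None
                        ) -> List[ReadPair]:
    """Uniform-expression FR read pairs: fragments land on contigs with
    probability proportional to length (or to a supplied abundance-times-
    length weight), fragment length uniform over ``frag_range``, mates
    read inward from the fragment ends, substitutions at ``subst_rate``
    per base, constant Q30 qualities. Deterministic per seed."""
    rng = np.random.default_rng(seed)
    contigs = list(assembly)
    lens = np.array([len(c) for c in contigs], dtype=np.float64)
    fmin, fmax = frag_range
    if np.any(lens < fmax):
        raise ValueError("fragment range exceeds a contig length")
    w = lens.copy()
    if abundance is not None:
        w *= np.array([abundance.get(c.id, 1.0) for c in contigs])
    w /= w.sum()
    ci = rng.choice(len(contigs), size=n_pairs, p=w)
    flen = rng.integers(fmin, fmax + 1, size=n_pairs)
    starts = (rng.random(n_pairs) *
              (lens[ci] - flen + 1)).astype(np.int64)
    flip = rng.integers(0, 2, size=n_pairs)  # which mate is read 1
    pairs: List[ReadPair] = []
    qual = "?" * read_len  # constant Q30
    n_subs = rng.binomial(2 * read_len, subst_rate, size=n_pairs)
    for i in range(n_pairs):
        c = contigs[ci[i]]
        s = int(starts[i])
        f = c.sequence[s:s + int(flen[i])]
        fwd = f[:read_len]
        rev = revcomp(f[-read_len:])
        if n_subs[i]:
            both = bytearray((fwd + rev).encode())
            for j in rng.integers(0, 2 * read_len, size=n_subs[i]):
                cur = both[j]
                choices = [b for b in b"ACGT" if b != cur]
                both[j] = choices[int(rng.integers(3))]
            s2 = both.decode()
            fwd, rev = s2[:read_len], s2[read_len:]
        if flip[i]:
            r1, r2 = rev, fwd
        else:
            r1, r2 = fwd, rev
        pairs.append(ReadPair(f"sim{i + 1:07d}", r1, r2, qual, qual))
    return pairs


# ---------------------------------------------------------------------------
# truth serialization (TSV, one row per error)

TRUTH_HEADER = ("error_type", "err_ids", "ref_ids", "coords",
                "removed_seqs", "added_seq", "original_seqs")


def write_truth(truths: Sequence[ErrorTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_HEADER) + "\n")
        for t in truths:
            fh.write("\t".join([
                t.error_type,
                ",".join(t.err_ids),
                ",".join(t.ref_ids),
                ";".join(f"{a}-{b}" for a, b in t.coords),
                ",".join(t.removed_seqs) or ".",
                t.added_seq or ".",
                ",".join(t.original_seqs),
            ]) + "\n")


def read_truth(path) -> List[ErrorTruth]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TRUTH_HEADER:
            raise ValueError(f"{path}: not a truth TSV")
        for line in fh:
            et, err_ids, ref_ids, coords, removed, added, orig = \
                line.rstrip("\n").split("\t")
            out.append(ErrorTruth(
                et, tuple(err_ids.split(",")), tuple(ref_ids.split(",")),
                tuple(orig.split(",")),
                coords=tuple(tuple(map(int, c.split("-")))
                             for c in coords.split(";") if c),
                removed_seqs=tuple(removed.split(",")) if removed != "." else (),
                added_seq=added if added != "." else ""))
    return out


# ---------------------------------------------------------------------------
# recovery scoring


def _aligned_match_positions(original: str, final: str) -> np.ndarray:
    """Boolean vector over ``original`` positions: matched (IUPAC-
    compatible) in the best infix alignment of original within final."""
    import edlib
    extra = [(a, b) for a in "RYSWKMBDHVN" for b in "ACGTRYSWKMBDHVN"]
    res = edlib.align(original, final, mode="HW", task="path",
                      additionalEqualities=extra)
    matched = np.zeros(len(original), dtype=bool)
    if res["editDistance"] < 0 or not res.get("cigar"):
        return matched
    qi = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            matched[qi:qi + n] = True
            qi += n
        elif ch in ("X", "I"):  # edlib: I consumes query in HW mode
            qi += n
        # 'D' consumes target only
    return matched


def _recovered_fraction(truth: ErrorTruth, final_seq: str) -> float:
    """Fraction of the removed bases present, in place, in the final
    contig."""
    removed_total = sum(len(s) for s in truth.removed_seqs)
    if removed_total == 0:
        return 1.0
    matched = _aligned_match_positions(truth.original_seqs[0], final_seq)
    got = 0
    for (a, b) in truth.coords:
        got += int(matched[a:b].sum())
    return got / removed_total


def _exact_present(seq: str, candidates: Sequence[str]) -> bool:
    return any(seqs_compatible(seq, c) for c in candidates)


def _contains(haystack: str, needle: str) -> bool:
    """Substring test, tolerating IUPAC ambiguity codes in the haystack."""
    if needle in haystack:
        return True
    if len(needle) > len(haystack):
        return False
    import edlib
    extra = [(a, b) for a in "RYSWKMBDHVN" for b in "ACGTRYSWKMBDHVN"]
    res = edlib.align(needle, haystack, mode="HW", task="distance", k=0,
                      additionalEqualities=extra)
    return res["editDistance"] == 0


@dataclass
class RecoveryTable:
    """Per-error-type counts of injected and correctly fixed errors."""

    n_errors: Dict[str, int] = field(default_factory=dict)
    n_fixed: Dict[str, int] = field(default_factory=dict)

    def pct(self, error_type: str) -> float:
        n = self.n_errors.get(error_type, 0)
        return 100.0 * self.n_fixed.get(error_type, 0) / n if n else 0.0

    def as_rows(self) -> List[Tuple[str, int, int, float]]:
        return [(t, self.n_errors.get(t, 0), self.n_fixed.get(t, 0),
                 round(self.pct(t), 1)) for t in ERROR_TYPES
                if t in self.n_errors]

    def to_json(self) -> str:
        return json.dumps({t: {"n": self.n_errors.get(t, 0),
                               "fixed": self.n_fixed.get(t, 0),
                               "pct": round(self.pct(t), 1)}
                           for t in ERROR_TYPES if t in self.n_errors},
                          indent=2)


def score_recovery(truths: Sequence[ErrorTruth], improved: Assembly,
                   cmap: ContigMap) -> RecoveryTable:
    """Score each injected error against the improved assembly.

    Fixed-if rules: terminal truncations and internal deletions need
    >= 90 % of the removed bases back in place in the mapped final
    contig; fragmentations, translocations and inversions need the final
    sequence identical to the original; unsupported insertions need every
    inserted base gone; chimeras need both constituent transcripts fully
    restored as separate contigs.
    """
    table = RecoveryTable()
    all_final = {c.id: c.sequence for c in improved}
    for truth in truths:
        table.n_errors[truth.error_type] = \
            table.n_errors.get(truth.error_type, 0) + 1
        finals: List[str] = []
        for eid in truth.err_ids:
            if eid not in cmap.mapping:
                raise ValueError(f"truth contig {eid!r} absent from map")
            for fid in cmap.finals_of(eid):
                if fid in all_final:
                    finals.append(all_final[fid])
        fixed = False
        et = truth.error_type
        if et in ("incomplete", "missing_seq"):
            fixed = any(_recovered_fraction(truth, f) >= 0.90 for f in finals)
        elif et in ("fragmented", "translocation", "inversion",
                    "unsupported_insertion"):
            fixed = _exact_present(truth.original_seqs[0], finals)
        elif et == "chimera":
            # the two fused sequences must be separated cleanly: each fully
            # present in its own final contig, and the fusion junction gone
            pa, pb = truth.original_seqs
            ids1 = [fid for eid in truth.err_ids
                    for fid in cmap.finals_of(eid) if fid in all_final]
            junction = pa[-25:] + pb[:25]
            fa = [fid for fid in ids1 if _contains(all_final[fid], pa)]
            fb = [fid for fid in ids1 if _contains(all_final[fid], pb)]
            no_junction = not any(_contains(all_final[fid], junction)
                                  for fid in ids1)
            fixed = no_junction and any(x != y for x in fa for y in fb)
        if fixed:
            table.n_fixed[truth.error_type] = \
                table.n_fixed.get(truth.error_type, 0) + 1
    return table
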