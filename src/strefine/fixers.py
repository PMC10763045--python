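"""Repairs applied to detected error signatures: end extension, fragment
merging, chimera splitting and local mis-assembly correction.

Each fixer is a pure function from (contig(s), signature, parameters) to
new contig(s) plus a description of what changed; the pipeline driver owns
event emission and assembly bookkeeping. All fixers are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._seq import encode_mask4, revcomp
from .core import (Assembly, Contig, CoverageBreak, InternalClipSite,
                   OverlapHit, Parameters, SoftClipCluster)
from .local_assembly import (OverlapSearcher, _overlap_candidates,
                             _score_shift, extend_overlap, find_local_overlap,
                             greedy_assemble, merge_by_overlap)

# ---------------------------------------------------------------------------
# small sequence helpers


def _compat_identity(a: str, b: str) -> float:
    """Fraction of IUPAC-compatible columns of two equal-length strings."""
    if len(a) != len(b) or not a:
        return 0.0
    ma, mb = encode_mask4(a), encode_mask4(b)
    return float(np.count_nonzero(ma & mb)) / len(a)


def _max_suffix_prefix(left: str, right: str, min_identity: float = 1.0,
                       max_ov: Optional[int] = None) -> int:
    """Largest t with left[-t:] compatible with right[:t] at
    >= min_identity; 0 when none."""
    cap = min(len(left), len(right))
    if max_ov is not None:
        cap = min(cap, max_ov)
    for t in range(cap, 0, -1):
        if _compat_identity(left[-t:], right[:t]) >= min_identity:
            return t
    return 0


def _best_hit(hits: Sequence[OverlapHit], query_len: int,
              min_identity_pct: float, min_span_frac: float = 0.9,
              exclude_anchor: Optional[Tuple[str, int, str]] = None,
              anchor_tol: int = 25) -> Optional[OverlapHit]:
    """First hit (hits are score-ordered) matching enough of the query at
    enough identity.

    ``exclude_anchor`` = (contig id, clip point, "start"|"end") drops the
    trivial self-match of a clip consensus onto its own flank: for a
    right-clip consensus that match starts at the clip point, for a
    left-clip consensus it ends there."""
    for h in hits:
        if h.identity_pct < min_identity_pct:
            continue
        if (h.query_range[1] - h.query_range[0]) < min_span_frac * query_len:
            continue
        if exclude_anchor is not None:
            cid, pos, side = exclude_anchor
            coord = h.subject_range[0] if side == "start" else h.subject_range[1]
            if h.subject_contig_id == cid and abs(coord - pos) <= anchor_tol:
                continue
        return h
    return None


# ---------------------------------------------------------------------------
# extension


def extend_with_clips(contig: Contig, cluster: SoftClipCluster,
                      consensus: str) -> Tuple[Contig, int]:
    """Extend an incomplete contig corner with the clip consensus.

    The consensus replaces any unsupported bases outside the clip point
    (none when the clip point sits exactly on the boundary, the usual
    case), so at a boundary cluster the length grows by exactly
    ``len(consensus)``. Returns (new contig, length gain)."""
    if not consensus:
        raise ValueError("empty consensus")
    p = cluster.position
    if cluster.direction == "left":
        new_seq = consensus + contig.sequence[p:]
    else:
        new_seq = contig.sequence[:p] + consensus
    gain = len(new_seq) - len(contig.sequence)
    return Contig(contig.id, new_seq, tags=set(contig.tags)), gain


@dataclass
class OrphanOutcome:
    """Result of an orphan-mate extension attempt."""

    contig: Optional[Contig] = None       # extended contig, if stitched
    gain: int = 0
    pending_block: Optional[str] = None   # unplaced assembled sequence
    edge: str = ""


def extend_with_orphans(contig: Contig, edge: str,
                        orphan_mates: Sequence[str],
                        params: Optional[Parameters] = None,
                        read_length: int = 100) -> OrphanOutcome:
    """Assemble the unmapped mates of an edge cluster and stitch the block
    to the contig across an edge overlap; a stitch must gain at least
    ``min_orphan_extension_pct`` % of the read length. Without an overlap
    the block is returned for addition as a separate (pending) contig.

    ``orphan_mates`` must already be oriented to the contig's forward
    strand."""
    params = params or Parameters()
    if not orphan_mates:
        return OrphanOutcome()
    blocks = greedy_assemble(list(orphan_mates), min_overlap=16,
                             min_identity_pct=95.0)
    block = blocks[0]
    if len(block) < read_length:
        return OrphanOutcome()
    min_gain = params.min_orphan_extension_pct / 100.0 * read_length
    ident = params.extend_identity_pct / 100.0
    cseq = contig.sequence
    if edge == "right":
        left_seq, right_seq = cseq, block
    else:
        left_seq, right_seq = block, cseq
    ml, mr = encode_mask4(left_seq), encode_mask4(right_seq)
    best = None  # (overlap_len, shift)
    for shift in _overlap_candidates(ml, mr):
        if shift <= 0 or shift + len(right_seq) <= len(left_seq):
            continue  # not a suffix-prefix configuration
        ov, identity = _score_shift(ml, mr, shift)
        if ov < params.min_island_overlap or identity < ident * 100.0:
            continue
        if best is None or ov > best[0]:
            best = (ov, shift)
    if best is None:
        return OrphanOutcome(pending_block=block, edge=edge)
    ov, shift = best
    if edge == "right":
        gain = shift + len(block) - len(cseq)
        new_seq = cseq[:shift] + block
    else:
        gain = shift  # == len(block) - ov
        new_seq = block[:shift] + cseq
    if gain < min_gain:
        return OrphanOutcome()
    return OrphanOutcome(
        contig=Contig(contig.id, new_seq, tags=set(contig.tags)),
        gain=gain, edge=edge)


# ---------------------------------------------------------------------------
# fragment merging


@dataclass
class MergeOutcome:
    left_id: str
    right_id: str
    merged: Contig
    overlap: int


def merge_fragments_by_clip(assembly: Assembly, contig_id: str, side: str,
                            params: Optional[Parameters] = None,
                            searcher: Optional[OverlapSearcher] = None
                            ) -> Optional[MergeOutcome]:
    """Merge a clip-extended contig with the contig its fresh extension
    lands on: the terminal ``seed_len`` bases of the extension seed a
    whole-assembly search requiring ``seed_identity_pct`` over the full
    seed; the winning hit (maximum score) is grown at
    ``extend_identity_pct`` and the contigs merged across the terminal
    overlap."""
    params = params or Parameters()
    contig = assembly[contig_id]
    seed_len = min(params.seed_len, len(contig.sequence))
    if side == "right":
        query = contig.sequence[-seed_len:]
    else:
        query = contig.sequence[:seed_len]
    searcher = searcher or OverlapSearcher(assembly)
    hits = [h for h in find_local_overlap(query, searcher, params)
            if h.subject_contig_id != contig_id and h.strand == "+"]
    hit = _best_hit(hits, len(query), params.seed_identity_pct,
                    min_span_frac=1.0)
    if hit is None:
        return None
    partner = assembly[hit.subject_contig_id]
    if side == "right":
        a, b = contig, partner
        seed = OverlapHit(
            query_range=(len(a.sequence) - seed_len + hit.query_range[0],
                         len(a.sequence) - seed_len + hit.query_range[1]),
            subject_contig_id=b.id, subject_range=hit.subject_range,
            strand="+", identity_pct=hit.identity_pct, n_gaps=hit.n_gaps,
            score=hit.score)
    else:
        a, b = partner, contig
        seed = OverlapHit(
            query_range=hit.subject_range, subject_contig_id=b.id,
            subject_range=hit.query_range, strand="+",
            identity_pct=hit.identity_pct, n_gaps=hit.n_gaps, score=hit.score)
    (a0, a1), (b0, b1) = extend_overlap(a, b, seed, params)
    if a1 != len(a.sequence) or b0 != 0:
        return None  # overlap is not terminal; not a simple fragmentation
    merged = merge_by_overlap(a, b, ((a0, a1), (b0, b1)))
    return MergeOutcome(a.id, b.id, merged, a1 - a0)


def merge_fragments_by_islands(assembly: Assembly, island,
                               params: Optional[Parameters] = None,
                               read_length: int = 100
                               ) -> Optional[MergeOutcome]:
    """Merge the two contigs of a linked read/mate island pair across a
    terminal edge overlap of >= ``min_island_overlap`` bases with score >=
    ``island_overlap_score``, starting within ``island_edge_slack_pct`` %
    of the read length from the island's outer edge."""
    params = params or Parameters()
    ca = assembly[island.contig_id]
    cb = assembly[island.partner_contig_id]
    # orient so `left` ends where `right` begins
    if island.edge == "right" and island.partner_edge == "left":
        left, right = ca, cb
    elif island.edge == "left" and island.partner_edge == "right":
        left, right = cb, ca
    else:
        return None  # same-edge islands would need an orientation flip
    ml, mr = encode_mask4(left.sequence), encode_mask4(right.sequence)
    slack = params.island_edge_slack_pct / 100.0 * read_length
    best = None
    for shift in _overlap_candidates(ml, mr):
        if shift <= 0 or shift + len(right.sequence) <= len(left.sequence):
            continue
        ov, identity = _score_shift(ml, mr, shift)
        if ov < params.min_island_overlap:
            continue
        score = identity  # identity over the overlap, as a percentage
        if score < params.island_overlap_score:
            continue
        # overlap must start within the slack of the outer edges
        if len(left.sequence) - shift - ov > slack or \
           (shift + len(right.sequence)) - len(left.sequence) < -slack:
            continue
        if best is None or ov > best[0]:
            best = (ov, shift)
    if best is None:
        return None
    ov, shift = best
    merged_seq = left.sequence[:shift] + right.sequence
    merged = Contig(left.id, merged_seq, tags=left.tags | right.tags)
    return MergeOutcome(left.id, right.id, merged, len(left.sequence) - shift)


# ---------------------------------------------------------------------------
# chimera splitting


@dataclass
class SplitOutcome:
    kind: str                          # event kind applied
    contigs_out: List[Contig] = field(default_factory=list)
    removed: List[str] = field(default_factory=list)  # removed sequences
    position: int = 0


def _route_split_piece(cid: str, smaller: str, larger: str, position: int,
                       params: Parameters, base_kind: str) -> SplitOutcome:
    """Shared disposition of the smaller piece of a split: removed as a
    self-chimera duplicate, kept as a new contig, or discarded as too
    short."""
    keep_larger = Contig(f"{cid}_s1", larger, tags={"split-product"})
    if len(smaller) >= WORD:
        hits = find_local_overlap(smaller, Contig("x", larger), params)
        dup = _best_hit(hits, len(smaller), params.internal_identity_pct,
                        min_span_frac=0.9)
    else:
        dup = None
    if dup is not None:
        return SplitOutcome(kind="self-chimera-removed",
                            contigs_out=[keep_larger], removed=[smaller],
                            position=position)
    if len(smaller) >= params.min_new_contig_len:
        return SplitOutcome(kind=base_kind,
                            contigs_out=[keep_larger,
                                         Contig(f"{cid}_s2", smaller,
                                                tags={"split-product"})],
                            position=position)
    return SplitOutcome(kind="discarded", contigs_out=[keep_larger],
                        removed=[smaller], position=position)


WORD = 11


def split_chimera_at_clip(contig: Contig, site: InternalClipSite,
                          params: Optional[Parameters] = None,
                          read_length: int = 100) -> Optional[SplitOutcome]:
    """Handle a one-sided internal clip site: excise an internal repeat
    when the clip consensus re-occurs in the contig (self-chimera),
    otherwise split at the clip point and route the smaller piece."""
    params = params or Parameters()
    if site.kind not in ("one_sided_left", "one_sided_right"):
        raise ValueError("site is not one-sided")
    p = site.positions[0]
    consensus = site.left_consensus or site.right_consensus
    anchor_side = "end" if site.kind == "one_sided_left" else "start"
    seq = contig.sequence
    hits = find_local_overlap(consensus, Contig(contig.id, seq), params) \
        if len(consensus) >= WORD else []
    hit = _best_hit(hits, len(consensus), params.internal_identity_pct,
                    min_span_frac=0.9,
                    exclude_anchor=(contig.id, p, anchor_side))
    if hit is not None and hit.strand == "+":
        h0, h1 = hit.subject_range
        if h1 <= p:
            left, right = seq[:h1], seq[p:]
            region = seq[h1:p]
        elif h0 >= p:
            left, right = seq[:p], seq[h0:]
            region = seq[p:h0]
        else:
            return None
        t = _max_suffix_prefix(left, right)
        joined = left + right[t:]
        return SplitOutcome(kind="self-chimera-removed",
                            contigs_out=[Contig(contig.id, joined,
                                                tags=set(contig.tags))],
                            removed=[region], position=p)
    piece1, piece2 = seq[:p], seq[p:]
    if not piece1 or not piece2:
        return None
    smaller, larger = (piece1, piece2) if len(piece1) <= len(piece2) \
        else (piece2, piece1)
    out = _route_split_piece(contig.id, smaller, larger, p, params,
                             "chimera-split-clip")
    if len(out.contigs_out) == 2:
        # keep positional order: piece1 -> _s1, piece2 -> _s2
        c1, c2 = out.contigs_out
        out.contigs_out = [Contig(c1.id, piece1, tags=c1.tags),
                           Contig(c2.id, piece2, tags=c2.tags)]
    return out


def split_chimera_at_crisscross(contig: Contig, site: InternalClipSite,
                                params: Optional[Parameters] = None
                                ) -> Optional[SplitOutcome]:
    """Split a fusion of two broken transcript pieces.

    A crisscross site whose consensuses hit nowhere in the contig and
    cannot be bridged into a missing-sequence insert marks the fusion
    point of two unrelated pieces. Each side keeps the bases its own clip
    evidence supports (the right-clip point for the left piece, the
    left-clip point for the right piece), so the pieces may share the few
    junction bases that alignments extended over by chance."""
    params = params or Parameters()
    if site.kind != "crisscross":
        raise ValueError("site is not crisscross")
    pr, pl = site.positions
    seq = contig.sequence
    piece1, piece2 = seq[:pr], seq[pl:]
    if len(piece1) < 1 or len(piece2) < 1:
        return None
    if len(piece1) <= len(piece2):
        smaller, larger, l_first = piece1, piece2, False
    else:
        smaller, larger, l_first = piece2, piece1, True
    out = _route_split_piece(contig.id, smaller, larger, pr, params,
                             "chimera-split-clip")
    if len(out.contigs_out) == 2:
        c1, c2 = out.contigs_out
        out.contigs_out = [Contig(c1.id, piece1, tags=c1.tags),
                           Contig(c2.id, piece2, tags=c2.tags)]
    elif l_first and out.contigs_out:
        out.contigs_out = [Contig(out.contigs_out[0].id, piece1,
                                  tags=out.contigs_out[0].tags)]
    return out


def split_chimera_at_coverage(contig: Contig, brk: CoverageBreak,
                              params: Optional[Parameters] = None
                              ) -> Optional[SplitOutcome]:
    """Split at an abrupt (or windowed) coverage break; the smaller piece
    is routed exactly as for a clip split."""
    params = params or Parameters()
    p = brk.position
    seq = contig.sequence
    piece1, piece2 = seq[:p], seq[p:]
    if not piece1 or not piece2:
        return None
    smaller, larger = (piece1, piece2) if len(piece1) <= len(piece2) \
        else (piece2, piece1)
    out = _route_split_piece(contig.id, smaller, larger, p, params,
                             "chimera-split-coverage")
    if len(out.contigs_out) == 2:
        c1, c2 = out.contigs_out
        out.contigs_out = [Contig(c1.id, piece1, tags=c1.tags),
                           Contig(c2.id, piece2, tags=c2.tags)]
    return out


# ---------------------------------------------------------------------------
# local mis-assemblies


@dataclass
class LocalFixOutcome:
    kind: str
    contig: Contig
    seq_delta: str = ""
    coords: Tuple[Tuple[int, int], ...] = ()
    routed_piece: Optional[str] = None  # long removed insert, to chimera check


def _trim_against(consensus: str, flank: str, from_end: bool,
                  min_identity: float = 0.9) -> str:
    """Drop the part of a clip consensus that merely re-matches the contig
    flank beyond the clip point (clips longer than the event capture
    genuine neighbouring sequence)."""
    cap = min(len(consensus), len(flank))
    best = 0
    for t in range(1, cap + 1):
        seg = consensus[-t:] if from_end else consensus[:t]
        ref = flank[:t] if from_end else flank[-t:]
        if _compat_identity(seg, ref) >= min_identity:
            best = t
    return consensus[:len(consensus) - best] if from_end else consensus[best:]


def fix_missing_sequence(contig: Contig, site: InternalClipSite,
                         params: Optional[Parameters] = None,
                         allow_concat: bool = True
                         ) -> Optional[LocalFixOutcome]:
    """Insert sequence flagged as missing by a crisscross clip site whose
    consensuses match nowhere else in the contig.

    The right-clip consensus appended at its clip point and the left-clip
    consensus prepended at its clip point describe the two true junction
    neighbourhoods; bridging them across their maximal overlap rebuilds
    the contig with the missing bases in place (and transparently absorbs
    clip points that overshoot the junction when missing bases happen to
    match the flank). When the two consensuses do not reach each other
    the insert is their end-to-end concatenation."""
    params = params or Parameters()
    if site.kind != "crisscross":
        raise ValueError("site is not crisscross")
    pr, pl = site.positions
    seq = contig.sequence
    right_cons = site.right_consensus or ""
    left_cons = site.left_consensus or ""
    if not right_cons or not left_cons:
        return None
    left_part = seq[:pr] + right_cons
    right_part = left_cons + seq[pl:]
    floor = max(len(right_cons), len(left_cons))
    cap = len(right_cons) + len(left_cons) + abs(pr - pl) + 20
    t = _max_suffix_prefix(left_part, right_part, min_identity=0.9,
                           max_ov=cap)
    if t >= floor:
        # the junction bridged by both consensus neighbourhoods; the net
        # gain may also be negative (a small unsupported duplicate at the
        # junction, e.g. residue of an earlier approximate fix)
        new_seq = left_part + right_part[t:]
        if new_seq == seq:
            return None
        gained = len(new_seq) - len(seq)
        kind = "missing-inserted" if gained >= 0 else "insertion-removed"
        delta = new_seq[pr:pr + gained] if gained > 0 else seq[pr:pr - gained]
    elif allow_concat and pr == pl:
        # the consensuses do not reach each other (missing block longer
        # than the clips): insert head and tail end-to-end
        delta = right_cons + left_cons
        new_seq = seq[:pr] + delta + seq[pl:]
        kind = "missing-inserted"
    else:
        return None
    return LocalFixOutcome(kind=kind,
                           contig=Contig(contig.id, new_seq,
                                         tags=set(contig.tags)),
                           seq_delta=delta, coords=((pr, pl),))


def _move_block(contig: Contig, b0: int, b1: int, strand: str,
                p: int) -> Optional[LocalFixOutcome]:
    """Excise the block [b0, b1), reverse-complement it for a minus-strand
    relocation, and reinsert at point ``p``; length is preserved."""
    seq = contig.sequence
    if not (0 <= b0 < b1 <= len(seq)) or (b0 <= p <= b1):
        return None
    frag = seq[b0:b1]
    if strand == "-":
        frag = revcomp(frag)
    rest = seq[:b0] + seq[b1:]
    p2 = p if p <= b0 else p - (b1 - b0)
    new_seq = rest[:p2] + frag + rest[p2:]
    if len(new_seq) != len(seq):
        return None
    kind = "inversion-fixed" if strand == "-" else "translocation-fixed"
    return LocalFixOutcome(kind=kind,
                           contig=Contig(contig.id, new_seq,
                                         tags=set(contig.tags)),
                           seq_delta=frag, coords=((b0, b1), (p, p)))


def resolve_adjacency_move(contig: Contig,
                           sited_hits: Sequence[Tuple[str, int, OverlapHit]],
                           params: Optional[Parameters] = None,
                           tol: int = 5) -> Optional[LocalFixOutcome]:
    """Reconstruct a translocation or inversion from two one-sided clip
    sites whose consensus hits jointly delineate a moved block.

    A *bypass* site shows the true sequence jumping over a block (a
    forward hit strictly on the anchor side of its clip point); a
    *destination* site shows the block's content continuing at another
    clip point, forward strand for a translocation, reverse strand for an
    inversion. Signatures arrive split this way when read pairs crossing
    a relocated block's boundaries are removed by orientation filtering.
    """
    for bi, (d, p, h) in enumerate(sited_hits):
        if h.strand != "+":
            continue
        if d == "left" and h.subject_range[1] < p - 10:
            b0, b1 = h.subject_range[1], p
        elif d == "right" and h.subject_range[0] > p + 10:
            b0, b1 = p, h.subject_range[0]
        else:
            continue
        for j, (d2, p2, h2) in enumerate(sited_hits):
            if j == bi or b0 <= p2 <= b1:
                continue
            s0, s1 = h2.subject_range
            if h2.strand == "-" and ((d2 == "right" and abs(s1 - b1) <= tol) or
                                     (d2 == "left" and abs(s0 - b0) <= tol)):
                out = _move_block(contig, b0, b1, "-", p2)
            elif h2.strand == "+" and ((d2 == "right" and abs(s0 - b0) <= tol) or
                                       (d2 == "left" and abs(s1 - b1) <= tol)):
                out = _move_block(contig, b0, b1, "+", p2)
            else:
                out = None
            if out is not None:
                return out
    return None


def fix_translocation_inversion(contig: Contig, site: InternalClipSite,
                                hit_left: Optional[OverlapHit],
                                hit_right: Optional[OverlapHit],
                                params: Optional[Parameters] = None
                                ) -> Optional[LocalFixOutcome]:
    """Move (and possibly reverse-complement) a mis-placed fragment back to
    the crisscross clip point. The two consensus hits bound the fragment;
    a reverse-strand hit marks an inversion. Total length is preserved."""
    params = params or Parameters()
    if site.kind != "crisscross":
        raise ValueError("site is not crisscross")
    if hit_left is None or hit_right is None:
        return None
    if hit_left.strand != hit_right.strand:
        return None
    strand = hit_left.strand
    q1 = min(hit_left.subject_range[0], hit_right.subject_range[0])
    q2 = max(hit_left.subject_range[1], hit_right.subject_range[1])
    return _move_block(contig, q1, q2, strand, site.positions[0])


def remove_unsupported_insertion(contig: Contig, site: InternalClipSite,
                                 params: Optional[Parameters] = None
                                 ) -> Optional[LocalFixOutcome]:
    """Delete the read-unsupported segment between facing clip points: the
    right-clip consensus must match the contig immediately after the left
    clip point and vice versa, so the deleted length equals the clip-point
    distance exactly."""
    params = params or Parameters()
    if site.kind != "facing":
        raise ValueError("site is not facing")
    p1, p2 = site.positions
    if p2 <= p1:
        return None
    seq = contig.sequence
    r_cons = site.right_consensus or ""
    l_cons = site.left_consensus or ""
    thr = params.internal_identity_pct / 100.0
    if not r_cons or not l_cons:
        return None
    # either clip point may have extended a few bases into the insert by
    # chance matches; recover the offsets by probing a small shift range
    max_shift = 8
    k = None
    for cand in range(max_shift + 1):
        probe = r_cons[:min(len(r_cons), len(seq) - p2 - cand)]
        if len(probe) < 10:
            break
        if _compat_identity(probe, seq[p2 + cand:p2 + cand + len(probe)]) >= thr:
            k = cand
            break
    if k is None:
        return None
    cut1 = p1 - k
    j = None
    for cand in range(max_shift + 1):
        m = min(len(l_cons), cut1 - cand)
        if m < 10:
            break
        probe = l_cons[-m:]
        if _compat_identity(probe, seq[cut1 - cand - m:cut1 - cand]) >= thr:
            j = cand
            break
    if j is None:
        return None
    cut1 -= 0  # right clip overshoot already folded in via k
    cut2 = p2 + j
    if not (0 <= cut1 < cut2 <= len(seq)):
        return None
    removed = seq[cut1:cut2]
    new_seq = seq[:cut1] + seq[cut2:]
    routed = removed if len(removed) >= params.min_new_contig_len else None
    return LocalFixOutcome(kind="insertion-removed",
                           contig=Contig(contig.id, new_seq,
                                         tags=set(contig.tags)),
                           seq_delta=removed, coords=((cut1, cut2),),
                           routed_piece=routed)
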