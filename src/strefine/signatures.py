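"""Error-signature detection on filtered alignments.

Five signature families drive the corrector: outward soft-clip clusters at
contig edges (incompleteness), edge reads with unmapped mates (missing
flanking sequence), internal soft-clip sites (false chimeras and local
mis-assemblies), linked read/mate islands on different contigs
(fragmentation), and abrupt or gradual per-base coverage breaks (chimeric
junctions between transcripts of different expression level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .alignment import MIN_CLIP, compute_coverage
from .core import (AlignmentRecord, Assembly, Contig, CoverageBreak,
                   CoverageProfile, InternalClipSite, MateIsland, Parameters,
                   SoftClipCluster)
from .local_assembly import consensus_from_clips

POOL_WINDOW = 5  # clip points this close are one cluster (aligner jitter)


# ---------------------------------------------------------------------------
# clip collection helpers


@dataclass
class _ClipGroup:
    position: int
    direction: str                    # direction the clipped bases extend
    members: List[AlignmentRecord] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.members)

    def fragments(self) -> List[Tuple[int, str]]:
        """Clipped substrings with offsets relative to the modal clip
        point. Fragments from reads clipped a few bases early (pooling
        jitter) are trimmed to the modal point so every column of a
        right-direction stack sits at offset >= 0 (and <= 0 for left)."""
        frags = []
        for rec in self.members:
            if self.direction == "right":
                frag = rec.seq[len(rec.seq) - rec.right_clip:]
                off = rec.end - self.position
                if off < 0:
                    frag = frag[-off:]
                    off = 0
                if frag:
                    frags.append((off, frag))
            else:
                frag = rec.seq[:rec.left_clip]
                off = rec.start - self.position - len(frag)
                end_off = off + len(frag)
                if end_off > 0:
                    frag = frag[:len(frag) - end_off]
                if frag:
                    frags.append((off, frag))
        return frags


def _span_arrays(records: Iterable[AlignmentRecord],
                 contig_id: str) -> Tuple[np.ndarray, np.ndarray]:
    starts, ends = [], []
    for rec in records:
        if rec.contig_id == contig_id:
            starts.append(rec.start)
            ends.append(rec.end)
    return (np.asarray(starts, dtype=np.int64),
            np.asarray(ends, dtype=np.int64))


def _collect_clip_groups(records: Iterable[AlignmentRecord],
                         contig_id: str,
                         contig_len: Optional[int] = None) -> List[_ClipGroup]:
    """Pool per-direction clip points within POOL_WINDOW at the modal point.

    Interior clips shorter than MIN_CLIP are alignment jitter and ignored,
    but clips of any length sitting exactly on a contig boundary are kept
    when ``contig_len`` is given: the aligner had no reference left to
    absorb them into, so a 1-2 base overhang there is genuine evidence."""
    raw: Dict[Tuple[str, int], List[AlignmentRecord]] = {}
    for rec in records:
        if rec.contig_id != contig_id:
            continue
        min_r = 1 if (contig_len is not None and rec.end == contig_len) \
            else MIN_CLIP
        min_l = 1 if (contig_len is not None and rec.start == 0) else MIN_CLIP
        if rec.right_clip >= min_r:
            raw.setdefault(("right", rec.end), []).append(rec)
        if rec.left_clip >= min_l:
            raw.setdefault(("left", rec.start), []).append(rec)
    groups: List[_ClipGroup] = []
    for direction in ("left", "right"):
        pts = sorted(p for d, p in raw if d == direction)
        if not pts:
            continue
        chains: List[List[int]] = [[pts[0]]]
        for p in pts[1:]:
            if p - chains[-1][-1] <= POOL_WINDOW:
                chains[-1].append(p)
            else:
                chains.append([p])
        for chain in chains:
            members: List[AlignmentRecord] = []
            modal, modal_n = chain[0], -1
            for p in chain:
                n = len(raw[(direction, p)])
                members.extend(raw[(direction, p)])
                if n > modal_n:
                    modal, modal_n = p, n
            groups.append(_ClipGroup(modal, direction, members))
    return groups


# a read must run this far past a clip point on both sides to count as
# spanning it: beyond pooling jitter plus the few bases an alignment can
# extend past a junction by chance matches
_SPAN_MARGIN = 10


def _support(group: _ClipGroup, starts: np.ndarray, ends: np.ndarray) -> float:
    """Clipped reads at the point over clipped-plus-spanning reads: a read
    whose alignment runs continuously through the point (with a small
    margin absorbing jitter) contradicts the junction hypothesis, while
    reads merely abutting it are junction artifacts and carry no vote."""
    p = group.position
    n_span = int(np.count_nonzero((starts <= p - _SPAN_MARGIN) &
                                  (ends >= p + _SPAN_MARGIN)))
    return group.n_reads / (group.n_reads + n_span)


# ---------------------------------------------------------------------------
# edge clips


def find_edge_clip_clusters(records: List[AlignmentRecord], contig: Contig,
                            params: Optional[Parameters] = None,
                            profile: Optional[CoverageProfile] = None
                            ) -> List[SoftClipCluster]:
    """Outward-pointing soft-clip clusters within ``edge_clip_window`` of a
    contig boundary, with enough reads and support fraction."""
    params = params or Parameters()
    L = len(contig)
    starts, ends = _span_arrays(records, contig.id)
    out = []
    for g in _collect_clip_groups(records, contig.id, contig_len=L):
        outward = (g.direction == "left" and g.position <= params.edge_clip_window) or \
                  (g.direction == "right" and L - g.position <= params.edge_clip_window)
        if not outward:
            continue
        if g.n_reads < params.min_clip_reads:
            continue
        support = _support(g, starts, ends)
        if support * 100.0 < params.clip_support_pct:
            continue
        out.append(SoftClipCluster(
            contig_id=contig.id, position=g.position, direction=g.direction,
            n_reads=g.n_reads, support_fraction=support,
            fragments=g.fragments(),
            read_ids=[r.read_id for r in g.members]))
    return out


# ---------------------------------------------------------------------------
# orphan mates


@dataclass
class OrphanCluster:
    """Edge reads pointing outward whose mates found no alignment."""

    contig_id: str
    edge: str                          # "left" | "right"
    read_ids: List[str]
    anchors: List[AlignmentRecord] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


def find_orphan_mate_clusters(records: List[AlignmentRecord], contig: Contig,
                              params: Optional[Parameters] = None
                              ) -> List[OrphanCluster]:
    """Clusters of >= ``min_orphan_reads`` outward edge reads with unmapped
    mates, each anchor having less than ``max_orphan_clip_pct`` of its
    length soft-clipped."""
    params = params or Parameters()
    L = len(contig)
    edges: Dict[str, List[AlignmentRecord]] = {"left": [], "right": []}
    for rec in records:
        if rec.contig_id != contig.id or rec.orientation != "mate-unmapped":
            continue
        rl = rec.read_length
        clipped_pct = 100.0 * (rec.left_clip + rec.right_clip) / rl
        if clipped_pct >= params.max_orphan_clip_pct:
            continue
        w = params.edge_window(rl)
        if rec.strand == "+" and rec.end > L - w:
            edges["right"].append(rec)
        elif rec.strand == "-" and rec.start < w:
            edges["left"].append(rec)
    out = []
    for edge in ("left", "right"):
        anchors = edges[edge]
        if len(anchors) >= params.min_orphan_reads:
            out.append(OrphanCluster(
                contig_id=contig.id, edge=edge,
                read_ids=[r.read_id for r in anchors], anchors=anchors))
    return out


# ---------------------------------------------------------------------------
# internal clip sites


def find_internal_clip_sites(records: List[AlignmentRecord], contig: Contig,
                             junctions: Optional[dict] = None,
                             params: Optional[Parameters] = None,
                             profile: Optional[CoverageProfile] = None
                             ) -> List[InternalClipSite]:
    """Internal soft-clip sites classified as one-sided (chimeric junction),
    crisscross (missing sequence / translocation / inversion) or facing
    (unsupported insertion). Clip points at splice-junction boundaries are
    ignored."""
    params = params or Parameters()
    jset = (junctions or {}).get(contig.id, set())
    L = len(contig)
    starts, ends = _span_arrays(records, contig.id)
    qualified = []
    for g in _collect_clip_groups(records, contig.id):
        if g.position <= params.edge_clip_window or \
           L - g.position <= params.edge_clip_window:
            continue
        if any(abs(g.position - j) <= POOL_WINDOW for j in jset):
            continue
        if g.n_reads < params.min_clip_reads:
            continue
        support = _support(g, starts, ends)
        if support * 100.0 < params.clip_support_pct:
            continue
        frags = g.fragments()
        if not frags:
            continue
        consensus = consensus_from_clips(frags, params, min_depth=2)
        if len(consensus) < params.min_internal_consensus:
            continue
        qualified.append((g, support, consensus))

    window = 2 * _typical_read_length(records)
    lefts = [q for q in qualified if q[0].direction == "left"]
    rights = [q for q in qualified if q[0].direction == "right"]
    used_l, used_r = set(), set()
    sites: List[InternalClipSite] = []

    # crisscross: left and right clips at (essentially) the same point
    for i, (gl, sl, cl) in enumerate(lefts):
        for j, (gr, sr, cr) in enumerate(rights):
            if j in used_r:
                continue
            if abs(gl.position - gr.position) <= POOL_WINDOW:
                used_l.add(i)
                used_r.add(j)
                sites.append(InternalClipSite(
                    contig_id=contig.id, kind="crisscross",
                    positions=(gr.position, gl.position),
                    left_consensus=cl, right_consensus=cr,
                    support_fraction=min(sl, sr),
                    n_reads=gl.n_reads + gr.n_reads))
                break

    # facing: right clips at p1 strictly left of left clips at p2
    for j, (gr, sr, cr) in enumerate(rights):
        if j in used_r:
            continue
        for i, (gl, sl, cl) in enumerate(lefts):
            if i in used_l:
                continue
            if gr.position < gl.position <= gr.position + window:
                used_r.add(j)
                used_l.add(i)
                sites.append(InternalClipSite(
                    contig_id=contig.id, kind="facing",
                    positions=(gr.position, gl.position),
                    left_consensus=cl, right_consensus=cr,
                    support_fraction=min(sl, sr),
                    n_reads=gl.n_reads + gr.n_reads))
                break

    for i, (gl, sl, cl) in enumerate(lefts):
        if i not in used_l:
            sites.append(InternalClipSite(
                contig_id=contig.id, kind="one_sided_left",
                positions=(gl.position,), left_consensus=cl,
                support_fraction=sl, n_reads=gl.n_reads))
    for j, (gr, sr, cr) in enumerate(rights):
        if j not in used_r:
            sites.append(InternalClipSite(
                contig_id=contig.id, kind="one_sided_right",
                positions=(gr.position,), right_consensus=cr,
                support_fraction=sr, n_reads=gr.n_reads))
    sites.sort(key=lambda s: s.positions[0])
    return sites


def _typical_read_length(records: Iterable[AlignmentRecord]) -> int:
    for rec in records:
        return rec.read_length
    return 100


# ---------------------------------------------------------------------------
# mate islands


def find_mate_islands(records: List[AlignmentRecord], assembly: Assembly,
                      params: Optional[Parameters] = None) -> List[MateIsland]:
    """Linked island pairs: >= ``min_island_reads`` outward edge reads on
    one contig whose mates cluster at an edge of a single other contig."""
    params = params or Parameters()
    groups: Dict[Tuple[str, str, str], List[AlignmentRecord]] = {}
    for rec in records:
        if rec.orientation != "cross":
            continue
        contig = assembly[rec.contig_id]
        w = params.edge_window(rec.read_length)
        L = len(contig)
        if rec.strand == "+" and rec.end > L - w:
            edge = "right"
        elif rec.strand == "-" and rec.start < w:
            edge = "left"
        else:
            continue
        groups.setdefault((rec.contig_id, edge, rec.mate_contig_id),
                          []).append(rec)

    islands: List[MateIsland] = []
    seen = set()
    for (cid, edge, partner), recs in sorted(groups.items()):
        if len(recs) < params.min_island_reads:
            continue
        # the partner-side island: the mates of these reads
        ids = {r.read_id for r in recs}
        partner_recs = [r for r in records
                        if r.contig_id == partner and r.read_id in ids
                        and r.orientation == "cross"]
        if len(partner_recs) < params.min_island_reads:
            continue
        pL = len(assembly[partner])
        pw = params.edge_window(partner_recs[0].read_length)
        p_left = sum(1 for r in partner_recs if r.start < pw)
        p_right = sum(1 for r in partner_recs if r.end > pL - pw)
        if max(p_left, p_right) < params.min_island_reads:
            continue
        p_edge = "left" if p_left >= p_right else "right"
        key = frozenset([(cid, edge), (partner, p_edge)])
        if key in seen:
            continue
        seen.add(key)
        islands.append(MateIsland(
            contig_id=cid, edge=edge,
            span=(min(r.start for r in recs), max(r.end for r in recs)),
            read_ids=sorted(ids),
            partner_contig_id=partner, partner_edge=p_edge,
            partner_span=(min(r.start for r in partner_recs),
                          max(r.end for r in partner_recs))))
    return islands


# ---------------------------------------------------------------------------
# coverage breaks


def find_abrupt_breaks(profile: CoverageProfile,
                       params: Optional[Parameters] = None,
                       read_length: int = 100) -> List[CoverageBreak]:
    """Positions where depth changes by >= ``abrupt_cov_pct`` % (relative to
    the larger of the two consecutive depths), outside the end-ignore
    zones. A zero-coverage run yields breaks at both of its ends."""
    params = params or Parameters()
    d = profile.depth.astype(np.float64)
    L = len(d)
    ignore = params.end_ignore_bases(read_length)
    if L < 2 * ignore + 2:
        return []
    a, b = d[:-1], d[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(a - b) / np.maximum(a, b) * 100.0
    rel = np.nan_to_num(rel, nan=0.0)
    idx = np.nonzero(rel >= params.abrupt_cov_pct)[0]
    out = []
    for i in idx:
        if not (ignore <= i < L - ignore):
            continue
        out.append(CoverageBreak(profile.contig_id, position=int(i) + 1,
                                 left_depth=float(a[i]), right_depth=float(b[i]),
                                 mode="abrupt"))
    return out


def find_gradual_breaks(profile: CoverageProfile,
                        params: Optional[Parameters] = None,
                        read_length: int = 100) -> List[CoverageBreak]:
    """Sliding-window break scan (two flanking windows of
    ``gradual_window`` bp); disabled unless ``gradual_check`` is on."""
    params = params or Parameters()
    if not params.gradual_check:
        return []
    d = profile.depth.astype(np.float64)
    w = params.gradual_window
    L = len(d)
    ignore = params.end_ignore_bases(read_length)
    if L < 2 * w + 1:
        return []
    cs = np.concatenate([[0.0], np.cumsum(d)])
    pos = np.arange(w, L - w + 1)
    left = (cs[pos] - cs[pos - w]) / w
    right = (cs[pos + w] - cs[pos]) / w
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(left - right) / np.maximum(left, right) * 100.0
    rel = np.nan_to_num(rel, nan=0.0)
    ok = rel >= params.gradual_cov_pct
    out = []
    run_start = None
    for i, flag in enumerate(ok):
        if flag and run_start is None:
            run_start = i
        if (not flag or i == len(ok) - 1) and run_start is not None:
            run_end = i if not flag else i + 1
            seg = slice(run_start, run_end)
            best = run_start + int(np.argmax(rel[seg]))
            p = int(pos[best])
            if ignore <= p < L - ignore:
                out.append(CoverageBreak(
                    profile.contig_id, position=p,
                    left_depth=float(left[best]), right_depth=float(right[best]),
                    mode="gradual"))
            run_start = None
    return out
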