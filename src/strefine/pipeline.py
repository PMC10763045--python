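"""Pipeline driver: redundancy removal and the nested inner/outer
correction iterations.

One outer pass is: inner extension loop (soft-clip consensus at contig
edges, edge-read-only realignment) -> clip-based fragment merging -> full
realignment -> orphan-mate extension and mate-island merging -> full
realignment -> chimera splitting and local mis-assembly fixes. Outer
passes repeat until a pass touches no contig (or ``outer_max`` is hit);
unplaced orphan blocks are then N-joined to their host contigs.

The corrector itself is fully deterministic; randomness exists only in
the simulator.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .alignment import (Aligner, ReadStore, compute_coverage,
                        detect_junctions, filter_alignments)
from .core import (AlignmentRecord, Assembly, ChangeEvent, Contig, ContigMap,
                   Parameters)
from .fixers import (LocalFixOutcome, MergeOutcome, SplitOutcome,
                     extend_with_clips, extend_with_orphans,
                     fix_missing_sequence, fix_translocation_inversion,
                     merge_fragments_by_clip, merge_fragments_by_islands,
                     remove_unsupported_insertion, resolve_adjacency_move,
                     split_chimera_at_clip, split_chimera_at_coverage,
                     split_chimera_at_crisscross)
from .io import write_reports
from .local_assembly import (OverlapSearcher, consensus_from_clips,
                             find_local_overlap)
from .signatures import (POOL_WINDOW, find_abrupt_breaks,
                         find_edge_clip_clusters, find_gradual_breaks,
                         find_internal_clip_sites, find_mate_islands,
                         find_orphan_mate_clusters)
from ._seq import revcomp


# ---------------------------------------------------------------------------
# lineage tracking


class _Lineage:
    """Tracks which initial contigs every current contig descends from."""

    def __init__(self, initial_ids: Sequence[str]):
        self.initial_ids = list(initial_ids)
        self.origin: Dict[str, Set[str]] = {i: {i} for i in initial_ids}
        self.touched: Set[str] = set()
        self.merged: Set[str] = set()
        self.split: Set[str] = set()

    def new_contig(self, cid: str) -> None:
        self.origin[cid] = set()

    def touch(self, cid: str) -> None:
        self.touched |= self.origin.get(cid, set())

    def merge(self, keep: str, gone: str) -> None:
        self.merged |= self.origin.get(keep, set()) | self.origin.get(gone, set())
        self.origin[keep] = self.origin.get(keep, set()) | \
            self.origin.pop(gone, set())

    def split_into(self, cid: str, outs: Sequence[str]) -> None:
        src = self.origin.pop(cid, set())
        self.split |= src
        for o in outs:
            self.origin[o] = self.origin.get(o, set()) | set(src)

    def rename(self, old: str, new: str) -> None:
        if old != new:
            self.origin[new] = self.origin.pop(old, set())

    def remove(self, cid: str) -> None:
        self.origin.pop(cid, None)

    def contig_map(self, final_assembly: Assembly) -> ContigMap:
        finals_by_initial: Dict[str, List[str]] = {i: [] for i in self.initial_ids}
        for cur, src in self.origin.items():
            if cur not in final_assembly:
                continue
            for i in src:
                if i in finals_by_initial:
                    finals_by_initial[i].append(cur)
        mapping: Dict[str, List[Tuple[str, str]]] = {}
        for i in self.initial_ids:
            finals = sorted(finals_by_initial[i])
            if not finals:
                mapping[i] = [("-", "removed")]
            elif len(finals) > 1:
                mapping[i] = [(f, "split-into") for f in finals]
            else:
                f = finals[0]
                if f == i:
                    rel = "extended" if i in self.touched else "unchanged"
                elif i in self.merged:
                    rel = "merged-into"
                elif i in self.split:
                    rel = "split-into"
                else:
                    rel = "extended"
                mapping[i] = [(f, rel)]
        return ContigMap(mapping)


# ---------------------------------------------------------------------------
# run state


@dataclass
class RunState:
    assembly: Assembly
    store: ReadStore
    params: Parameters
    outer_iter: int = 0
    inner_iter: int = 0
    contigs_with_errors: int = 0
    events: List[ChangeEvent] = field(default_factory=list)
    pending_orphan_blocks: List[Tuple[str, str, str]] = field(default_factory=list)
    records: List[AlignmentRecord] = field(default_factory=list)
    ext_sides: Dict[str, Set[str]] = field(default_factory=dict)
    junction_check: bool = True
    converged: bool = False
    lineage: _Lineage = None  # type: ignore[assignment]
    sam_records: Optional[List[AlignmentRecord]] = None
    intermediates: List[Assembly] = field(default_factory=list)
    keep_intermediates: bool = False

    def __post_init__(self):
        if self.lineage is None:
            self.lineage = _Lineage(self.assembly.ids)

    def emit(self, kind: str, contigs_in, contigs_out, coords=(),
             seq_delta: str = "", inner: Optional[int] = None) -> None:
        self.events.append(ChangeEvent(
            outer_iter=self.outer_iter, inner_iter=inner, kind=kind,
            contigs_in=tuple(contigs_in), contigs_out=tuple(contigs_out),
            coords=tuple(coords), seq_delta=seq_delta,
            seq=len(self.events)))


# ---------------------------------------------------------------------------
# alignment plumbing


def _full_alignment(state: RunState) -> List[AlignmentRecord]:
    if state.sam_records is not None:
        records, state.sam_records = state.sam_records, None
        return filter_alignments(records, state.params)
    aligner = Aligner(state.assembly, state.params)
    return filter_alignments(aligner.align(state.store), state.params)


def _group_by_contig(records: List[AlignmentRecord]
                     ) -> Dict[str, List[AlignmentRecord]]:
    by: Dict[str, List[AlignmentRecord]] = {}
    for rec in records:
        by.setdefault(rec.contig_id, []).append(rec)
    return by


def _shift_records(records: List[AlignmentRecord],
                   left_gains: Dict[str, int]) -> None:
    if not left_gains:
        return
    for rec in records:
        g = left_gains.get(rec.contig_id)
        if g:
            rec.start += g
            rec.end += g
        if rec.mate_start is not None and rec.mate_contig_id in left_gains:
            rec.mate_start += left_gains[rec.mate_contig_id]


# ---------------------------------------------------------------------------
# redundancy removal


def remove_redundant(assembly: Assembly, params: Optional[Parameters] = None,
                     state: Optional[RunState] = None) -> Assembly:
    """Greedy longest-first clustering: a contig is removed when it aligns
    to an already-kept representative at identity >=
    ``redundancy_identity`` over at least 90 % of the shorter sequence."""
    import edlib
    params = params or Parameters()
    order = sorted(assembly, key=lambda c: (-len(c), c.id))
    kept: List[Contig] = []
    sketches: List[set] = []
    removed: List[Tuple[str, str]] = []
    from .simulate import _sketch  # shared k-mer sketch prefilter
    for contig in order:
        sk = _sketch(contig.sequence)
        rep = None
        for other, osk in zip(kept, sketches):
            if len(sk & osk) < 0.3 * max(1, len(sk)):
                continue
            res = edlib.align(contig.sequence, other.sequence, mode="HW",
                              task="distance")
            ed = res["editDistance"]
            if ed < 0:
                continue
            identity = 1.0 - ed / len(contig.sequence)
            if identity >= params.redundancy_identity:
                rep = other
                break
        if rep is None:
            kept.append(contig)
            sketches.append(sk)
        else:
            removed.append((contig.id, rep.id))
    if state is not None:
        for gone, rep in removed:
            state.emit("redundancy-removed", (gone,), (rep,))
            state.lineage.merge(rep, gone)
            state.lineage.merged.discard(rep)  # rep itself is unchanged
    removed_ids = {g for g, _ in removed}
    out = Assembly((Contig(c.id, c.sequence, set(c.tags))
                    for c in assembly if c.id not in removed_ids),
                   read_length=assembly.read_length)
    return out


# ---------------------------------------------------------------------------
# inner loop (clip extension)


def run_inner(state: RunState) -> None:
    """Extend incomplete contig corners from edge soft-clip consensi until
    no contig is extended or ``inner_max`` passes are done.

    Opens with the current full alignment. Later passes realign only the
    reads that can change: unmapped (or filtered) pairs, and pairs mapped
    near the edges of contigs extended in the previous pass — alignments
    of other reads against unchanged reference sequence are unchanged.
    Bookkeeping is incremental: superseded records are flagged dead and
    per-contig lists compacted on access.
    """
    params = state.params
    state.records = _full_alignment(state)
    n_pairs = state.store.n_pairs
    pair_recs: List[List[AlignmentRecord]] = [[] for _ in range(n_pairs)]
    by: Dict[str, List[AlignmentRecord]] = {}
    mapped_count = np.zeros(n_pairs, dtype=np.int8)
    external: List[AlignmentRecord] = []  # ingested records without a slot
    for r in state.records:
        if r.read_index >= 0:
            pair_recs[r.read_index].append(r)
            mapped_count[r.read_index] += 1
        else:
            external.append(r)
        by.setdefault(r.contig_id, []).append(r)
    active: Optional[Set[str]] = None  # None = every contig (first pass)

    for inner in range(1, params.inner_max + 1):
        state.inner_iter = inner
        left_gains: Dict[str, int] = {}
        extended_now: Set[str] = set()
        cids = state.assembly.ids if active is None else \
            [c for c in state.assembly.ids if c in active]
        for cid in cids:
            recs = by.get(cid)
            if not recs:
                continue
            recs = [r for r in recs if not r.dead]
            by[cid] = recs
            contig = state.assembly[cid]
            L = len(contig)
            w = params.edge_clip_window
            if not any((r.left_clip and r.start <= w) or
                       (r.right_clip and L - r.end <= w) for r in recs):
                continue
            clusters = find_edge_clip_clusters(recs, contig, params)
            best: Dict[str, object] = {}
            for cl in clusters:  # one per direction: closest to the boundary
                d = cl.position if cl.direction == "left" else L - cl.position
                cur = best.get(cl.direction)
                if cur is None or d < cur[0]:
                    best[cl.direction] = (d, cl)
            for direction in ("right", "left"):  # right first: stable coords
                if direction not in best:
                    continue
                cl = best[direction][1]
                if not cl.fragments:
                    continue
                consensus = consensus_from_clips(
                    cl.fragments, params, min_depth=params.min_clip_reads)
                if not consensus:
                    continue
                new_contig, gain = extend_with_clips(contig, cl, consensus)
                if gain <= 0:
                    continue
                state.assembly.replace(cid, new_contig)
                contig = new_contig
                state.lineage.touch(cid)
                state.emit("clip-extended", (cid,), (cid,),
                           coords=((cl.position, cl.position),),
                           seq_delta=consensus, inner=inner)
                state.ext_sides.setdefault(cid, set()).add(direction)
                extended_now.add(cid)
                if direction == "left":
                    left_gains[cid] = left_gains.get(cid, 0) + gain
        if not extended_now or inner == params.inner_max:
            break
        for cid, g in left_gains.items():
            for r in by.get(cid, ()):
                if not r.dead:
                    r.start += g
                    r.end += g
        # realignment subset: unmapped pairs plus pairs near the edges of
        # contigs that just changed
        subset: Set[int] = set(np.nonzero(mapped_count < 2)[0].tolist())
        for cid in extended_now:
            L = len(state.assembly[cid])
            for r in by.get(cid, ()):
                if r.dead or r.read_index < 0:
                    continue
                w2 = params.edge_window(r.read_length)
                if r.start < w2 or r.end > L - w2:
                    subset.add(r.read_index)
        aligner = Aligner(state.assembly, params)
        fresh = filter_alignments(
            aligner.align(state.store, sorted(subset)), params)
        for pi in subset:
            for r in pair_recs[pi]:
                r.dead = True
            pair_recs[pi] = []
            mapped_count[pi] = 0
        active = set(extended_now)
        for r in fresh:
            pair_recs[r.read_index].append(r)
            mapped_count[r.read_index] += 1
            by.setdefault(r.contig_id, []).append(r)
            active.add(r.contig_id)
    state.records = [r for lst in pair_recs for r in lst if not r.dead] + \
        [r for r in external if not r.dead]


# ---------------------------------------------------------------------------
# stage helpers


def _apply_merge(state: RunState, mo: MergeOutcome, kind: str) -> None:
    state.assembly.replace(mo.left_id, mo.merged)
    state.assembly.remove(mo.right_id)
    state.lineage.merge(mo.left_id, mo.right_id)
    state.emit(kind, (mo.left_id, mo.right_id), (mo.merged.id,),
               coords=((len(mo.merged.sequence), mo.overlap),))


def _merge_stage_clips(state: RunState) -> None:
    """Merge contigs whose fresh inner-loop extensions land on another
    contig."""
    params = state.params
    searcher: Optional[OverlapSearcher] = None
    consumed: Set[str] = set()
    for cid in list(state.ext_sides):
        if cid in consumed or cid not in state.assembly:
            continue
        for side in sorted(state.ext_sides[cid]):
            if cid in consumed:
                break
            if searcher is None:
                searcher = OverlapSearcher(state.assembly)
            mo = merge_fragments_by_clip(state.assembly, cid, side, params,
                                         searcher)
            if mo is None or mo.right_id in consumed or mo.left_id in consumed:
                continue
            _apply_merge(state, mo, "merged-clip")
            # the stage-wide index keeps the pre-merge coordinates; hits on
            # consumed contigs are skipped, and chains of merges resolve on
            # the next outer pass after a fresh realignment
            consumed |= {mo.left_id, mo.right_id}
    state.ext_sides = {}


def _orphan_and_island_stage(state: RunState) -> None:
    params = state.params
    state.records = _full_alignment(state)
    by = _group_by_contig(state.records)
    rl = state.store.read_length
    # collect islands before mutating the assembly
    islands = find_mate_islands(state.records, state.assembly, params)

    ob_counter = sum(1 for _ in state.pending_orphan_blocks)
    for cid in state.assembly.ids:
        recs = by.get(cid)
        if not recs:
            continue
        contig = state.assembly[cid]
        for cluster in find_orphan_mate_clusters(recs, contig, params):
            mates = []
            for anchor in cluster.anchors:
                slot = 2 * anchor.read_index + (1 if anchor.mate_index == 1 else 0)
                seq = state.store.seqs[slot]
                mates.append(revcomp(seq) if anchor.strand == "+" else seq)
            outcome = extend_with_orphans(contig, cluster.edge, mates,
                                          params, read_length=rl)
            if outcome.contig is not None:
                state.assembly.replace(cid, outcome.contig)
                contig = outcome.contig
                state.lineage.touch(cid)
                state.emit("orphan-extended", (cid,), (cid,),
                           coords=((0, outcome.gain),))
            elif outcome.pending_block is not None:
                ob_counter += 1
                bid = f"{cid}_ob{ob_counter}"
                if bid in state.assembly:
                    continue
                state.assembly.add(Contig(bid, outcome.pending_block,
                                          tags={"orphan-derived"}))
                state.lineage.new_contig(bid)
                state.pending_orphan_blocks.append((bid, cid, cluster.edge))
                state.emit("new-contig", (cid,), (bid,))

    consumed: Set[str] = set()
    for island in islands:
        a, b = island.contig_id, island.partner_contig_id
        if a in consumed or b in consumed:
            continue
        if a not in state.assembly or b not in state.assembly:
            continue
        mo = merge_fragments_by_islands(state.assembly, island, params,
                                       read_length=rl)
        if mo is None:
            continue
        _apply_merge(state, mo, "merged-island")
        consumed |= {mo.left_id, mo.right_id}
    # merged blocks that were pending are no longer pending
    state.pending_orphan_blocks = [
        (bid, host, edge) for bid, host, edge in state.pending_orphan_blocks
        if bid in state.assembly]


def _consensus_hits(contig: Contig, consensus: str, p: int, side: str,
                    params: Parameters, searcher: OverlapSearcher):
    """Best non-trivial hit of a clip consensus within its own contig;
    ``side`` is the consensus's anchored end ("start" for right-clip
    consensi, "end" for left-clip ones)."""
    from .fixers import _best_hit
    if len(consensus) < 11:
        return None
    hits = find_local_overlap(consensus, searcher, params)
    return _best_hit(hits, len(consensus), params.internal_identity_pct,
                     min_span_frac=0.9, exclude_anchor=(contig.id, p, side))


def _structural_stage(state: RunState) -> None:
    """One structural fix per contig, highest-priority signature first:
    translocation/inversion, then unsupported insertion, missing sequence,
    clip-based chimera split, coverage-based split."""
    params = state.params
    state.records = _full_alignment(state)
    junctions = detect_junctions(state.records) if state.junction_check else {}
    by = _group_by_contig(state.records)
    rl = state.store.read_length
    for cid in state.assembly.ids:
        recs = by.get(cid)
        if not recs:
            continue
        contig = state.assembly[cid]
        profile = compute_coverage(recs, contig)
        sites = find_internal_clip_sites(recs, contig, junctions, params,
                                         profile)
        sites.sort(key=lambda s: (-s.support_fraction, s.positions[0]))
        searcher = None
        outcome = None

        def get_searcher():
            nonlocal searcher
            if searcher is None:
                searcher = OverlapSearcher(contig)
            return searcher

        criss = [s for s in sites if s.kind == "crisscross"]
        facing = [s for s in sites if s.kind == "facing"]
        one_sided = [s for s in sites if s.kind.startswith("one_sided")]

        criss_hits = {}
        for s in criss:
            hl = _consensus_hits(contig, s.left_consensus or "",
                                 s.positions[1], "end", params,
                                 get_searcher())
            hr = _consensus_hits(contig, s.right_consensus or "",
                                 s.positions[0], "start", params,
                                 get_searcher())
            criss_hits[id(s)] = (hl, hr)

        # 1. translocation / inversion from a crisscross site
        for s in criss:
            hl, hr = criss_hits[id(s)]
            if hl is not None and hr is not None:
                outcome = fix_translocation_inversion(contig, s, hl, hr, params)
                if outcome is not None:
                    break
        # 1b. translocation / inversion split over one-sided sites
        one_sided_hits = {}
        if outcome is None and one_sided:
            sited = []
            for s in one_sided:
                direction = "left" if s.kind == "one_sided_left" else "right"
                cons = s.left_consensus or s.right_consensus or ""
                h = _consensus_hits(contig, cons, s.positions[0],
                                    "end" if direction == "left" else "start",
                                    params, get_searcher())
                one_sided_hits[id(s)] = h
                if h is not None:
                    sited.append((direction, s.positions[0], h))
            if len(sited) >= 2:
                outcome = resolve_adjacency_move(contig, sited, params)
        # 2. unsupported insertion
        if outcome is None:
            for s in facing:
                outcome = remove_unsupported_insertion(contig, s, params)
                if outcome is not None:
                    break
        # 3. missing sequence; an unbridgeable hitless crisscross is the
        # fusion point of two broken pieces and is split instead
        if outcome is None:
            for s in criss:
                hl, hr = criss_hits[id(s)]
                if hl is None and hr is None:
                    outcome = fix_missing_sequence(contig, s, params,
                                                   allow_concat=False)
                    if outcome is None:
                        outcome = split_chimera_at_crisscross(contig, s,
                                                              params)
                    if outcome is not None:
                        break
        # 4. clip-based chimera split
        if outcome is None:
            for s in one_sided:
                outcome = split_chimera_at_clip(contig, s, params,
                                                read_length=rl)
                if outcome is not None:
                    break
        # 5. coverage-based split
        if outcome is None:
            breaks = find_abrupt_breaks(profile, params, read_length=rl)
            breaks += find_gradual_breaks(profile, params, read_length=rl)
            jset = junctions.get(cid, set())
            for brk in breaks:
                if any(abs(brk.position - j) <= POOL_WINDOW for j in jset):
                    continue
                outcome = split_chimera_at_coverage(contig, brk, params)
                if outcome is not None:
                    break
        if outcome is None:
            continue
        _apply_structural(state, cid, outcome)


def _apply_structural(state: RunState, cid: str, outcome) -> None:
    params = state.params
    if isinstance(outcome, LocalFixOutcome):
        state.assembly.replace(cid, outcome.contig)
        state.lineage.touch(cid)
        state.emit(outcome.kind, (cid,), (outcome.contig.id,),
                   coords=outcome.coords, seq_delta=outcome.seq_delta)
        if outcome.routed_piece:
            piece = outcome.routed_piece
            hits = find_local_overlap(piece, outcome.contig, params) \
                if len(piece) >= 11 else []
            from .fixers import _best_hit
            dup = _best_hit(hits, len(piece), params.internal_identity_pct,
                            min_span_frac=0.9)
            if dup is None and len(piece) >= params.min_new_contig_len:
                nid = f"{cid}_ins"
                if nid not in state.assembly:
                    state.assembly.add(Contig(nid, piece,
                                              tags={"split-product"}))
                    state.lineage.new_contig(nid)
                    state.emit("new-contig", (cid,), (nid,))
        return
    if isinstance(outcome, SplitOutcome):
        outs = outcome.contigs_out
        if len(outs) == 1 and outs[0].id == cid:
            # in-place excision (self-chimera repeat removal)
            state.assembly.replace(cid, outs[0])
            state.lineage.touch(cid)
            state.emit(outcome.kind, (cid,), (cid,),
                       coords=((outcome.position, outcome.position),),
                       seq_delta=outcome.removed[0] if outcome.removed else "")
            return
        state.assembly.remove(cid)
        for c in outs:
            state.assembly.add(c)
        state.lineage.split_into(cid, [c.id for c in outs])
        state.emit(outcome.kind, (cid,), tuple(c.id for c in outs),
                   coords=((outcome.position, outcome.position),),
                   seq_delta=outcome.removed[0] if outcome.removed else "")
        if outcome.kind == "discarded" or (outcome.removed and
                                           outcome.kind != "chimera-split-clip"):
            pass  # removed sequences are recorded in the event only


# ---------------------------------------------------------------------------
# outer loop and run


def run_outer(state: RunState) -> None:
    """One outer pass (inner loop, merges, orphan/island stage, structural
    stage); updates ``contigs_with_errors``."""
    state.outer_iter += 1
    n_before = len(state.events)
    run_inner(state)
    _merge_stage_clips(state)
    _orphan_and_island_stage(state)
    _structural_stage(state)
    touched = set()
    for ev in state.events[n_before:]:
        touched.update(ev.contigs_in)
    state.contigs_with_errors = len(touched)


def _join_pending_blocks(state: RunState) -> None:
    n = state.params.n_join
    for bid, host, edge in state.pending_orphan_blocks:
        if bid not in state.assembly or host not in state.assembly:
            continue
        block = state.assembly[bid].sequence
        hseq = state.assembly[host].sequence
        joined = hseq + "N" * n + block if edge == "right" \
            else block + "N" * n + hseq
        state.assembly.replace(host, Contig(host, joined,
                                            tags=state.assembly[host].tags))
        state.assembly.remove(bid)
        state.lineage.merge(host, bid)
        state.lineage.merged -= state.lineage.origin.get(host, set())
        state.lineage.touch(host)
        state.emit("N-joined", (host, bid), (host,))
    state.pending_orphan_blocks = []


def run(assembly: Assembly, reads, params: Optional[Parameters] = None,
        out_dir: Optional[str] = None, sam_path: Optional[str] = None,
        junction_check: bool = True,
        keep_intermediates: bool = False) -> RunState:
    """Run the full corrector; returns the final :class:`RunState` (with
    ``assembly``, ``events`` and ``converged`` flag). Writes the improved
    FASTA, change log and contig map to ``out_dir`` when given."""
    params = params or Parameters()
    if len(assembly) == 0:
        raise ValueError("empty assembly")
    store = reads if isinstance(reads, ReadStore) else ReadStore(reads)
    work = assembly.copy()
    work.read_length = store.read_length
    state = RunState(assembly=work, store=store, params=params,
                     junction_check=junction_check,
                     keep_intermediates=keep_intermediates)
    if sam_path is not None:
        from .io import parse_sam
        state.sam_records = parse_sam(sam_path, work)
    if params.dedup_check:
        state.assembly = remove_redundant(state.assembly, params, state)
    while state.outer_iter < params.outer_max:
        run_outer(state)
        if state.keep_intermediates:
            state.intermediates.append(state.assembly.copy())
        if state.contigs_with_errors <= params.error_threshold:
            state.converged = True
            break
    _join_pending_blocks(state)
    if out_dir is not None:
        cmap = state.lineage.contig_map(state.assembly)
        write_reports(state.events, cmap, state.assembly, out_dir,
                      intermediates=state.intermediates or None)
    return state


def contig_map_of(state: RunState) -> ContigMap:
    return state.lineage.contig_map(state.assembly)
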