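"""Domain types shared by every stage of the corrector.

The objects here mirror the vocabulary of reference-free assembly
correction: an :class:`Assembly` of :class:`Contig` sequences being
repaired, per-read :class:`AlignmentRecord` placements, detected error
signatures (:class:`SoftClipCluster`, :class:`MateIsland`,
:class:`CoverageBreak`, :class:`InternalClipSite`), and the audit trail
(:class:`ChangeEvent`, :class:`ContigMap`) that makes every edit to the
assembly traceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from ._seq import validate_sequence

# ---------------------------------------------------------------------------
# assembly containers


class Contig:
    """One identified nucleotide sequence of the assembly being repaired."""

    __slots__ = ("id", "sequence", "tags")

    def __init__(self, id: str, sequence: str, tags: Optional[set] = None):
        validate_sequence(sequence, f"contig {id!r}")
        self.id = id
        self.sequence = sequence
        self.tags = set(tags) if tags else set()

    def __len__(self) -> int:
        return len(self.sequence)

    def __repr__(self) -> str:
        return f"Contig({self.id!r}, len={len(self.sequence)})"


class Assembly:
    """Ordered collection of contigs with unique ids."""

    def __init__(self, contigs: Iterable[Contig] = (), read_length: int = 100):
        self._contigs: Dict[str, Contig] = {}
        self.read_length = read_length
        for c in contigs:
            self.add(c)

    def add(self, contig: Contig) -> None:
        if contig.id in self._contigs:
            raise ValueError(f"duplicate contig id {contig.id!r}")
        self._contigs[contig.id] = contig

    def remove(self, contig_id: str) -> Contig:
        return self._contigs.pop(contig_id)

    def replace(self, contig_id: str, new: Contig) -> None:
        """Swap a contig in place, keeping assembly order."""
        if new.id != contig_id and new.id in self._contigs:
            raise ValueError(f"duplicate contig id {new.id!r}")
        items = [(new.id, new) if k == contig_id else (k, v)
                 for k, v in self._contigs.items()]
        self._contigs = dict(items)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._contigs

    def __getitem__(self, contig_id: str) -> Contig:
        return self._contigs[contig_id]

    def __iter__(self):
        return iter(self._contigs.values())

    def __len__(self) -> int:
        return len(self._contigs)

    @property
    def ids(self) -> List[str]:
        return list(self._contigs)

    def total_bases(self) -> int:
        return sum(len(c) for c in self)

    def copy(self) -> "Assembly":
        return Assembly(
            (Contig(c.id, c.sequence, set(c.tags)) for c in self),
            read_length=self.read_length,
        )


# ---------------------------------------------------------------------------
# alignments

# orientation classes of a read pair; "FR" is the proper inward-facing class,
# "F1F2"/"R1R2"/"RF" are the removable improper classes, "cross" marks mates
# on different contigs (kept: they are the fragmentation signature).
ORIENTATIONS = ("FR", "F1F2", "R1R2", "RF", "cross", "mate-unmapped", "unpaired")

_QUERY_OPS = frozenset("MSI")
_REF_OPS = frozenset("MDN")


class AlignmentRecord:
    """One mate's placement on a contig (0-based, half-open coordinates).

    Geometry derived from the CIGAR (read/reference lengths, end, clip
    lengths) is computed once at construction; records are created in the
    hundreds of thousands per realignment pass."""

    __slots__ = (
        "read_id", "mate_index", "contig_id", "start", "cigar", "strand",
        "mapq", "mate_mapped", "mate_contig_id", "mate_start", "orientation",
        "seq", "read_index", "read_length", "ref_length", "end",
        "left_clip", "right_clip", "dead",
    )

    def __init__(self, read_id, mate_index, contig_id, start, cigar, strand,
                 mapq, mate_mapped=False, mate_contig_id=None, mate_start=None,
                 orientation="unpaired", seq="", read_index=-1):
        self.read_id = read_id
        self.mate_index = mate_index
        self.contig_id = contig_id
        self.start = start
        self.cigar = cigar  # list of (op, length), op in {M,S,I,D,N}
        self.strand = strand
        self.mapq = mapq
        self.mate_mapped = mate_mapped
        self.mate_contig_id = mate_contig_id
        self.mate_start = mate_start
        self.orientation = orientation
        self.seq = seq  # read bases in reference orientation
        self.read_index = read_index
        self.dead = False  # superseded by a later realignment pass
        rl = refl = 0
        for op, n in cigar:
            if op in _QUERY_OPS:
                rl += n
            if op in _REF_OPS:
                refl += n
        self.read_length = rl
        self.ref_length = refl
        self.end = start + refl
        self.left_clip = cigar[0][1] if cigar and cigar[0][0] == "S" else 0
        self.right_clip = cigar[-1][1] if cigar and cigar[-1][0] == "S" else 0

    def m_spans(self) -> List[Tuple[int, int]]:
        """Reference intervals covered by M ops."""
        spans = []
        pos = self.start
        for op, n in self.cigar:
            if op == "M":
                spans.append((pos, pos + n))
            if op in _REF_OPS:
                pos += n
        return spans

    def validate(self, contig_len: Optional[int] = None) -> None:
        if self.read_length <= 0:
            raise ValueError(f"{self.read_id}: CIGAR consumes no query bases")
        if contig_len is not None and self.end > contig_len:
            raise ValueError(f"{self.read_id}: alignment overruns contig")

    def __repr__(self) -> str:
        cig = "".join(f"{n}{op}" for op, n in self.cigar)
        return (f"AlignmentRecord({self.read_id}/{self.mate_index} "
                f"{self.contig_id}:{self.start} {cig} {self.strand})")


# ---------------------------------------------------------------------------
# error signatures


@dataclass
class SoftClipCluster:
    """Outward-pointing soft-clips pooled at a contig-edge position."""

    contig_id: str
    position: int              # 0-based clip point
    direction: str             # "left" | "right": direction the clips extend
    n_reads: int
    support_fraction: float
    fragments: List[Tuple[int, str]] = field(default_factory=list)  # (offset, seq)
    read_ids: List[str] = field(default_factory=list)

    def __post_init__(self):
        if self.n_reads < 1:
            raise ValueError("cluster with no supporting reads")
        if not (0.0 < self.support_fraction <= 1.0):
            raise ValueError("support_fraction outside (0, 1]")
        if any(not s for _, s in self.fragments):
            raise ValueError("empty clip fragment")


@dataclass
class MateIsland:
    """Edge reads on one contig whose mates cluster on a single partner."""

    contig_id: str
    edge: str                  # "left" | "right"
    span: Tuple[int, int]
    read_ids: List[str]
    partner_contig_id: str
    partner_edge: str = ""
    partner_span: Tuple[int, int] = (0, 0)

    def __post_init__(self):
        if not self.read_ids:
            raise ValueError("island with no reads")


@dataclass
class InternalClipSite:
    """Soft-clip pattern away from the contig ends (chimera / local error)."""

    contig_id: str
    kind: str                  # one_sided_left | one_sided_right | crisscross | facing
    positions: Tuple[int, ...]
    left_consensus: Optional[str] = None
    right_consensus: Optional[str] = None
    support_fraction: float = 1.0
    n_reads: int = 1


@dataclass
class CoverageBreak:
    contig_id: str
    position: int              # break between position-1 and position
    left_depth: float
    right_depth: float
    mode: str = "abrupt"       # "abrupt" | "gradual"


class CoverageProfile:
    """Per-base read depth over one contig (M ops only)."""

    __slots__ = ("contig_id", "depth")

    def __init__(self, contig_id: str, depth: np.ndarray):
        if np.any(depth < 0):
            raise ValueError("negative depth")
        self.contig_id = contig_id
        self.depth = depth

    def __len__(self) -> int:
        return len(self.depth)


@dataclass
class OverlapHit:
    """A local alignment hit of a query against an assembly contig."""

    query_range: Tuple[int, int]
    subject_contig_id: str
    subject_range: Tuple[int, int]
    strand: str
    identity_pct: float
    n_gaps: int
    score: float               # (identity_pct / query length) * 100

    def __post_init__(self):
        if self.query_range[0] >= self.query_range[1]:
            raise ValueError("empty query range")
        if self.subject_range[0] >= self.subject_range[1]:
            raise ValueError("empty subject range")


# ---------------------------------------------------------------------------
# audit trail

EVENT_KINDS = (
    "redundancy-removed", "clip-extended", "orphan-extended", "N-joined",
    "merged-clip", "merged-island", "chimera-split-clip",
    "chimera-split-coverage", "self-chimera-removed", "missing-inserted",
    "insertion-removed", "translocation-fixed", "inversion-fixed",
    "new-contig", "discarded",
)


@dataclass
class ChangeEvent:
    """One edit applied to the assembly; streams are append-only and ordered."""

    outer_iter: int
    inner_iter: Optional[int]
    kind: str
    contigs_in: Tuple[str, ...]
    contigs_out: Tuple[str, ...]
    coords: Tuple[Tuple[int, int], ...] = ()
    seq_delta: str = ""
    seq: int = 0               # sequence number within the run

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.contigs_in:
            raise ValueError("event with no input contigs")


MAP_RELATIONS = ("unchanged", "extended", "merged-into", "split-into", "removed")


@dataclass
class ContigMap:
    """Initial contig id -> [(final contig id, relation)] over a whole run."""

    mapping: Dict[str, List[Tuple[str, str]]]

    def finals_of(self, initial_id: str) -> List[str]:
        return [f for f, rel in self.mapping.get(initial_id, ()) if rel != "removed"]


# ---------------------------------------------------------------------------
# parameters

_PCT_FIELDS = (
    "clip_support_pct", "max_orphan_clip_pct", "min_orphan_extension_pct",
    "seed_identity_pct", "extend_identity_pct", "island_overlap_score",
    "island_edge_slack_pct", "internal_identity_pct", "abrupt_cov_pct",
    "gradual_cov_pct",
)


@dataclass
class Parameters:
    """All tunable thresholds of the corrector, with their default values.

    Counts are in reads or bases, percentages in [0, 100]; ``read_length``
    multiples (``realign_edge_window``, ``end_ignore``) are resolved by the
    pipeline once the read length is known.
    """

    edge_clip_window: int = 25          # bases from a boundary for edge clips
    min_clip_reads: int = 3             # reads supporting a clip cluster
    clip_support_pct: float = 75.0      # % of covering reads that must clip
    realign_edge_window: Optional[int] = None  # default 2 x read_length
    min_orphan_reads: int = 3           # edge reads with unmapped mates
    max_orphan_clip_pct: float = 25.0   # max % of anchor read soft-clipped
    min_orphan_extension_pct: float = 50.0  # min gain, % of read length
    n_join: int = 5                     # Ns joining unplaced orphan blocks
    seed_len: int = 25                  # merge seed taken from an extension
    seed_identity_pct: float = 100.0
    extend_identity_pct: float = 90.0
    max_gaps: int = 0
    min_island_reads: int = 5
    min_island_overlap: int = 10        # bases
    island_overlap_score: float = 90.0
    island_edge_slack_pct: float = 5.0  # % of read length
    min_internal_consensus: int = 10    # bases
    internal_identity_pct: float = 90.0
    min_new_contig_len: int = 200       # bases
    abrupt_cov_pct: float = 80.0
    gradual_window: int = 100           # bp
    gradual_cov_pct: float = 80.0
    end_ignore: Optional[int] = None    # default read_length
    min_mapq: int = 20                  # Phred
    redundancy_identity: float = 0.95   # fraction
    inner_max: int = 30
    outer_max: int = 100
    error_threshold: int = 0            # contigs
    gradual_check: bool = False
    dedup_check: bool = True

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None or isinstance(v, bool):
                continue
            if v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")
        for name in _PCT_FIELDS:
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if not (0 <= self.redundancy_identity <= 1):
            raise ValueError("redundancy_identity must be a fraction in [0, 1]")

    def edge_window(self, read_length: int) -> int:
        return self.realign_edge_window if self.realign_edge_window is not None \
            else 2 * read_length

    def end_ignore_bases(self, read_length: int) -> int:
        return self.end_ignore if self.end_ignore is not None else read_length


def default_parameters() -> Parameters:
    """A fresh :class:`Parameters` object with every field at its default."""
    return Parameters()
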