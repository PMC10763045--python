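"""Readers and writers: FASTA (assembly), FASTQ (reads), SAM (alignments),
and the tool's TSV reports (change log and contig map).

Only plain-text formats are handled; gzipped FASTA/FASTQ are transparently
decompressed. SAM ingestion goes through pysam so externally produced
alignments (any soft-clip-aware aligner) can be dropped into the pipeline.
"""

from __future__ import annotations

import gzip
import os
from typing import IO, Iterator, List, Optional, Tuple

import pysam
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core import (AlignmentRecord, Assembly, ChangeEvent, Contig, ContigMap)

FASTA_WRAP = 80


class ReadPair:
    """A paired-end fragment's two mates (sequences 5'->3' as sequenced)."""

    __slots__ = ("read_id", "seq1", "seq2", "qual1", "qual2")

    def __init__(self, read_id, seq1, seq2, qual1=None, qual2=None):
        if qual1 is not None and len(qual1) != len(seq1):
            raise ValueError(f"{read_id}: quality/sequence length mismatch")
        if qual2 is not None and len(qual2) != len(seq2):
            raise ValueError(f"{read_id}: quality/sequence length mismatch")
        self.read_id = read_id
        self.seq1 = seq1
        self.seq2 = seq2
        self.qual1 = qual1
        self.qual2 = qual2


def _open_text(path) -> IO[str]:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, read_length: int = 100) -> Assembly:
    """Load an assembly; the header token before the first whitespace is the
    contig id, sequences are uppercased. Duplicate ids and empty records are
    hard errors."""
    assembly = Assembly(read_length=read_length)
    with _open_text(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            cid = header.split()[0] if header.split() else ""
            if not cid:
                raise ValueError(f"{path}: record with empty id")
            if not seq:
                raise ValueError(f"{path}: empty sequence for record {cid!r}")
            if cid in assembly:
                raise ValueError(f"{path}: duplicate id {cid!r}")
            assembly.add(Contig(cid, seq.upper()))
    return assembly


def write_fasta(assembly: Assembly, path, wrap: int = FASTA_WRAP) -> None:
    with open(path, "w") as fh:
        for contig in assembly:
            fh.write(f">{contig.id}\n")
            s = contig.sequence
            for i in range(0, len(s), wrap):
                fh.write(s[i:i + wrap] + "\n")


# ---------------------------------------------------------------------------
# FASTQ


def _strip_mate_suffix(name: str) -> str:
    tok = name.split()[0]
    if len(tok) > 2 and tok[-2] == "/" and tok[-1] in "12":
        return tok[:-2]
    return tok


def read_fastq_pair(path1, path2) -> Iterator[ReadPair]:
    """Stream read pairs from two FASTQ files in file order.

    Record counts must match and ids must pair up after stripping a ``/1``,
    ``/2`` or whitespace suffix.
    """
    with _open_text(path1) as fh1, _open_text(path2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        k = 0
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                raise ValueError(
                    f"paired FASTQ files differ in record count (at record {k})")
            id1 = _strip_mate_suffix(r1[0])
            id2 = _strip_mate_suffix(r2[0])
            if id1 != id2:
                raise ValueError(
                    f"read id mismatch at record {k}: {id1!r} vs {id2!r}")
            yield ReadPair(id1, r1[1].upper(), r2[1].upper(), r1[2], r2[2])
            k += 1


def write_fastq_pair(pairs, path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = p.qual1 or "I" * len(p.seq1)
            q2 = p.qual2 or "I" * len(p.seq2)
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{q2}\n")


# ---------------------------------------------------------------------------
# SAM ingestion

_CIGAR_OPS = "MIDNSHP=X"


def _cigar_from_pysam(read: "pysam.AlignedSegment") -> List[Tuple[str, int]]:
    cig = []
    for op, n in read.cigartuples or ():
        c = _CIGAR_OPS[op]
        if c in "HP":
            continue  # hard clips/padding consume nothing we track
        if c in "=X":
            c = "M"
        if c not in "MSIDN":
            raise ValueError(f"unsupported CIGAR op {c!r}")
        if cig and cig[-1][0] == c:
            cig[-1] = (c, cig[-1][1] + n)
        else:
            cig.append((c, n))
    return [(op, n) for op, n in cig]


def _orientation(strand1, start1, end1, strand2, start2, end2) -> str:
    if strand1 == strand2:
        return "F1F2" if strand1 == "+" else "R1R2"
    # opposite strands on the same contig: FR (facing) or RF (tail-to-tail)
    if strand1 == "+":
        fs, rs = start1, start2
    else:
        fs, rs = start2, start1
    return "FR" if fs <= rs else "RF"


def classify_pair(rec1: Optional[AlignmentRecord],
                  rec2: Optional[AlignmentRecord]) -> None:
    """Fill mate linkage and orientation class on a pair of records
    (either may be None for an unmapped mate)."""
    for a, b in ((rec1, rec2), (rec2, rec1)):
        if a is None:
            continue
        if b is None:
            a.mate_mapped = False
            a.mate_contig_id = None
            a.mate_start = None
            a.orientation = "mate-unmapped"
        else:
            a.mate_mapped = True
            a.mate_contig_id = b.contig_id
            a.mate_start = b.start
    if rec1 is None or rec2 is None:
        return
    if rec1.contig_id != rec2.contig_id:
        rec1.orientation = rec2.orientation = "cross"
        return
    ori = _orientation(rec1.strand, rec1.start, rec1.end,
                       rec2.strand, rec2.start, rec2.end)
    rec1.orientation = rec2.orientation = ori


def parse_sam(path, assembly: Assembly) -> List[AlignmentRecord]:
    """Ingest a SAM file of paired-end alignments against ``assembly``.

    Secondary/supplementary lines are skipped; orientation classes are
    derived from FLAG and mate fields. Unknown reference names and malformed
    CIGARs are hard errors.
    """
    records: List[AlignmentRecord] = []
    by_read = {}
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as sam:
        for ref in sam.references:
            if ref not in assembly:
                raise ValueError(f"SAM reference {ref!r} not in assembly")
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name not in assembly:
                raise ValueError(
                    f"SAM reference {read.reference_name!r} not in assembly")
            cigar = _cigar_from_pysam(read)
            if not cigar:
                raise ValueError(f"{read.query_name}: missing CIGAR")
            mate_index = 2 if read.is_read2 else 1
            rec = AlignmentRecord(
                read_id=_strip_mate_suffix(read.query_name),
                mate_index=mate_index,
                contig_id=read.reference_name,
                start=read.reference_start,
                cigar=cigar,
                strand="-" if read.is_reverse else "+",
                mapq=read.mapping_quality,
                seq=(read.query_sequence or "").upper(),
            )
            rec.validate(len(assembly[rec.contig_id]))
            records.append(rec)
            by_read.setdefault(rec.read_id, {})[mate_index] = rec
            if read.is_paired and read.mate_is_unmapped:
                rec.orientation = "mate-unmapped"
    for mates in by_read.values():
        if len(mates) == 2:
            classify_pair(mates.get(1), mates.get(2))
    return records


# ---------------------------------------------------------------------------
# reports

CHANGELOG_HEADER = ("outer_iter", "inner_iter", "kind", "contigs_in",
                    "contigs_out", "coords", "seq_delta_len")
MAP_HEADER = ("initial_id", "final_id", "relation")


def write_change_log(events: List[ChangeEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CHANGELOG_HEADER) + "\n")
        for ev in events:
            coords = ";".join(f"{a}-{b}" for a, b in ev.coords)
            fh.write("\t".join([
                str(ev.outer_iter),
                "" if ev.inner_iter is None else str(ev.inner_iter),
                ev.kind,
                ",".join(ev.contigs_in),
                ",".join(ev.contigs_out),
                coords,
                str(len(ev.seq_delta)),
            ]) + "\n")


def write_contig_map(cmap: ContigMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MAP_HEADER) + "\n")
        for initial, dests in cmap.mapping.items():
            for final, relation in dests:
                fh.write(f"{initial}\t{final}\t{relation}\n")


def read_contig_map(path) -> ContigMap:
    mapping = {}
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != MAP_HEADER:
            raise ValueError(f"{path}: not a contig map TSV")
        for line in fh:
            initial, final, relation = line.rstrip("\n").split("\t")
            mapping.setdefault(initial, []).append((final, relation))
    return ContigMap(mapping)


def write_reports(events: List[ChangeEvent], cmap: ContigMap,
                  assembly: Assembly, out_dir,
                  intermediates: Optional[List[Assembly]] = None) -> None:
    """Write the improved FASTA, per-iteration intermediate FASTAs, the TSV
    change log and the TSV contig map. Deterministic for identical inputs."""
    os.makedirs(out_dir, exist_ok=True)
    write_fasta(assembly, os.path.join(out_dir, "improved.fa"))
    write_change_log(events, os.path.join(out_dir, "change_log.tsv"))
    write_contig_map(cmap, os.path.join(out_dir, "contig_map.tsv"))
    for i, inter in enumerate(intermediates or (), start=1):
        write_fasta(inter, os.path.join(out_dir, f"iteration_{i:03d}.fa"))
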