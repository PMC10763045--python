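# Methods

This note documents the correction model, the numerical choices behind
it, the synthetic benchmark, and the limits of what passing tests
demonstrate.

## Correction model

The corrector treats the supertranscriptome assembly as the hypothesis
and the paired-end reads as the evidence. Reads are aligned to the
current assembly; systematic disagreement patterns (not attributable to
sequencing error) identify assembly errors, and each pattern has a
deterministic repair. The assembly is edited and the loop repeats until a
full pass finds nothing to change.

**Iteration structure.** One outer pass consists of: (1) the inner
extension loop — align, collect outward soft-clip clusters at contig
edges, extend each end with the clip consensus, realign and repeat until
no end grows (cap `inner_max`, default 30); (2) clip-based merging — the
terminal 25 bases of each fresh extension are searched across the whole
assembly; a full-length perfect hit on another contig seeds an overlap
that is grown at 90 % running identity and, when terminal on both sides,
merged; (3) orphan-mate extension and island merging after a full
realignment — unmapped mates of outward edge reads are re-assembled
greedily and stitched over an edge overlap (gain >= 50 % of read length),
or added as pending contigs that are joined with 5 Ns at the end of the
run if never merged; linked read/mate islands on two contigs merge them
across a terminal overlap (>= 10 bases, >= 90 % score, within 5 % of read
length of the island edge); (4) structural repairs after another full
realignment — translocations/inversions, unsupported insertions, missing
sequence, and chimera splits, at most one structural fix per contig per
pass (an edit invalidates the other sites' coordinates; they are
re-detected next pass). Outer passes repeat until a pass touches zero
contigs (threshold `error_threshold`, default 0) or `outer_max` (default
100) is reached. Optional redundancy removal (greedy longest-first
clustering at 0.95 identity over the shorter sequence) runs once before
iteration.

**Signature semantics.** A clip cluster's support fraction is
`clipped / (clipped + spanning)`, where a spanning read runs at least 10
bases past the clip point on both sides. Reads that merely abut the
point carry no vote: at a genuine junction the opposing side's reads
start exactly there, and counting them as contradicting evidence would
veto every junction whose alignments extended a few bases past it by
chance matches (a 1/4-per-base event). The same chance-match physics
motivates three other choices: clip points within 5 bases pool into one
cluster at the modal point; the insertion fixer probes cut-point shifts
of up to 8 bases against the clip consensi; and the missing-sequence
fixer rebuilds the junction by bridging `contig[:p] + right-consensus`
with `left-consensus + contig[p:]` across their maximal >= 90 %-identity
overlap, which absorbs overshot clip points without explicit bookkeeping
(and can also remove a few junction bases left over from an earlier
approximate repair — emitted as an `insertion-removed` event).

**Distinguishing the crisscross cases.** At a crisscross site (left- and
right-clips at one point), the two consensus sequences are searched
within the contig (flank-trivial matches at the clip point itself are
excluded). Both hit elsewhere: the hits bound a relocated block, which is
excised and reinserted at the clip point, reverse-complemented for a
reverse-strand hit (inversion). Neither hits and the consensi bridge:
missing sequence, inserted at the junction. Neither hits and the consensi
cannot be bridged: the junction fuses two unrelated transcript pieces —
a false chimera — and the contig is split there, each piece keeping the
bases its own clip evidence supports (the pieces may share the few
junction bases alignments extended over by chance). Relocations whose
signature is split over two one-sided sites (read pairs crossing a moved
block's boundary are removed by orientation filtering, which can starve
one clip direction) are recovered by pairing a *bypass* site (forward hit
strictly on the anchor side of its clip point) with a *destination* site
whose hit lands on the matching block boundary.

**Split-piece routing.** The smaller piece of any split is re-searched
against the larger: a >= 90 %-identity, >= 90 %-span hit marks a
self-chimera duplicate (piece dropped); otherwise pieces of >= 200 bases
become new contigs and shorter ones are discarded (logged).

## The built-in aligner

Each mate is placed by exact 15-mer seeding (six seeds per strand) and a
maximum-scoring-segment scan along each candidate diagonal (match +1,
mismatch −2) — Smith–Waterman restricted to a single diagonal. Unextendable
ends become soft-clips; clipped tails shorter than 3 bases are absorbed as
jitter unless they sit on a contig boundary, where the reference simply
ends and a 1–2 base overhang is genuine evidence. Gapless placement is
the correct model here: Illumina error is substitution-dominated and
every structural discrepancy the corrector looks for expresses itself as
a clip, not as a small indel. Gap handling lives in the contig-vs-contig
overlap search instead (and the default there ignores gapped hits
outright, so that search is gapless too; its hits are ranked by raw
segment score, with the identity-per-query-length composite as
tie-break). mapq is `40 × (1 − second_best/best)` capped at 60, where
`second_best` counts only placements competing for the same read bases —
a read split across a true junction is not ambiguous, its two halves
simply belong to different loci. Records with mapq < 20 and both mates of
F1F2, R1R2 and tail-to-tail RF pairs are dropped; pairs split across
contigs and reads with unmapped mates are kept, as they are fragmentation
and incompleteness signatures. Pre-computed SAM alignments may be
supplied; they drive the first alignment pass, after which the built-in
aligner takes over for realignment (iterative correction requires
realigning against edited contigs).

Inside the inner loop only reads that can change are realigned: unmapped
or filtered pairs, and pairs near the edges of contigs extended in the
previous pass. Alignments of other reads against unchanged reference
sequence are unchanged by construction, so this is a pure optimization.

## Consensus and local assembly

Clip consensi are per-column majority votes over the fragment stack
anchored at the modal clip point (the stack's layout is fully determined
by the clip offsets, so no assembly step is needed); tied columns emit
the covering IUPAC code, and columns below `min_clip_reads` coverage end
the consensus — a thin single-read tail would write its sequencing errors
into the contig. IUPAC codes are retained downstream, and all identity
computations treat an ambiguity code as matching any base it denotes, so
later iterations still map reads across consensus-derived sequence.
Orphan mates are assembled with a greedy overlap-layout-consensus
procedure (longest qualifying suffix–prefix overlap first, >= 16 bases at
>= 95 % identity, either strand) that accumulates per-column counts so the
merged consensus is a majority vote rather than first-sequence-wins.

## Parameters

All thresholds live in one `Parameters` object; the defaults are the
method's standard operating point: edge clip window 25 bases, >= 3
clipped reads at >= 75 % support, realignment edge window 2 × read
length, >= 3 orphan anchors with < 25 % clipped bases and a minimum
stitched gain of 50 % of read length, 5 Ns for unplaced orphan blocks,
25-base merge seeds at 100 % identity extended at 90 %, zero gaps
allowed, >= 5-read islands with >= 10-base overlaps at >= 90 % score
within 5 % of read length of the island edge, >= 10-base internal
consensi at >= 90 % identity, 200-base minimum for new contigs, >= 80 %
abrupt coverage change outside one read length from the ends (the
100 bp sliding-window variant exists but is off by default: coverage
fluctuation makes it false-positive-prone), mapq >= 20, 0.95 redundancy
identity, inner cap 30, outer cap 100, convergence at zero erroneous
contigs.

## Synthetic benchmark

The generator draws i.i.d. uniform-GC contigs (default 1–3 kb, always
> 500 bp) rejected for pairwise similarity (no two share > 95 %
identity), so every k-mer is effectively unique and read placement is
unambiguous except where an error makes it genuinely ambiguous. The
injector plants one error per contig: terminal truncations of 10–30 % per
affected side (left, right or both); fragmentation cuts at 40–60 % of
length; chimeras fusing the prefix of one transcript (cut at 40–60 %) to
the suffix of another, both originals removed; internal deletions and
random-sequence insertions of 30–70 % of read length; translocated or
reverse-complemented blocks of 20–30 % of contig length moved at least
two read lengths away. The read simulator emits FR pairs with fragment
lengths uniform on 250–500 bp, uniform expression (fragments proportional
to contig length; a per-contig abundance vector exists to exercise
coverage-based chimera detection), substitution-only errors at 0.5 % per
base (Illumina error is substitution-dominated and the corrector's
signatures are clip-based, so indel noise would only obscure the
measurement), and constant Q30 qualities. Everything is bit-reproducible
per seed.

The scorer grades an error fixed if: >= 90 % of removed bases are back in
place (terminal truncations, internal deletions — counted on an infix
alignment of the original against the mapped final contig); the final
sequence equals the original exactly (fragmentation, translocation,
inversion, insertion removal; IUPAC-compatible equality counts); or both
fused pieces are separated cleanly — each fully contained in its own
final contig and the fusion junction absent everywhere (chimeras; the
fused pieces rather than the full source transcripts are the recovery
target, since the benchmark removes the source transcripts and no read
evidence for a complete reconstruction exists at finite coverage).
Calibration invariants: the unrepaired assembly scores 0 % and the
pre-error assembly under the identity mapping scores 100 %, per type.

**Problem sizes.** The acceptance benchmark uses 400 contigs, 50 errors
per type and 200k read pairs (~50× coverage); the test suite runs the
same benchmark once plus oracle comparisons at 200–300 bp scale. These
sizes put every signature deep into its detectable regime while keeping a
full run in minutes on one CPU.

## What the benchmark does not show

* **Real assemblies.** Synthetic contigs have no shared exons, paralogs,
  repeats or splice structure, so multi-mapping ambiguity is absent
  except where injected. The splice-junction exclusion is exercised only
  by unit tests (the simulator produces reads directly from
  supertranscripts, which have no junction-spanning clips).
* **Coverage dependence.** At ~50× the do-no-harm property holds exactly
  (zero events on clean data). Below ~20×, chance internal
  zero-coverage holes read as chimeric junctions and can split intact
  contigs; conversely thin clip stacks slow or stall terminal recovery.
  The error-fixing thresholds are read-count thresholds, and everything
  scales with depth.
* **Terminal bases.** The very last bases of a transcript are covered
  only by fragments ending exactly there (expected ~0.2 reads per end at
  50×), so no method can recover a fully deleted terminal base from read
  evidence; the >= 90 % recovery criterion for truncations reflects
  this.
* **Chance-match jitter.** Alignments extend past a true junction when
  the next base matches by chance (P = 1/4 per base). The bridge-merge,
  shift-probing and overlap-preserving-split mechanisms absorb this in
  the common cases, but a residual off-by-one occasionally survives as a
  single-base substitution after repair — visible in the inversion and
  translocation recovery rates sitting slightly below 100 %.

## Known limitations

Orientation filtering removes read pairs that straddle a relocated
block's boundary, which is what splits some inversion signatures over two
one-sided sites; the adjacency-pair resolution recovers most but not all
of these. The island-merge path requires a physical sequence overlap, so
fragment pairs with zero overlap merge only via the clip-extension route.
Merging never reverse-complements a contig: fragments assembled in
opposite orientations are out of scope. The redundancy clusterer is
greedy and alignment-based (edlib) with a k-mer sketch prefilter; it
approximates, not reproduces, any particular external clustering tool.
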