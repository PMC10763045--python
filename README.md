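# strefine

Reference-free correction of de novo supertranscriptome assemblies using
paired-end RNA-seq evidence.

## The problem

Studies of organisms without a reference genome start from a de novo
transcriptome or supertranscriptome assembly — one contig per gene built
directly from RNA-seq reads. Assemblers working from short reads under
varying transcript abundance produce characteristic errors: redundant
contigs, incomplete supertranscripts (missing terminal exons), fragmented
supertranscripts (one gene split over several contigs), false chimeras
(two genes fused into one contig), and local mis-assemblies (missing
sequence, unsupported insertions, translocations, inversions). Existing
correction tools lean on BLAST against a related species, which fails
exactly where de novo assembly matters most.

`strefine` repairs these errors using only the paired-end reads that built
the assembly. When reads are mapped back to their own assembly, each error
type leaves a diagnostic footprint:

| Signature | Error it marks |
|---|---|
| Outward soft-clips clustered at a contig edge | incomplete supertranscript |
| Edge reads whose mates are unmapped | missing flanking sequence |
| Clip consensus from one contig matching another | fragmentation |
| Read/mate islands on two different contigs | fragmentation |
| One-sided internal soft-clip cluster | chimeric junction |
| Abrupt per-base coverage break | chimeric junction (expression change) |
| Crisscross internal clips (pointing apart) | missing sequence, translocation, inversion |
| Facing internal clips (pointing together) | unsupported insertion |

The corrector runs as two nested iterations: an inner loop that grows
incomplete contig ends from soft-clip consensus sequences (realigning only
edge reads between passes), and an outer loop that, after each inner loop,
merges fragmented contigs, extends ends with re-assembled orphan mates,
splits false chimeras and repairs local mis-assemblies, each stage followed
by a fresh realignment. Iteration stops when a full pass changes nothing
(or a configurable cap is reached). Every edit is logged to a change log,
and a contig map records how each input contig relates to the final
assembly.

All stages are backed by built-in primitives — a seed-and-extend read
aligner that reports soft-clips and placement-uniqueness mapq, a
column-majority consensus caller (IUPAC codes at ties), a greedy
overlap-layout-consensus assembler for orphan mates, and an exact-word
seeded local overlap search — so a correction run is a single in-process
computation with no external aligner or assembler required (pre-computed
SAM alignments can be supplied for the first pass).

The package also ships the benchmark harness used to validate it: a
synthetic supertranscriptome generator, an injector for the seven error
types with field-standard size ranges, a paired-end read simulator, and a
recovery scorer that grades each injected error as fixed or not.

## Worked example

Generate a small benchmark (40 synthetic supertranscripts, 3 errors of
each of the seven types, 20k read pairs), correct it, and score recovery:

```
$ strefine simulate --n-contigs 40 --errors-per-type 3 --n-pairs 20000 \
      --seed 7 --out bench
wrote benchmark with 21 injected errors to bench

$ strefine run --assembly bench/erroneous.fa --r1 bench/reads_1.fq \
      --r2 bench/reads_2.fq --out improved --no-dedup --no-junction-check
outer iterations: 4  events: 171  contigs: 40

$ strefine evaluate --truth bench/truth.tsv \
      --improved improved/improved.fa --map improved/contig_map.tsv
error_type      n_errors  n_fixed  pct_fixed
incomplete      3         3        100.0
fragmented      3         3        100.0
chimera         3         3        100.0
missing_seq     3         3        100.0
unsupported_insertion  3  2        66.7
translocation   3         3        100.0
inversion       3         3        100.0
```

The run converged in 4 outer iterations after applying 171 edits; 20 of
the 21 injected errors were repaired to the scorer's standard (terminal
truncations and internal deletions need >= 90 % of the removed bases back
in place; fragmentations, translocations, inversions and insertions need
the original sequence restored exactly; chimeras need both fused pieces
cleanly separated). `improved/change_log.tsv` lists every edit —

```
outer_iter  inner_iter  kind           contigs_in  contigs_out  coords     seq_delta_len
1           1           clip-extended  st0011_p1   st0011_p1    1055-1055  46
1           1           clip-extended  st0011_p2   st0011_p2    0-0        41
```

— here the first inner pass extended the two halves of a fragmented
supertranscript by 46 and 41 bases toward each other; a later merge event
joins them. `--no-dedup` and `--no-junction-check` are appropriate for
simulated reads (no redundant input contigs, no splice junctions); both
stages are on by default for real data.

The library mirrors the CLI: `strefine.pipeline.run()` takes an
`Assembly` and read pairs and returns the run state with the improved
assembly, event stream and convergence flag;
`strefine.simulate` exposes the generator, injector, read simulator and
`score_recovery`.

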