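# Methods

## The problem

Variant-calling workflows sandwich several SAM-file *preparation steps*
between the aligner and the analysis tool: removing unmapped reads,
filtering on mapping quality, replacing read groups, reordering or
filtering the sequence dictionary, coordinate sorting, and PCR duplicate
marking. Standard practice chains one command-line tool invocation per
step, which re-reads, re-parses and re-writes the whole file at every
step. samprep executes an arbitrary pipeline of such steps in a **single
pass** over the records, and guarantees the result is byte-identical to
running the steps one at a time.

## Three-level filters and the execution model

Every step is a *three-level filter*:

1. a **header stage**, run once per execution, which may modify the header
   and returns a worker factory (or nothing, for header-only steps);
2. a **worker stage**, run once per worker, which sets up worker-local
   state and returns the record stage;
3. a **record stage**, run once per record, which may modify the record in
   place and returns keep/drop.

The engine streams records through the record stages of all steps in
order, short-circuiting on the first drop. Steps with cross-record state
register a *finalize hook* that runs after the last record: duplicate
marking needs end-of-stream knowledge to tell complete pairs from reads
whose mate is missing, so per-record verdicts alone cannot be final.
After finalization the optional whole-set operation (sorting) reorders the
surviving records in memory, and output steps (duplicate removal) are
applied while writing. Everything runs in memory; there is no external
sort or disk spilling, so input size is bounded by RAM.

**Parallelism is a contract, not a mechanism.** The engine promises that
output is byte-identical for every worker count. The implementation
assigns records round-robin to per-worker record-stage instances and
processes them in input order on one thread; the shared duplicate tables
resolve every collision with a deterministic preference (below), so a
genuinely threaded scheduler satisfying the same commutativity would
produce the same bytes. This keeps the correctness argument (and its
tests) independent of any scheduler.

## Byte fidelity

Pipelines are validated by textual comparison of outputs, so the parser
and serializer must be the identity on untouched content: header line
order, attribute order within header lines, optional-field order, unknown
and duplicate tags are all preserved verbatim, and optional-field values
are never interpreted beyond what a step's contract requires. This is why
the package carries its own SAM text layer rather than normalizing through
a binding.

## Duplicate marking

Duplicate scoring and grouping follow Picard's conventions:

* **Score** = sum of phred base qualities ≥ 15 (`"*"` quality scores 0);
  a pair's score is the sum of both ends. Centralized in
  `markdup.dup_score` so it can be swapped.
* **Key** = (library, reference index, unclipped 5′ coordinate, strand).
  The unclipped coordinate counts both soft and hard clips, so
  differently-clipped copies of one molecule collide. The library comes
  from the record's RG tag via the @RG line's LB attribute; records
  without one fall into the library `"unknown"`, and duplicates are only
  detected within a library.
* **Roles**: unmapped, secondary and supplementary records are exempt
  (never marked, never able to mark). A record is a *pair end* only when
  its flag claims a mapped mate **and** the mate is actually present in
  the input; otherwise it is a *fragment* (unpaired, mate unmapped, or
  mate missing).
* **Semantics**: among complete pairs sharing a pair key exactly the best
  pair is unmarked; among fragments sharing an end key exactly the best is
  unmarked unless any complete pair has an end there, in which case all
  fragments at that key are marked; pair ends are never marked because of
  fragments.

Instead of Picard's three passes (sort, group/select, rewrite), a
memoization table keeps the best record (or pair) per key as the single
pass progresses: each collision marks the worse contender immediately and
keeps the better one. Mates are matched through a pending map keyed by
qname and scored when the second mate arrives; the finalize hook
downgrades never-matched pending reads to fragments and replays them
through the fragment table.

**Tie-break.** Higher score wins; on equal scores the lexicographically
smaller qname wins (for pairs, the pair's qname). A strict
better-score-only rule would keep whichever record happened to arrive
first — order- and scheduler-dependent — so the strengthened ordering is
what makes the marked set a pure function of the record multiset. Marking
clears all pre-existing 0x400 bits first and touches no other field.

Two primary records with the same qname and the same first/second-of-pair
flags are rejected as malformed input rather than silently paired.

## Split by genomic region and merge

A region is one sequence-dictionary contig (finer windowing is
unsupported). The splitter writes one file per contig, one for *spanning
pairs* (complete pairs whose ends map to different contigs), and one for
unmapped records; every file carries the full original header. Both ends
of a spanning pair go to the spanning file, so the pair is complete where
it is scored; each end is additionally *copied* into its own region's
file with the provenance tag `sp:i:1`. Duplicate marking treats an
`sp`-tagged record purely as "a pair end exists at this key": it asserts
the pair-trumps-fragment rule for co-located fragments but never competes
itself. Merge discards all `sp`-tagged copies (the spanning file's
version of each record is authoritative, whatever flags a copy acquired),
verifies the record count against the split manifest, and writes the
union coordinate-sorted.

Two cases need care and drove design choices:

* a flag-paired read whose mate is missing from the file is a fragment,
  so the splitter determines mate presence before routing and sends such
  reads to their region file even when RNEXT names another contig —
  otherwise their fragment competition would happen in the wrong file;
* whether a pair is "spanning" depends only on the two ends' contigs,
  never on processing order.

With these rules, per-file marking + merge provably equals whole-file
marking: pairs sharing a pair key always land in the same file (equal
keys imply equal contig pairs), fragments sharing an end key land in the
same region file, and every complete pair end is represented (in person
or by copy) wherever it must trump fragments.

## Sorting

Coordinate order is (dictionary index of RNAME, POS) with a stable sort,
so ties keep input order and results are reproducible across worker
counts. Records with RNAME `"*"` sort last; placed-unmapped records (0x4
set, coordinates borrowed from the mate) sort at their stated coordinate
as samtools and Picard do. Queryname order is plain lexicographic.

## Concrete steps

* `filter_unmapped` drops records with flag 0x4 set.
* `filter_erroneous_mapping(min_mapq, require_consistent_flags)` — the
  mapping-score/flag filter is realized as an explicit, configurable
  predicate (defaults `min_mapq=0`, consistency check on): mapped records
  below the MAPQ threshold are dropped, as are records whose flag and
  RNAME/POS contradict each other in either direction.
* `replace_read_groups` replaces all @RG lines with one spec and points
  every record's RG tag at it; nothing else is touched.
* `replace_reference_sequences` installs a new dictionary, drops records
  on removed contigs, and for surviving records whose mate's contig was
  removed sets RNEXT `"*"`, PNEXT 0, TLEN 0 and the mate-unmapped bit —
  the least surprising convention. If the relative order of retained
  contigs changed, the execution report flags that a re-sort is needed.
* @PG bookkeeping is opt-in: the engine appends nothing, and the CLI adds
  a single @PG whose CL field is the *canonicalized* command (fixed stage
  order, not argv), so sequential-vs-combined and flag-permutation
  comparisons stay byte-identical. `--no-pg` disables it.

The CLI applies steps in a fixed canonical order regardless of flag
order — unmapped filter, MAPQ filter, duplicate marking, read-group
replacement, dictionary replacement, sort, then duplicate removal at
write-out — matching the five-step clinical protocol's placement of
marking before read-group replacement (libraries are taken from the
original RG tags). Users needing a different order chain two invocations.

## Synthetic workloads

`FixtureSpec`/`generate` produce deterministic SAM files containing the
workload classes the correctness arguments depend on: proper pairs,
unpaired fragments, PCR duplicates (same unclipped 5′ coordinates and
strands, fresh qname, perturbed — or with probability 0.35 identical,
forcing score ties — base qualities), soft-clipped reads (clips
re-rolled on copies so keys must be clip-invariant), cross-contig pairs,
pairs with a deleted mate, unmapped reads, occasional MAPQ-0 records, and
unknown optional tags. Base qualities are uniform on phred 2–40 so score
ties also arise naturally at small n. Defaults (150 pairs, 40 fragments,
10 unmapped per file; duplicate rate 0.3; cross-region rate 0.1; clip
rate 0.3; missing-mate rate 0.05; three contigs) give a few hundred
records per file — large enough that every code path and collision type
occurs, small enough that the quadratic-tolerant oracles stay instant.

What the generator does **not** emulate: reference-derived sequences,
realistic error/quality models, optical duplicate coordinates, secondary
and supplementary alignments, BAM/CRAM containers. Passing tests
therefore demonstrate the algebraic guarantees (equivalence, determinism,
fidelity) on structurally representative inputs, not performance or
robustness against the full zoo of real-world aligner quirks.

## Reference oracles

Two deliberately naive implementations exist only to check the engine:
a three-phase duplicate marker (collect, group by independently computed
keys, select per group) sharing only the score and tie-break definitions
with the production path, and a sequential pipeline runner that executes
each step as its own full pass with intermediate files — the standard
practice the single-pass architecture replaces. Problem sizes in the
test suite and the acceptance script (roughly 300–1300 records per file,
20 fixture seeds for marking, 5 for split/merge) were chosen so the full
check battery completes in seconds while exercising every collision
class; the guarantees themselves are size-independent.

## Known limitations

* Whole-file operations (sorting, and record storage during a pipeline)
  are in-memory; very large inputs should be split by region first.
* CRAM is unsupported; BAM only insofar as an external tool converts to
  SAM text (gzip-compressed SAM is read transparently).
* No optical-duplicate detection and no duplicate-metrics output.
* Queryname sort is plain lexicographic, with no natural-number variant.
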