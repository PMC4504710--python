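# samprep

Single-pass SAM preparation pipelines for variant-calling workflows.

Between the aligner and the variant caller, SAM/BAM files go through a
series of *preparation steps* — removing unmapped reads, filtering on
mapping quality, replacing read groups, reordering or filtering the
sequence dictionary, coordinate sorting, marking PCR duplicates. Standard
practice runs one tool invocation per step, so an *n*-step pipeline
parses and rewrites the whole file *n* times. samprep composes the steps
as **three-level filters** (a header stage, a worker stage, a per-record
stage) and executes any pipeline in **one pass**, guaranteed to produce
output byte-identical to running the steps one at a time. It is written
for pipeline engineers and method developers who want composable,
testable preparation steps with exact, diff-able semantics.

## What's inside

* **Filter engine** (`samprep.engine`) — compose steps, run them in a
  single pass, with a hard determinism contract: output is byte-identical
  for every worker count.
* **Duplicate marking** (`samprep.markdup`) — Picard-equivalent semantics
  reformulated as a single-pass filter over best-record memoization
  tables. A record's key is *(library, reference index, unclipped 5′
  coordinate, strand)*; its score is the sum of base qualities ≥ 15; a
  complete pair outranks any co-located fragment; ties break to the
  smaller qname so the marked set is invariant under any permutation of
  the input.
* **Split / merge by genomic region** (`samprep.split_merge`) — split a
  file into per-contig files plus a spanning-pairs file and an unmapped
  file such that *per-file* duplicate marking followed by merge equals
  *whole-file* marking, exactly.
* **Concrete steps** (`samprep.steps`), **sorting** (`samprep.sorting`),
  a byte-fidelity **SAM text layer** (`samprep.model`, `samprep.samio`),
  and a deterministic **synthetic-workload generator with reference
  oracles** (`samprep.simulate`).

See `docs/methods.md` for the algorithms and the design decisions.

## Worked example

Generate a small synthetic workload and prepare it with one command:

```sh
samprep fixtures demo.sam --seed 7 --pairs 40 --fragments 10 --unmapped 3
samprep prep demo.sam demo_prepped.sam \
    --filter-unmapped-reads --mark-duplicates --sort-order coordinate
```

The report (standard error) shows the single pass:

```
records read:    116
records dropped: 3
records written: 113
  dropped by filter-unmapped-reads: 3
  dropped by mark-duplicates: 0
```

116 records went in; the 3 unmapped reads were dropped by the unmapped
filter; duplicate marking *marks* rather than removes, so it drops
nothing — of the 113 records written, 25 carry flag bit 0x400 (this
fixture plants PCR copies at ~30% of templates). The output starts with
the updated header:

```
@HD	VN:1.6	SO:coordinate
@SQ	SN:chr1	LN:100000
...
```

`SO:coordinate` records the sort; permuting the step flags gives
byte-identical output because steps always run in a fixed canonical
order. The same pipeline through the library API:

```python
from samprep import (open_sam, run_pipeline, Pipeline,
                     filter_unmapped, mark_duplicates)

pipeline = Pipeline(steps=[filter_unmapped(), mark_duplicates()],
                    whole_set_operation="sort_coordinate")
report = run_pipeline(open_sam("demo.sam"), pipeline, "demo_prepped.sam")
```

Split/merge round trip with preserved duplicate semantics:

```sh
samprep split demo.sam regions/     # per-contig + spanning + unmapped files
samprep merge regions/ merged.sam   # drops split copies, re-sorts, verifies counts
```

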