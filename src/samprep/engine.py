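"""Single-pass pipeline execution engine.

A preparation pipeline is a list of steps, each a *three-level filter*:

1. a **header stage**, run exactly once per execution, which may modify the
   SAM header and returns a worker factory (or ``None`` when the step does
   no per-record work);
2. a **worker stage** (the factory), run once per worker to set up
   worker-local state and return the record stage;
3. a **record stage**, called once per record, which may modify the record
   in place and returns ``True`` to keep it or ``False`` to drop it.

The engine makes a single pass over the input: every record flows through
the record stages of all steps, in step order, with short-circuit on drop.
After the last record, registered finalize hooks run (duplicate marking
resolves fragment-vs-pair there); then the optional whole-set operation
(sorting) reorders the surviving records in memory; finally output steps
are applied while writing.

Worker-count independence is a hard contract: the output is byte-identical
for every value of ``workers``.  Records are assigned round-robin to
per-worker record-stage instances and processed in input order, so steps
with worker-local state see the same partition a threaded scheduler would,
while any cross-worker shared state (the duplicate tables) resolves
collisions with deterministic tie-breaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from .model import SamAlignment, SamHeader
from .samio import RecordStream, Source, write_sam
from . import sorting as _sorting

logger = logging.getLogger("samprep")

RecordStage = Callable[[SamAlignment], bool]
WorkerStage = Callable[[], RecordStage]
HeaderStage = Callable[[SamHeader, dict], Optional[WorkerStage]]


class PipelineError(RuntimeError):
    """A step failed; carries the step name (and record number if known)."""


@dataclass
class PreparationStep:
    """A named three-level filter.

    ``header_stage(header, state)`` runs once per execution.  ``state`` is a
    per-execution dict shared by all steps; a step needing an end-of-stream
    hook appends a callable to ``state["finalizers"]`` (run in registration
    order after the last record, before the whole-set operation).
    """

    name: str
    header_stage: HeaderStage


@dataclass
class Pipeline:
    """An ordered list of steps plus an optional whole-set operation.

    ``whole_set_operation`` is one of ``"sort_coordinate"``,
    ``"sort_queryname"`` or ``None``.  ``output_steps`` are ordinary
    preparation steps applied during write-out, after sorting.
    """

    steps: list[PreparationStep] = field(default_factory=list)
    whole_set_operation: Optional[str] = None
    output_steps: list[PreparationStep] = field(default_factory=list)


@dataclass
class ExecutionReport:
    """Bookkeeping for one pipeline execution."""

    records_read: int = 0
    records_dropped: int = 0
    records_written: int = 0
    step_drops: dict[str, int] = field(default_factory=dict)
    resort_required: bool = False

    def summary(self) -> str:
        lines = [
            f"records read:    {self.records_read}",
            f"records dropped: {self.records_dropped}",
            f"records written: {self.records_written}",
        ]
        for name, n in self.step_drops.items():
            lines.append(f"  dropped by {name}: {n}")
        if self.resort_required:
            lines.append("note: contig order changed; output needs re-sorting")
        return "\n".join(lines)


def compose(
    steps: list[PreparationStep], header: SamHeader, state: Optional[dict] = None
) -> RecordStage:
    """Combine the record stages of *steps* into one keep/drop function.

    Header stages run immediately (once); the returned function applies each
    record stage in order and short-circuits on the first drop, so side
    effects of earlier stages persist while later stages never see dropped
    records.  An empty step list composes to the identity (keep all).
    """
    if state is None:
        state = {}
    state.setdefault("finalizers", [])
    stages: list[tuple[str, RecordStage]] = []
    for step in steps:
        factory = _run_header_stage(step, header, state)
        if factory is not None:
            stages.append((step.name, factory()))

    def combined(rec: SamAlignment) -> bool:
        for name, stage in stages:
            try:
                keep = stage(rec)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"step {name!r} failed: {exc}") from exc
            if not keep:
                return False
        return True

    return combined


def _run_header_stage(
    step: PreparationStep, header: SamHeader, state: dict
) -> Optional[WorkerStage]:
    try:
        return step.header_stage(header, state)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"step {step.name!r} failed in header stage: {exc}") from exc


def run_pipeline(
    stream: RecordStream,
    pipeline: Pipeline,
    sink: Source,
    workers: int = 1,
) -> ExecutionReport:
    """Execute *pipeline* over *stream* in a single pass, writing to *sink*.

    ``workers`` partitions per-record work across worker-local record-stage
    instances; the output is byte-identical for every value (>= 1).
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    header = stream.header
    state: dict = {"finalizers": []}
    report = ExecutionReport()

    factories: list[tuple[PreparationStep, WorkerStage]] = []
    for step in pipeline.steps:
        factory = _run_header_stage(step, header, state)
        if factory is not None:
            factories.append((step, factory))
            report.step_drops.setdefault(step.name, 0)

    # one record-stage instance per (worker, step): worker-local state
    worker_stages = [
        [(step, factory()) for step, factory in factories]
        for _ in range(workers)
    ]

    kept: list[SamAlignment] = []
    for rank, rec in enumerate(stream.records):
        report.records_read += 1
        keep = True
        for step, stage in worker_stages[rank % workers]:
            try:
                keep = stage(rec)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(
                    f"step {step.name!r} failed on record {rank + 1}: {exc}"
                ) from exc
            if not keep:
                report.step_drops[step.name] += 1
                report.records_dropped += 1
                break
        if keep:
            kept.append(rec)

    for finalize in state["finalizers"]:
        finalize()

    if pipeline.whole_set_operation == "sort_coordinate":
        kept = _sorting.sort_records(header, kept, "coordinate")
    elif pipeline.whole_set_operation == "sort_queryname":
        kept = _sorting.sort_records(header, kept, "queryname")
    elif pipeline.whole_set_operation is not None:
        raise ValueError(
            f"unknown whole-set operation {pipeline.whole_set_operation!r}"
        )

    out_state: dict = {"finalizers": []}
    out_stage = compose(pipeline.output_steps, header, out_state)

    def _emit():
        for rec in kept:
            if out_stage(rec):
                yield rec
            else:
                report.records_dropped += 1

    report.records_written = write_sam(header, _emit(), sink)
    report.resort_required = bool(state.get("resort_required"))
    logger.info("pipeline done: %s", report)
    return report
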