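"""Staged concurrent execution of block conversion.

The conversion of a genotype file is a pipeline of three stages — read,
compress, write — applied to a sequence of blocks.  Running the stages
concurrently lets block k+1 be read while block k is compressed and block
k-1 written, so the make-span approaches n + stages - 1 steps instead of
n * stages.  This module provides that executor: one reader, q parse
workers, p compress workers, and one writer that restores block order
through a reorder buffer.  In-flight memory is bounded: at most
``capacity`` blocks exist between reader and writer at any instant
(backpressure), so a slow sink stalls the reader instead of exhausting
memory.

The executor changes the schedule, never the results: for every
configuration the output equals the serial composition
``sink(compress_fn(parse_fn(block)))`` over the source, in source order.
Workers are realized as threads; the callables must be pure per block.

Every run produces a :class:`StageTrace` of per-block stage intervals in
monotonic event ticks (not wall time), so scheduling assertions are
hardware-independent.
"""

from __future__ import annotations

import itertools
import os
import threading
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Iterable, Iterator, Optional

STAGES = ("read", "parse", "compress", "write")


@dataclass(frozen=True)
class PipelineConfig:
    """Worker counts and memory bound for a pipeline run.

    ``p`` — compress workers; ``q`` — parse workers; ``buffer_size`` —
    markers per block; ``memory_limit`` — bytes of in-flight blocks.
    A value of 0 means "resolve an optimized default" (see
    :func:`resolve_auto`).
    """

    p: int = 0
    q: int = 0
    buffer_size: int = 0
    memory_limit: int = 0
    capacity: int = 0  # in-flight blocks between reader and writer

    def resolved(self) -> bool:
        return min(self.p, self.q, self.buffer_size, self.capacity) >= 1


DEFAULT_BUFFER_SIZE = 10  # markers per block


def resolve_auto(
    config: PipelineConfig,
    cpu_count: Optional[int] = None,
    typical_block_bytes: int = 0,
) -> PipelineConfig:
    """Fill in every 0-valued field with its optimized default.

    Worker counts reserve one core each for the reader and the writer:
    p = max(1, CPUs - 2); q = max(1, min(p, CPUs // 2)).  The queue
    capacity is 2 * max(p, q) blocks unless an explicit memory_limit is
    given, in which case it is floor(memory_limit / typical_block_bytes),
    at least 1.
    """
    cpus = cpu_count if cpu_count is not None else (os.cpu_count() or 1)
    p = config.p if config.p >= 1 else max(1, cpus - 2)
    q = config.q if config.q >= 1 else max(1, min(p, cpus // 2))
    buffer_size = config.buffer_size if config.buffer_size >= 1 else DEFAULT_BUFFER_SIZE
    if config.capacity >= 1:
        capacity = config.capacity
    elif config.memory_limit >= 1 and typical_block_bytes >= 1:
        capacity = max(1, config.memory_limit // typical_block_bytes)
    else:
        capacity = 2 * max(p, q)
    return replace(config, p=p, q=q, buffer_size=buffer_size, capacity=capacity)


@dataclass(frozen=True, slots=True)
class StageEvent:
    block_index: int
    stage: str
    start: int
    finish: int
    worker: str


class StageTrace:
    """Per-block, per-stage intervals in monotonic event ticks.

    Ticks come from a single shared counter, so `a.finish < b.start`
    certifies that interval `a` ended before `b` began.
    """

    def __init__(self) -> None:
        self._events: list[StageEvent] = []
        self._lock = threading.Lock()
        self._ticker = itertools.count(1)

    def tick(self) -> int:
        with self._lock:
            return next(self._ticker)

    def add(self, block_index: int, stage: str, start: int, finish: int, worker: str) -> None:
        with self._lock:
            self._events.append(StageEvent(block_index, stage, start, finish, worker))

    @property
    def events(self) -> list[StageEvent]:
        return list(self._events)

    def by_block(self, block_index: int) -> dict[str, StageEvent]:
        return {e.stage: e for e in self._events if e.block_index == block_index}

    def to_tsv(self) -> str:
        lines = ["block_index\tstage\tstart\tfinish\tworker"]
        for e in sorted(self._events, key=lambda e: (e.start, e.block_index)):
            lines.append(f"{e.block_index}\t{e.stage}\t{e.start}\t{e.finish}\t{e.worker}")
        return "\n".join(lines) + "\n"


class PipelineError(Exception):
    """First (by block order) failure of a pipeline run."""

    def __init__(self, block_index: int, stage: str, cause: BaseException):
        self.block_index = block_index
        self.stage = stage
        self.cause = cause
        super().__init__(f"block {block_index} failed in stage '{stage}': {cause}")


@dataclass
class PipelineSummary:
    blocks_read: int = 0
    blocks_written: int = 0
    status: str = "ok"


def run_pipeline(
    source: Iterable[Any],
    parse_fn: Callable[[Any], Any],
    compress_fn: Callable[[Any], Any],
    sink: Callable[[Any], None],
    config: PipelineConfig,
) -> tuple[PipelineSummary, StageTrace]:
    """Drive blocks from ``source`` through parse and compress workers to ``sink``.

    Every produced block is written exactly once, in ascending block order,
    regardless of worker completion order.  At most ``config.capacity``
    blocks are in flight between reader and writer.  On any stage failure
    the pipeline stops admitting new blocks, drains the in-flight ones,
    writes whatever precedes the failure, and raises :class:`PipelineError`
    for the first failing block in block order.
    """
    cfg = config if config.resolved() else resolve_auto(config)
    trace = StageTrace()
    summary = PipelineSummary()

    permits = threading.Semaphore(cfg.capacity)
    cond = threading.Condition()
    done: dict[int, Any] = {}  # compressed blocks awaiting the writer
    errors: dict[int, tuple[str, BaseException]] = {}
    produced = 0
    reader_finished = False
    stop = threading.Event()

    def record_error(idx: int, stage: str, exc: BaseException) -> None:
        stop.set()
        with cond:
            errors[idx] = (stage, exc)
            cond.notify_all()

    parse_pool = ThreadPoolExecutor(max_workers=cfg.q, thread_name_prefix="parse")
    compress_pool = ThreadPoolExecutor(max_workers=cfg.p, thread_name_prefix="compress")

    def compress_task(idx: int, parsed: Any) -> None:
        t0 = trace.tick()
        try:
            result = compress_fn(parsed)
        except BaseException as e:  # noqa: BLE001 - surfaced via PipelineError
            record_error(idx, "compress", e)
            return
        trace.add(idx, "compress", t0, trace.tick(), threading.current_thread().name)
        with cond:
            done[idx] = result
            cond.notify_all()

    def parse_task(idx: int, block: Any) -> None:
        t0 = trace.tick()
        try:
            parsed = parse_fn(block)
        except BaseException as e:  # noqa: BLE001
            record_error(idx, "parse", e)
            return
        trace.add(idx, "parse", t0, trace.tick(), threading.current_thread().name)
        compress_pool.submit(compress_task, idx, parsed)

    def reader() -> None:
        nonlocal produced, reader_finished
        it: Iterator[Any] = iter(source)
        idx = 0
        while not stop.is_set():
            # timed acquire so a failed run cannot leave the reader parked
            if not permits.acquire(timeout=0.05):
                continue
            if stop.is_set():
                permits.release()
                break
            t0 = trace.tick()
            try:
                block = next(it)
            except StopIteration:
                permits.release()
                break
            except BaseException as e:  # noqa: BLE001
                permits.release()
                with cond:
                    produced = idx
                record_error(idx, "read", e)
                return
            trace.add(idx, "read", t0, trace.tick(), "reader")
            with cond:
                produced = idx + 1
            parse_pool.submit(parse_task, idx, block)
            idx += 1
        with cond:
            reader_finished = True
            cond.notify_all()

    reader_thread = threading.Thread(target=reader, name="reader", daemon=True)
    reader_thread.start()

    # Writer runs in the calling thread: pops blocks in index order.
    next_idx = 0
    failure: Optional[PipelineError] = None
    try:
        while True:
            with cond:
                cond.wait_for(
                    lambda: next_idx in done
                    or next_idx in errors
                    or (reader_finished and next_idx >= produced)
                )
                if next_idx in errors:
                    stage, exc = errors[next_idx]
                    failure = PipelineError(next_idx, stage, exc)
                    break
                if next_idx not in done:
                    break  # clean EOF: every produced block has been written
                item = done.pop(next_idx)
            t0 = trace.tick()
            try:
                sink(item)
            except BaseException as e:  # noqa: BLE001
                failure = PipelineError(next_idx, "write", e)
                stop.set()
                break
            trace.add(next_idx, "write", t0, trace.tick(), "writer")
            permits.release()
            summary.blocks_written += 1
            next_idx += 1
    finally:
        stop.set()
        reader_thread.join()
        parse_pool.shutdown(wait=True)
        compress_pool.shutdown(wait=True)

    summary.blocks_read = produced
    if failure is None and errors:
        # an error landed on a block past EOF bookkeeping; surface the first
        idx = min(errors)
        failure = PipelineError(idx, errors[idx][0], errors[idx][1])
    if failure is not None:
        summary.status = "error"
        raise failure
    return summary, trace
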