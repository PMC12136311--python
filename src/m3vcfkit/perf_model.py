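"""Analytic timing model for staged, multi-threaded file conversion.

A dataset of m markers is processed in n = ceil(m / l) blocks of l markers.
Per block, the three stages take Tread (= Tload + Tparse), Tcompress and
Twrite.  The model quantifies, under an idealized no-overhead assumption,
three independent sources of time savings:

* T1 — workflow pipelining: the sequential schedule costs
  n * (Tread + Tcompress + Twrite); the pipelined schedule is modelled as
  compress-dominated, 1 * Tread + n * Tcompress + 1 * Twrite, so
  T1 = (n - 1) * (Tread + Twrite).
* T2 — compressing each block on p threads: Tcompress -> Tcompress / p,
  saving T2 = (p - 1) * Tcompress / p.
* T3 — parsing on q threads within the read stage:
  Tread -> Tload + Tparse / q, saving T3 = (q - 1) * Tparse / q.

The total saving is Ts = T1 + T2 + T3.  Thread-count saturation is
described by Amdahl's law, S(alpha, p) = 1 / ((1 - alpha) + alpha / p),
where alpha is the parallelizable fraction of the task.

A separate step-count view: with one block admitted per step once the pipe
is full, a pipelined s-stage schedule finishes n blocks in n + s - 1 steps
versus n * s sequentially (e.g. 3 blocks through 3 stages: 5 steps vs 9).

The pipelined-time formula is deliberately the literal compress-dominated
idealization, not a general max-based make-span: T1 is defined against it
and the identity time_sequential - time_pipelined == savings_workflow
holds exactly under it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum


class ScheduleMode(Enum):
    SEQUENTIAL = "sequential"
    PIPELINED = "pipelined"


@dataclass(frozen=True)
class WorkloadModel:
    """Per-block stage times for a dataset of m markers in blocks of l.

    Times are in arbitrary consistent units (the model is scale-free).
    ``t_read`` is derived: t_load + t_parse.
    """

    m: int  # total markers
    l: int  # markers per block
    t_load: float = 0.0  # raw-line reading within the read stage
    t_parse: float = 0.0  # field parsing within the read stage
    t_compress: float = 0.0
    t_write: float = 0.0

    def __post_init__(self) -> None:
        if self.m < 1 or self.l < 1:
            raise ValueError("m and l must be >= 1")
        for name in ("t_load", "t_parse", "t_compress", "t_write"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n(self) -> int:
        """Number of blocks: ceil(m / l)."""
        return -(-self.m // self.l)

    @property
    def t_read(self) -> float:
        return self.t_load + self.t_parse


@dataclass(frozen=True)
class ParallelismParams:
    """p compress threads, q parse threads, alpha parallelizable fraction."""

    p: int = 1
    q: int = 1
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.p < 1 or self.q < 1:
            raise ValueError("p and q must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


def step_count(n_blocks: int, n_stages: int, mode: ScheduleMode) -> int:
    """Steps to push n_blocks through n_stages stages.

    Sequential: every block runs all stages before the next starts, so
    n_blocks * n_stages.  Pipelined: the pipe fills in n_stages steps and
    then completes one block per step: n_blocks + n_stages - 1.
    """
    if n_blocks < 1 or n_stages < 1:
        raise ValueError("n_blocks and n_stages must be >= 1")
    if mode is ScheduleMode.SEQUENTIAL:
        return n_blocks * n_stages
    return n_blocks + n_stages - 1


def time_sequential(w: WorkloadModel) -> float:
    """Total time of the unpipelined schedule: n * (Tread + Tcompress + Twrite)."""
    return w.n * (w.t_read + w.t_compress + w.t_write)


def time_pipelined(w: WorkloadModel) -> float:
    """Compress-dominated pipelined time: 1*Tread + n*Tcompress + 1*Twrite."""
    return w.t_read + w.n * w.t_compress + w.t_write


def savings_workflow(w: WorkloadModel) -> float:
    """T1 = (n - 1) * (Tread + Twrite); equals sequential minus pipelined time."""
    return (w.n - 1) * (w.t_read + w.t_write)


def savings_compress(t_compress: float, p: int) -> tuple[float, float]:
    """Ideal p-thread compression: returns (Tcompress/p, T2 = (p-1)*Tcompress/p)."""
    if p < 1:
        raise ValueError("p must be >= 1")
    parallel_time = t_compress / p
    return parallel_time, t_compress - parallel_time


def savings_parse(t_load: float, t_parse: float, q: int) -> tuple[float, float]:
    """Ideal q-thread parsing: returns (Tload + Tparse/q, T3 = (q-1)*Tparse/q)."""
    if q < 1:
        raise ValueError("q must be >= 1")
    read_time = t_load + t_parse / q
    return read_time, t_parse - t_parse / q


def total_savings(w: WorkloadModel, params: ParallelismParams) -> float:
    """Ts = T1 + T2 + T3: the three idealized savings are additive."""
    t1 = savings_workflow(w)
    _, t2 = savings_compress(w.t_compress, params.p)
    _, t3 = savings_parse(w.t_load, w.t_parse, params.q)
    return t1 + t2 + t3


def amdahl_speedup(alpha: float, p: float) -> float:
    """Theoretical speedup 1 / ((1 - alpha) + alpha / p) on p threads.

    Saturates at 1 / (1 - alpha) as p grows: the serial fraction bounds
    the achievable gain regardless of thread count.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if p < 1:
        raise ValueError("p must be >= 1")
    denom = (1.0 - alpha) + alpha / p
    return math.inf if denom == 0.0 else 1.0 / denom


def replay_unit_time(
    trace,
    stages: tuple[str, ...] = ("read", "compress", "write"),
    lanes: dict[str, int] | None = None,
) -> int:
    """Discrete-event replay of a pipeline StageTrace with unit stage times.

    Re-schedules the trace's events assuming every stage takes exactly one
    tick, honouring the per-block stage order and a bounded number of lanes
    (workers) per stage; within a stage, blocks are admitted in block order
    (the reorder buffer's output order).  Returns the make-span in ticks.
    For a full pipelined run of n blocks this reproduces
    ``step_count(n, len(stages), PIPELINED)``, tying the executor's observed
    schedule back to the analytic model without any wall-clock measurement.
    """
    lanes = lanes or {}
    stage_pos = {s: i for i, s in enumerate(stages)}
    events = sorted(
        (e for e in trace.events if e.stage in stage_pos),
        key=lambda e: (stage_pos[e.stage], e.block_index),
    )
    if not events:
        return 0
    finish: dict[tuple[int, str], int] = {}
    lane_free: dict[str, list[int]] = {s: [0] * max(1, lanes.get(s, 1)) for s in stages}
    for e in events:
        i = stage_pos[e.stage]
        ready = finish.get((e.block_index, stages[i - 1]), 0) if i > 0 else 0
        lane_times = lane_free[e.stage]
        k = min(range(len(lane_times)), key=lane_times.__getitem__)
        start = max(ready, lane_times[k])
        finish[(e.block_index, e.stage)] = start + 1
        lane_times[k] = start + 1
    return max(finish.values())


def model_table(w: WorkloadModel, params: ParallelismParams) -> str:
    """Human-readable summary of every model quantity for given inputs."""
    t_seq = time_sequential(w)
    t_pipe = time_pipelined(w)
    t1 = savings_workflow(w)
    c_time, t2 = savings_compress(w.t_compress, params.p)
    r_time, t3 = savings_parse(w.t_load, w.t_parse, params.q)
    ts = total_savings(w, params)
    rows = [
        ("markers m", w.m),
        ("block size l", w.l),
        ("blocks n = ceil(m/l)", w.n),
        ("T_read = T_load + T_parse", w.t_read),
        ("sequential time n(T_read+T_compress+T_write)", t_seq),
        ("pipelined time T_read + n*T_compress + T_write", t_pipe),
        ("T1 workflow savings (n-1)(T_read+T_write)", t1),
        (f"compress time on p={params.p} threads", c_time),
        ("T2 compress savings (p-1)T_compress/p", t2),
        (f"read time with q={params.q} parse threads", r_time),
        ("T3 parse savings (q-1)T_parse/q", t3),
        ("Ts total savings T1+T2+T3", ts),
        (f"Amdahl speedup (alpha={params.alpha}, p={params.p})",
         amdahl_speedup(params.alpha, params.p)),
        ("steps sequential (n blocks, 3 stages)",
         step_count(w.n, 3, ScheduleMode.SEQUENTIAL)),
        ("steps pipelined (n blocks, 3 stages)",
         step_count(w.n, 3, ScheduleMode.PIPELINED)),
    ]
    width = max(len(r[0]) for r in rows)
    return "\n".join(
        f"{name:<{width}}  {val:g}" if isinstance(val, float) else f"{name:<{width}}  {val}"
        for name, val in rows
    )
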