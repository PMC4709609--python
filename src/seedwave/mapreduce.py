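"""Chunked parallel map/reduce execution of the aligner.

The reference is split into overlapping chunks; each map task aligns every
query (optionally itself split into overlapping query chunks) against one
reference chunk and emits alignment records in global reference
coordinates, keyed by (query id, chunk id).  Shuffle groups records by
query and sorts them by reference offset; reduce keeps a nonredundant,
nonoverlapping subset per query by a greedy sweep.  Worker makespans are
instrumented: per-worker map time decomposes into data fetch, query split,
alignment and store; per-worker reduce time into data fetch, reduce
function and store; phase aggregates are the means over workers and the
total is their sum (the platform-initialisation term is taken as zero).

Workers are processes on one machine standing in for cloud VMs.  All
scheduling is output-invariant: results are collected by task identity, so
the final record set is bit-identical for any worker count and with phase
overlap on or off.
"""

from __future__ import annotations

import json
import os
import time
from concurrent.futures import FIRST_COMPLETED, ProcessPoolExecutor, wait
from dataclasses import asdict, dataclass, field

from .records import AlignmentRecord
from .seeding import SeedParams, align_long_read
from .sequence import Sequence
from .sw import ScoringScheme

__all__ = [
    "ChunkRecord",
    "QueryRecord",
    "IntermediateRecord",
    "MakespanReport",
    "RunConfig",
    "split_reference",
    "split_query",
    "map_task",
    "shuffle_sort",
    "reduce_task",
    "run_pipeline",
    "makespan_summary",
]


@dataclass(frozen=True)
class ChunkRecord:
    """Key/value payload for one overlapping reference chunk."""

    key: str
    residues: str
    ref_name: str
    g_start: int
    g_end: int
    overlap_left: int
    overlap_right: int


@dataclass(frozen=True)
class QueryRecord:
    """Key/value payload for one query chunk."""

    key: str
    residues: str
    query_id: str
    local_offset: int


@dataclass(frozen=True)
class IntermediateRecord:
    """Map output: (query id, chunk id) key with global-coordinate records."""

    query_id: str
    chunk_id: str
    records: tuple[AlignmentRecord, ...]


@dataclass
class MapWorkerTiming:
    worker_id: int
    get_data: float = 0.0
    query_split: float = 0.0
    align: float = 0.0
    store: float = 0.0
    total: float = 0.0


@dataclass
class ReduceWorkerTiming:
    worker_id: int
    get_data: float = 0.0
    fn: float = 0.0
    store: float = 0.0
    total: float = 0.0


@dataclass
class MakespanReport:
    """Per-worker makespans of one pipeline run."""

    map_workers: list[MapWorkerTiming] = field(default_factory=list)
    reduce_workers: list[ReduceWorkerTiming] = field(default_factory=list)
    wall_total: float = 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "map_workers": [asdict(t) for t in self.map_workers],
                "reduce_workers": [asdict(t) for t in self.reduce_workers],
                "wall_total": self.wall_total,
                "summary": makespan_summary(self),
            }
        )


def makespan_summary(report: MakespanReport) -> dict[str, float]:
    """Aggregate makespans: phase means over workers and their sum.

    The total equals map mean plus reduce mean; the virtual-machine
    configuration term of a cloud deployment is fixed at zero here.
    """
    if not report.map_workers:
        raise ValueError("empty makespan report")
    t_map = sum(t.total for t in report.map_workers) / len(report.map_workers)
    if report.reduce_workers:
        t_reduce = sum(t.total for t in report.reduce_workers) / len(
            report.reduce_workers
        )
    else:
        t_reduce = 0.0
    return {"t_map": t_map, "t_reduce": t_reduce, "total": t_map + t_reduce}


def _split_spans(n: int, chunk_len: int, overlap: int) -> list[tuple[int, int]]:
    if chunk_len < 1:
        raise ValueError("chunk length must be positive")
    if overlap < 0 or overlap >= chunk_len:
        raise ValueError("require 0 <= overlap < chunk length")
    if n <= chunk_len:
        return [(0, n)]
    step = chunk_len - overlap
    spans = []
    start = 0
    while True:
        end = min(start + chunk_len, n)
        spans.append((start, end))
        if end >= n:
            break
        start += step
    return spans


def split_reference(ref: Sequence, chunk_len: int, overlap: int) -> list[ChunkRecord]:
    """Overlapping reference chunks covering the reference exactly.

    Chunk i starts at ``i * (chunk_len - overlap)``; adjacent chunks share
    ``overlap`` positions; the last chunk ends at the reference end.
    """
    spans = _split_spans(len(ref), chunk_len, overlap)
    chunks = []
    for i, (s, e) in enumerate(spans):
        chunks.append(
            ChunkRecord(
                key=f"{ref.name}:{i:05d}",
                residues=ref.residues[s:e],
                ref_name=ref.name,
                g_start=s,
                g_end=e,
                overlap_left=0 if i == 0 else overlap,
                overlap_right=0 if i == len(spans) - 1 else overlap,
            )
        )
    return chunks


def split_query(query: Sequence, q_chunk_len: int | None, q_overlap: int = 0
                ) -> list[QueryRecord]:
    """Overlapping query chunks (one chunk when ``q_chunk_len`` is None)."""
    if q_chunk_len is None:
        q_chunk_len = max(len(query), 1)
        q_overlap = 0
    spans = _split_spans(len(query), q_chunk_len, q_overlap)
    return [
        QueryRecord(
            key=f"{query.name}/{i:04d}",
            residues=query.residues[s:e],
            query_id=query.name,
            local_offset=s,
        )
        for i, (s, e) in enumerate(spans)
    ]


def map_task(
    chunk: ChunkRecord,
    queries: list[Sequence],
    scheme: ScoringScheme,
    params: SeedParams,
    cores: int = 1,
    both_strands: bool = True,
    q_chunk_len: int | None = None,
    q_overlap: int = 0,
    spill_dir: str | None = None,
) -> tuple[list[IntermediateRecord], dict[str, float]]:
    """Align every query (chunk) against one reference chunk.

    Queries are split inside the task (the query-split makespan term is
    charged to the map worker).  Emitted records carry global reference
    coordinates and parent-query coordinates.  Timing terms are returned
    alongside the records.
    """
    if cores < 1:
        raise ValueError("cores must be >= 1")
    t0 = time.perf_counter()
    r_chunk = Sequence(chunk.ref_name, chunk.residues)
    t_get = time.perf_counter() - t0

    t0 = time.perf_counter()
    q_records: list[QueryRecord] = []
    for q in queries:
        q_records.extend(split_query(q, q_chunk_len, q_overlap))
    t_qi = time.perf_counter() - t0

    t0 = time.perf_counter()
    out: list[IntermediateRecord] = []
    by_query: dict[str, list[AlignmentRecord]] = {}
    try:
        for qr in q_records:
            local = align_long_read(
                Sequence(qr.query_id, qr.residues),
                r_chunk,
                scheme,
                params,
                both_strands=both_strands,
            )
            for rec in local:
                glob = AlignmentRecord(
                    query=qr.query_id,
                    q_start=rec.q_start + qr.local_offset,
                    q_end=rec.q_end + qr.local_offset,
                    ref=chunk.ref_name,
                    r_start=rec.r_start + chunk.g_start,
                    r_end=rec.r_end + chunk.g_start,
                    strand=rec.strand,
                    score=rec.score,
                    ops=rec.ops,
                    chunk_id=chunk.key,
                )
                by_query.setdefault(qr.query_id, []).append(glob)
    except Exception as exc:  # surface failing chunk/query identifiers
        raise RuntimeError(f"map task failed for chunk {chunk.key}: {exc}") from exc
    t_align = time.perf_counter() - t0

    t0 = time.perf_counter()
    for query_id in sorted(by_query):
        out.append(
            IntermediateRecord(query_id, chunk.key, tuple(by_query[query_id]))
        )
    if spill_dir:
        os.makedirs(spill_dir, exist_ok=True)
        path = os.path.join(spill_dir, f"map-{chunk.key.replace(':', '_')}.jsonl")
        with open(path, "w") as fh:
            for rec in out:
                fh.write(
                    json.dumps(
                        {
                            "km": [rec.query_id, rec.chunk_id],
                            "vm": [asdict(r) for r in rec.records],
                        }
                    )
                    + "\n"
                )
    t_store = time.perf_counter() - t0
    timing = {
        "get_data": t_get,
        "query_split": t_qi,
        "align": t_align,
        "store": t_store,
    }
    return out, timing


_SORT_KEY = lambda r: (r.r_start, -r.score, r.chunk_id, r.strand, r.q_start,
                       r.r_end, r.ops)


def shuffle_sort(
    records: list[IntermediateRecord],
) -> dict[str, list[AlignmentRecord]]:
    """Group by query id; sort each group by (start, -score, chunk id)."""
    groups: dict[str, list[AlignmentRecord]] = {}
    for inter in records:
        groups.setdefault(inter.query_id, []).extend(inter.records)
    return {
        qid: sorted(groups[qid], key=_SORT_KEY) for qid in sorted(groups)
    }


def reduce_task(
    group: list[AlignmentRecord], redundancy_fraction: float = 0.5
) -> list[AlignmentRecord]:
    """Greedy sweep keeping nonredundant, nonoverlapping records.

    Walking the sorted group, a record is dropped if it is an exact
    duplicate of a retained record (overlap-zone duplication) or if, on the
    same strand, its reference interval overlaps a retained record by more
    than ``redundancy_fraction`` of the shorter interval.
    """
    retained: list[AlignmentRecord] = []
    seen: set[tuple] = set()
    for rec in group:
        key = rec.identity_key()
        if key in seen:
            continue
        conflict = False
        for kept in retained:
            if kept.strand != rec.strand:
                continue
            ov = min(kept.r_end, rec.r_end) - max(kept.r_start, rec.r_start)
            shorter = min(kept.r_length, rec.r_length)
            if shorter <= 0:
                continue
            if ov / shorter > redundancy_fraction:
                conflict = True
                break
        if not conflict:
            retained.append(rec)
            seen.add(key)
    return retained


@dataclass
class RunConfig:
    """One validated pipeline configuration."""

    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    seeding: SeedParams = field(default_factory=SeedParams)
    chunk_len: int = 100_000
    overlap: int = 10_000
    q_chunk_len: int | None = None
    q_overlap: int = 0
    workers: int = 1
    cores: int = 1
    both_strands: bool = True
    redundancy_fraction: float = 0.5
    early_reduce: bool = True
    spill_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.workers < 1 or self.cores < 1:
            raise ValueError("workers and cores must be >= 1")
        if not 0.0 <= self.redundancy_fraction <= 1.0:
            raise ValueError("redundancy_fraction must lie in [0, 1]")


def _run_map_task(args):
    chunk, queries, scheme, params, cfg = args
    return map_task(
        chunk,
        queries,
        scheme,
        params,
        cores=cfg.cores,
        both_strands=cfg.both_strands,
        q_chunk_len=cfg.q_chunk_len,
        q_overlap=cfg.q_overlap,
        spill_dir=cfg.spill_dir,
    )


def run_pipeline(
    ref: Sequence,
    queries: list[Sequence],
    config: RunConfig | None = None,
) -> tuple[list[AlignmentRecord], MakespanReport]:
    """Split -> map (w workers) -> shuffle -> reduce (w workers).

    With phase overlap on, reduce-side grouping starts as soon as the first
    map task completes; the retained record set is identical either way and
    for any worker count (order-normalised).
    """
    config = config or RunConfig()
    wall0 = time.perf_counter()
    chunks = split_reference(ref, config.chunk_len, config.overlap)
    w = config.workers
    task_args = [
        (chunk, queries, config.scoring, config.seeding, config) for chunk in chunks
    ]
    results: list[tuple[list[IntermediateRecord], dict[str, float]] | None]
    results = [None] * len(chunks)
    reduce_get0: float | None = None

    if w == 1 or len(chunks) == 1:
        for i, args in enumerate(task_args):
            results[i] = _run_map_task(args)
            if config.early_reduce and reduce_get0 is None:
                reduce_get0 = time.perf_counter()
    else:
        with ProcessPoolExecutor(max_workers=w) as pool:
            futures = {pool.submit(_run_map_task, args): i
                       for i, args in enumerate(task_args)}
            pending = set(futures)
            while pending:
                done, pending = wait(pending, return_when=FIRST_COMPLETED)
                if config.early_reduce and reduce_get0 is None:
                    reduce_get0 = time.perf_counter()
                for fut in done:
                    results[futures[fut]] = fut.result()

    # per-worker map timings: task i belongs to logical worker i % w
    map_timings = [MapWorkerTiming(worker_id=i) for i in range(min(w, len(chunks)))]
    intermediates: list[IntermediateRecord] = []
    for i, res in enumerate(results):
        inter, timing = res
        intermediates.extend(inter)
        t = map_timings[i % len(map_timings)]
        t.get_data += timing["get_data"]
        t.query_split += timing["query_split"]
        t.align += timing["align"]
        t.store += timing["store"]
        t.total += sum(timing.values())

    t_shuffle0 = time.perf_counter()
    groups = shuffle_sort(intermediates)
    t_shuffle = time.perf_counter() - t_shuffle0
    if reduce_get0 is None:
        reduce_get0 = t_shuffle0

    group_ids = list(groups)
    n_red = max(1, min(w, max(len(group_ids), 1)))
    reduce_timings = [ReduceWorkerTiming(worker_id=i) for i in range(n_red)]
    finals: list[AlignmentRecord] = []
    for i, qid in enumerate(group_ids):
        rt = reduce_timings[i % n_red]
        t0 = time.perf_counter()
        kept = reduce_task(groups[qid], config.redundancy_fraction)
        rt.fn += time.perf_counter() - t0
        finals.extend(kept)
    t0 = time.perf_counter()
    finals.sort(key=lambda r: (r.query, r.strand, r.r_start, r.q_start, -r.score,
                               r.ops))
    t_store = time.perf_counter() - t0
    shuffle_share = t_shuffle / n_red
    store_share = t_store / n_red
    for rt in reduce_timings:
        rt.get_data = shuffle_share
        rt.store = store_share
        rt.total = rt.get_data + rt.fn + rt.store
    report = MakespanReport(
        map_workers=map_timings,
        reduce_workers=reduce_timings,
        wall_total=time.perf_counter() - wall0,
    )
    return finals, report
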