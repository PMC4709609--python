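import json
import os

import numpy as np
import pytest

from conftest import random_dna
from seedwave.mapreduce import (
    MakespanReport,
    MapWorkerTiming,
    ReduceWorkerTiming,
    RunConfig,
    makespan_summary,
    map_task,
    reduce_task,
    run_pipeline,
    shuffle_sort,
    split_query,
    split_reference,
)
from seedwave.records import AlignmentRecord
from seedwave.seeding import SeedParams, align_long_read
from seedwave.sequence import Sequence
from seedwave.sw import ScoringScheme


def _norm(records):
    return sorted(
        (r.query, r.strand, r.q_start, r.q_end, r.r_start, r.r_end, r.score, r.ops)
        for r in records
    )


def _rec(query="q", q0=0, q1=10, r0=0, r1=10, strand="+", score=10.0, ops="10=",
         chunk="c"):
    return AlignmentRecord(query, q0, q1, "ref", r0, r1, strand, score, ops, chunk)


# -- splitting -----------------------------------------------------------


def test_split_reference_spec_example():
    ref = Sequence("r", "A" * 100)
    chunks = split_reference(ref, 40, 10)
    assert [(c.g_start, c.g_end) for c in chunks] == [(0, 40), (30, 70), (60, 100)]
    assert [c.key for c in chunks] == ["r:00000", "r:00001", "r:00002"]
    assert chunks[0].overlap_left == 0 and chunks[1].overlap_left == 10
    assert chunks[-1].overlap_right == 0


def test_split_reference_no_overlap_partitions():
    ref = Sequence("r", random_dna(np.random.default_rng(0), 90))
    chunks = split_reference(ref, 30, 0)
    assert "".join(c.residues for c in chunks) == ref.residues


def test_split_reference_short_input_single_chunk():
    ref = Sequence("r", "A" * 35)
    chunks = split_reference(ref, 40, 10)
    assert [(c.g_start, c.g_end) for c in chunks] == [(0, 35)]


def test_split_reference_coverage_and_roundtrip():
    rng = np.random.default_rng(1)
    ref = Sequence("r", random_dna(rng, 257))
    chunks = split_reference(ref, 64, 16)
    covered = set()
    for c in chunks:
        assert ref.residues[c.g_start : c.g_end] == c.residues
        covered.update(range(c.g_start, c.g_end))
    assert covered == set(range(257))
    for a, b in zip(chunks, chunks[1:]):
        assert a.g_end - b.g_start == 16  # adjacent chunks share `overlap`


def test_split_reference_errors():
    ref = Sequence("r", "A" * 100)
    with pytest.raises(ValueError):
        split_reference(ref, 40, 40)
    with pytest.raises(ValueError):
        split_reference(ref, 0, 0)


def test_split_query_examples():
    q = Sequence("q", "A" * 1000)
    assert [(r.local_offset, r.local_offset + len(r.residues))
            for r in split_query(q, 1000)] == [(0, 1000)]
    assert [(r.local_offset, r.local_offset + len(r.residues))
            for r in split_query(q, 600, 200)] == [(0, 600), (400, 1000)]
    with pytest.raises(ValueError):
        split_query(q, 100, 100)
    assert len(split_query(q, None)) == 1  # query chunking off


# -- map -----------------------------------------------------------------


def test_map_task_global_offsets(scheme):
    rng = np.random.default_rng(2)
    ref = Sequence("ref", random_dna(rng, 900))
    chunks = split_reference(ref, 400, 100)
    q = Sequence("q", ref.residues[450:570])  # inside chunk 1 [300, 700)
    inters, timing = map_task(chunks[1], [q], scheme, SeedParams())
    assert len(inters) == 1
    assert inters[0].query_id == "q" and inters[0].chunk_id == chunks[1].key
    best = max(inters[0].records, key=lambda r: r.score)
    assert (best.r_start, best.r_end) == (450, 570)
    assert set(timing) == {"get_data", "query_split", "align", "store"}
    assert all(v >= 0.0 for v in timing.values())


def test_map_task_overlap_zone_emitted_by_both_chunks(scheme):
    rng = np.random.default_rng(3)
    ref = Sequence("ref", random_dna(rng, 800))
    chunks = split_reference(ref, 500, 200)  # chunks [0,500), [300,800)
    q = Sequence("q", ref.residues[350:450])  # wholly inside the overlap
    hits = []
    for c in chunks:
        inters, _ = map_task(c, [q], scheme, SeedParams())
        for inter in inters:
            hits.append(_norm(inter.records))
    assert len(hits) == 2 and hits[0] == hits[1]


def test_map_task_unrelated_query_empty(scheme):
    rng = np.random.default_rng(4)
    ref = Sequence("ref", random_dna(rng, 400))
    q = Sequence("q", random_dna(rng, 80))
    chunks = split_reference(ref, 400, 0)
    inters, _ = map_task(chunks[0], [q], scheme,
                         SeedParams(min_report_score=60.0))
    assert inters == []


def test_map_task_error_names_chunk(scheme):
    chunk = split_reference(Sequence("ref", "ACGT" * 30), 120, 0)[0]
    with pytest.raises(ValueError):
        map_task(chunk, [Sequence("q", "ACGT")], scheme, SeedParams(), cores=0)
    with pytest.raises(RuntimeError, match="ref:00000"):
        map_task(chunk, [Sequence("q", "")], scheme, SeedParams())


def test_map_task_spill_dir(tmp_path, scheme):
    rng = np.random.default_rng(5)
    ref = Sequence("ref", random_dna(rng, 300))
    q = Sequence("q", ref.residues[100:200])
    chunk = split_reference(ref, 300, 0)[0]
    spill = str(tmp_path / "spill")
    inters, _ = map_task(chunk, [q], scheme, SeedParams(), spill_dir=spill)
    files = os.listdir(spill)
    assert len(files) == 1
    with open(os.path.join(spill, files[0])) as fh:
        lines = [json.loads(line) for line in fh]
    assert lines[0]["km"] == ["q", chunk.key]
    assert len(lines[0]["vm"]) == len(inters[0].records)


# -- shuffle and reduce --------------------------------------------------


def test_shuffle_sort_grouping_and_tiebreak():
    from seedwave.mapreduce import IntermediateRecord

    a = _rec(r0=5, score=10.0, chunk="c1")
    b = _rec(r0=5, score=20.0, chunk="c2")
    c = _rec(r0=5, score=10.0, chunk="c0")
    inters = [
        IntermediateRecord("q", "c1", (a,)),
        IntermediateRecord("q", "c2", (b,)),
        IntermediateRecord("q", "c0", (c,)),
    ]
    grouped = shuffle_sort(inters)
    assert list(grouped) == ["q"]
    assert grouped["q"] == [b, c, a]  # higher score first, then chunk id
    assert shuffle_sort([]) == {}


def test_shuffle_sort_permutation_invariance():
    from seedwave.mapreduce import IntermediateRecord

    rng = np.random.default_rng(6)
    inters = [
        IntermediateRecord(
            f"q{i % 3}",
            f"c{i}",
            tuple(
                _rec(query=f"q{i % 3}", r0=int(rng.integers(0, 50)),
                     score=float(rng.integers(1, 30)), chunk=f"c{i}")
                for _ in range(3)
            ),
        )
        for i in range(6)
    ]
    base = shuffle_sort(inters)
    for _ in range(5):
        perm = list(inters)
        rng.shuffle(perm)
        assert shuffle_sort(perm) == base


def test_reduce_duplicate_collapse():
    a = _rec(chunk="c0")
    b = _rec(chunk="c1")  # identical apart from source chunk
    assert len(reduce_task([a, b])) == 1


def test_reduce_disjoint_retained():
    a = _rec(r0=0, r1=10)
    b = _rec(r0=50, r1=60, q0=20, q1=30)
    assert len(reduce_task([a, b])) == 2


def test_reduce_overlap_rule_spec_example():
    a = _rec(r0=0, r1=100, score=50.0, ops="100=")
    b = _rec(r0=10, r1=100, q0=1, q1=91, score=40.0, ops="90=")  # 90% overlap
    kept = reduce_task([a, b], redundancy_fraction=0.5)
    assert kept == [a]
    # opposite strands never conflict
    c = _rec(r0=10, r1=100, q0=1, q1=91, score=40.0, ops="90=", strand="-")
    assert len(reduce_task([a, c], redundancy_fraction=0.5)) == 2


def _reference_reduce(group, frac):
    """Independent restatement of the greedy rule for small groups."""
    kept = []
    seen = set()
    for rec in group:
        if rec.identity_key() in seen:
            continue
        ok = True
        for k in kept:
            if k.strand != rec.strand:
                continue
            ov = min(k.r_end, rec.r_end) - max(k.r_start, rec.r_start)
            short = min(k.r_end - k.r_start, rec.r_end - rec.r_start)
            if short > 0 and ov / short > frac:
                ok = False
        if ok:
            kept.append(rec)
            seen.add(rec.identity_key())
    return kept


def test_reduce_matches_reference_on_random_small_groups():
    rng = np.random.default_rng(7)
    for _ in range(40):
        group = sorted(
            (
                _rec(
                    r0=(s := int(rng.integers(0, 40))),
                    r1=s + int(rng.integers(1, 30)),
                    q0=0,
                    q1=int(rng.integers(1, 30)),
                    strand="+" if rng.random() < 0.7 else "-",
                    score=float(rng.integers(1, 50)),
                    ops=f"{int(rng.integers(1, 30))}=",
                    chunk=f"c{int(rng.integers(0, 3))}",
                )
                for _ in range(int(rng.integers(0, 10)))
            ),
            key=lambda r: (r.r_start, -r.score, r.chunk_id),
        )
        frac = float(rng.choice([0.0, 0.3, 0.5, 1.0]))
        assert reduce_task(group, frac) == _reference_reduce(group, frac)


# -- makespans -----------------------------------------------------------


def test_makespan_summary_spec_example():
    report = MakespanReport(
        map_workers=[MapWorkerTiming(0, total=2.0), MapWorkerTiming(1, total=4.0)],
        reduce_workers=[ReduceWorkerTiming(0, total=1.0),
                        ReduceWorkerTiming(1, total=1.0)],
    )
    s = makespan_summary(report)
    assert s == {"t_map": 3.0, "t_reduce": 1.0, "total": 4.0}


def test_makespan_summary_single_worker_and_empty():
    report = MakespanReport(map_workers=[MapWorkerTiming(0, total=5.0)])
    s = makespan_summary(report)
    assert s["t_map"] == 5.0 and s["t_reduce"] == 0.0 and s["total"] == 5.0
    with pytest.raises(ValueError):
        makespan_summary(MakespanReport())


def test_run_config_validation():
    with pytest.raises(ValueError):
        RunConfig(workers=0)
    with pytest.raises(ValueError):
        RunConfig(redundancy_fraction=1.5)


# -- pipeline ------------------------------------------------------------


def _fixture(seed, ref_len=900, n_reads=2, read_len=110):
    from seedwave.simulate import generate_reference, sample_reads

    ref = generate_reference(ref_len, 0.5, seed)
    reads, _ = sample_reads(ref, n_reads, read_len, 0.02, 0.0, 0.0, 0.5, seed + 1)
    return ref, reads


def test_pipeline_degenerate_equals_direct_call(scheme):
    ref, reads = _fixture(50)
    config = RunConfig(chunk_len=2000, overlap=0)  # single chunk
    finals, report = run_pipeline(ref, reads, config)
    direct = []
    for q in reads:
        direct.extend(align_long_read(q, ref, config.scoring, config.seeding))
    from seedwave.mapreduce import IntermediateRecord

    inters = [IntermediateRecord(q.name, "ref:00000",
                                 tuple(r for r in direct if r.query == q.name))
              for q in reads]
    expected = []
    for qid, group in shuffle_sort(inters).items():
        expected.extend(reduce_task(group, config.redundancy_fraction))
    assert _norm(finals) == _norm(expected)
    s = makespan_summary(report)
    assert s["total"] == pytest.approx(s["t_map"] + s["t_reduce"])


def test_pipeline_worker_invariance(scheme):
    ref, reads = _fixture(51)
    base = dict(chunk_len=400, overlap=150)
    out = {}
    for w in (1, 2, 4):
        finals, _ = run_pipeline(ref, reads, RunConfig(workers=w, **base))
        out[w] = _norm(finals)
    assert out[1] == out[2] == out[4]


def test_pipeline_chunked_vs_unchunked(scheme):
    ref, reads = _fixture(52)
    chunked, _ = run_pipeline(ref, reads, RunConfig(chunk_len=400, overlap=150))
    unchunked, _ = run_pipeline(ref, reads, RunConfig(chunk_len=10_000, overlap=0))
    assert _norm(chunked) == _norm(unchunked)


def test_pipeline_early_reduce_invariance(scheme):
    ref, reads = _fixture(53)
    on, _ = run_pipeline(ref, reads,
                         RunConfig(chunk_len=400, overlap=150, early_reduce=True))
    off, _ = run_pipeline(ref, reads,
                          RunConfig(chunk_len=400, overlap=150, early_reduce=False))
    assert _norm(on) == _norm(off)


def test_pipeline_overlap_zone_alignment_appears_once(scheme):
    rng = np.random.default_rng(54)
    ref = Sequence("ref", random_dna(rng, 800))
    q = Sequence("q", ref.residues[350:450])  # wholly inside [300,500) overlap
    finals, _ = run_pipeline(ref, [q], RunConfig(chunk_len=500, overlap=200))
    spans = [f for f in finals if (f.r_start, f.r_end) == (350, 450)]
    assert len(spans) == 1


def test_pipeline_report_timing_consistency(scheme):
    ref, reads = _fixture(55)
    _, report = run_pipeline(ref, reads, RunConfig(chunk_len=400, overlap=150))
    for t in report.map_workers:
        parts = t.get_data + t.query_split + t.align + t.store
        assert t.total == pytest.approx(parts)
    for t in report.reduce_workers:
        assert t.total == pytest.approx(t.get_data + t.fn + t.store)
    doc = json.loads(report.to_json())
    assert set(doc) == {"map_workers", "reduce_workers", "wall_total", "summary"}
    assert doc["wall_total"] > 0.0


def test_pipeline_task_error_names_chunk(scheme):
    ref = Sequence("ref", "ACGT" * 100)
    bad = Sequence("q", "")  # empty query -> align_long_read raises
    with pytest.raises(RuntimeError, match="map task failed for chunk"):
        run_pipeline(ref, [bad], RunConfig(chunk_len=1000, overlap=0))
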