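# seedwave

A long-read DNA aligner built from first principles: an FM-index / prefix-DAWG
seeding stage, an exact affine-gap Smith–Waterman kernel with a bit-identical
wavefront (anti-diagonal) parallel fill, and a MapReduce-style pipeline that
splits the reference into overlapping chunks, aligns in parallel map tasks,
and merges redundant hits in a reduce step with per-phase makespan accounting.

## How it works

1. **Indexing** (`seedwave.index`) — a suffix array built by prefix doubling
   over the sentinel-terminated reference, from which an FM-index (BWT,
   occurrence table, symbol counts) supports O(1)-per-symbol backward search.
   The *query* is compiled into a prefix DAWG: states are suffix-array
   intervals of the query itself, so repeated query substrings are visited
   once.
2. **Seeding** (`seedwave.seeding`) — a dynamic program over the product of
   the query DAWG and the implicit suffix trie of the reference FM-index,
   using the same affine-gap recurrences as Smith–Waterman. With its pruning
   heuristics switched off this DP provably finds the full Smith–Waterman
   optimum; with defaults it emits short high-scoring seed pairs which are
   deduplicated, thinned per diagonal band, and extended.
3. **Extension** (`seedwave.sw`) — exact Gotoh affine-gap local alignment
   (match 1, mismatch −3, gap open 5, gap extend 2). The wavefront fill
   processes anti-diagonals in contiguous per-diagonal buffers split across
   lanes; its matrices and tracebacks are bit-identical to the serial fill
   and faster in practice. Seeds are extended inside an adaptive window
   (full query × a reference diagonal band) that doubles only when the
   alignment touches a window edge.
4. **Pipeline** (`seedwave.mapreduce`) — the reference is split into
   overlapping chunks; each map task aligns every read against one chunk,
   recording per-phase timings (get data, query split, align, store); a
   shuffle sort orders intermediate records deterministically and a greedy
   reduce drops duplicates from overlap zones and dominated same-strand
   overlaps. Final output is invariant to worker count, chunking, and
   early-reduce mode.

## Command line

```sh
seedwave simulate --length 2000 --n-reads 3 --read-len 300 --sub-rate 0.02 \
    --seed 7 --out-prefix demo
seedwave align --ref demo.ref.fa --query demo.reads.fa
```

prints (real output):

```
#query	q_start	q_end	ref	r_start	r_end	strand	score	ops	chunk_id
read00000	0	301	ref	1223	1523	+	267.0	11=1X39=1X10=1X35=1X71=1I34=1X18=1X64=1X11=	ref:00000
read00001	0	300	ref	783	1083	+	256.0	43=1X6=2I51=2D21=1X2=1X64=1X3=1X22=1X28=1X51=	ref:00000
read00002	0	297	ref	378	678	-	284.0	71=1X22=3D203=	ref:00000
```

Other commands:

- `seedwave index --ref ref.fa --out ref.idx.json` — serialize the FM-index.
- `seedwave sw --a ACGTTGCA --b ACGTGCA` → `{"score": 4.0, "a_interval":
  [0, 4], "b_interval": [0, 4], "ops": "4="}` (a local alignment keeps the
  exact 4-mer rather than paying the gap-open cost).
- `seedwave align ... --format sam --out out.sam` — SAM output via pysam
  (FLAG 16 for reverse strand, `{=,X,I,D}` CIGARs, `AS`/`ZS`/`ZE` tags).
- `seedwave align ... --workers 4 --log run.json` — parallel map tasks and a
  JSON makespan report.
- `seedwave bench` — timing and agreement smoke checks.

Exit codes: 0 success, 1 usage error, 2 runtime error.

## Python API

```python
from seedwave import RunConfig, run_pipeline
from seedwave.simulate import generate_reference, sample_reads

ref = generate_reference(50_000, gc_fraction=0.5, seed=1)
reads, truths = sample_reads(ref, 10, 1000, sub_rate=0.02, seed=2)
finals, report = run_pipeline(ref, reads, RunConfig(workers=2))
```

## Reproduction

```sh
python -m pytest -o addopts= -p no:cacheprovider -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The test suite includes `tests/test_acceptance.py`, one test per acceptance
property: Smith–Waterman scores against exhaustive path enumeration,
wavefront/serial bit-identity, suffix-array and backward-search oracles,
seeding-DP/Smith–Waterman equivalence with heuristics off, pipeline output
invariance, ≥95 % origin recovery for 100 mutated 1 kb reads from a 50 kb
reference, and makespan/wavefront performance identities. The acceptance
script reports the same quantities as fractions/percentages in JSON; with
`--seed 1` every agreement fraction is 1.0 and read recovery is 100 %.

See `docs/methods.md` for algorithmic details and design decisions.
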