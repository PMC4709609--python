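# Methods

This document specifies the algorithms implemented in `seedwave` precisely
enough to reimplement them, and records the design decisions behind the
heuristics.

## Notation

The reference is `R` (length `m`), a query read is `Q` (length `n`), both
over `{A,C,G,T,N}`. Coordinates are 0-based, intervals half-open. The
scoring scheme is `match = 1`, `mismatch = −3`, `gap_open = 5`,
`gap_extend = 2`; a gap of length `k` costs `gap_open + (k−1)·gap_extend`.
`N` never matches anything, including another `N`.

## Affine-gap local alignment (`seedwave.sw`)

Gotoh three-matrix recurrence over `(a, b) ∈ [1, |A|] × [1, |B|]`:

```
I[a,b] = max(I[a,b−1] − gap_extend, Z[a,b−1] − gap_open)   # gap in A
J[a,b] = max(J[a−1,b] − gap_extend, Z[a−1,b] − gap_open)   # gap in B
Z[a,b] = max(0, Z[a−1,b−1] + s(A[a],B[b]), I[a,b], J[a,b])
```

Row-0/column-0 boundaries: `Z = 0`, `I = J = −∞` (−1e30 in practice, so a
fresh gap can never open off the border). Traceback starts at the smallest
`(row, col)` cell attaining the best score and prefers diagonal over `J`
(read insertion, CIGAR `I`) over `I` (deletion, `D`); it stops at the first
zero. CIGARs use `{=, X, I, D}`.

Both fills are Numba-compiled over int64-encoded symbols. The inner cell
function is forced inline (`inline="always"`); as a real compiled call it
dominated the serial fill.

### Wavefront fill

Anti-diagonal `d` holds cells `{(a, d−a)}`; every cell on `d` depends only
on diagonals `d−1` (left/up) and `d−2` (diagonal), so the fill computes all
cells of `d−1` and `d−2` before any cell of `d`, and splits each diagonal
into `lanes` contiguous blocks.

A naive strided walk over the full matrices was ~1.7× *slower* than the
serial fill (cache/TLB thrashing on column-strided loads). The implemented
version keeps four contiguous length-(|A|+1) buffers indexed by row `a` —
`z1, i1, j1` for diagonal `d−1` and `z2` for `d−2` — so every recurrence
*read* is contiguous; only the result stores into `Z/I/J` are strided, and
buffers rotate after each diagonal. Per-cell arithmetic is unchanged, so the
matrices are bit-identical to the serial fill for any lane count (verified
exhaustively in the tests), and the fill is ~2× faster at 2000×2000.

## Index structures (`seedwave.index`)

- **Suffix array** by numpy prefix doubling on the sentinel-terminated text
  (`$` sorts before `A..Z`).
- **FM-index**: `bwt[i] = text[(sa[i] − 1) mod n]`; `counts[c]` = number of
  text symbols strictly smaller than `c`; `occ(c, k)` = occurrences of `c`
  in `bwt[:k]`. Backward extension of interval `[lo, hi)` by symbol `c` is
  `[counts[c] + occ(c, lo), counts[c] + occ(c, hi))`. An LF-mapping walk
  starting at row 0 (the rank of the sentinel suffix) reconstructs the text.
  Serializable to versioned JSON.
- **Prefix DAWG of the query**: states are suffix-array intervals of the
  query's own FM-index, built by BFS over backward extensions and
  deduplicated on interval. Two substrings share a state exactly when they
  have the same set of occurrence start positions (e.g. `AN` and `ANA` in
  `ANA`); each state records its minimum accepted length. Node count is
  bounded by `2·|Q|`; nodes are emitted in reverse postorder (topological
  for the seeding DP).

## Seeding DP (`seedwave.seeding`)

The DP aligns the query DAWG against the implicit suffix trie of the
reference FM-index (trie nodes = SA intervals) with the same affine
recurrence, processing reference-trie levels in increasing depth per DAWG
node and storing only positive-score states (a dominated or non-positive
state can never seed the optimum, by the same argument that lets local SW
clamp at zero). A state emits a seed-interval pair when its match score
`E ≥ min_seed_score` and its SA interval width `≤ max_interval_width`.

With heuristics disabled (`max_interval_width = 10⁹`, `min_seed_score =
None` → one match, `max_seed_len = None`, `seed_diag_bucket = 0`), the best
pair score equals the full Smith–Waterman optimum; this exactness is a
tested invariant.

### Default heuristics (all off-switchable via `SeedParams`)

Measured on 300 bp reads vs a 5 kb reference unless noted:

- `max_seed_len = 50`: caps DP reference depth. Uncapped, state count
  explodes (1.07 M states, 21 s/read); capped, 0.03 s. Seeds only need to
  anchor extensions.
- `min_seed_score = 20`: roughly a clean 20-mer. At the exactness threshold
  (score 1) thousands of spurious ~7 bp seeds made alignment ~3× slower.
- Diagonal-band thinning (`seed_diag_band = 32`, `seed_diag_bucket = 500`):
  keeps the best seed per (diagonal band, reference bucket). Gap states
  shift a hit's diagonal by ±1 per gap column, so one true locus litters a
  band of adjacent diagonals — banding collapses ~21 000 pairs across 186
  adjacent diagonals into a handful of extensions.
- Covered-seed skip: a seed lying inside an already-reported alignment's
  query and reference span on the same diagonal band (±32) is not
  re-extended.

### Extension window

Each surviving seed is extended by full Smith–Waterman (wavefront fill)
inside a window of the *entire query* × the reference band
`[diag − w, diag + n + w]` where `diag = r_pos − q_pos` and
`w = extension_window` (default 100). `w` doubles only while the alignment
touches a padded reference edge. An earlier design that grew the window
only when the alignment abutted the edge was fragile: a profitable
continuation that begins with mismatches can end strictly inside the edge,
so the window never grew and a truncated alignment was reported (caught by
a pipeline chunked-vs-unchunked invariance test).

Alignments scoring below `min_report_score` (default 30) are dropped;
reverse-strand hits are computed on the reverse complement and reported in
forward reference coordinates with query coordinates re-mapped.

## MapReduce pipeline (`seedwave.mapreduce`)

- **Split**: the reference is cut into chunks of `chunk_len` (default
  100 000) stepping by `chunk_len − overlap` (default overlap 10 000), keyed
  `name:00000, name:00001, …`. Any alignment shorter than the overlap is
  fully contained in at least one chunk.
- **Map**: one task per chunk aligns every read (both strands by default)
  and re-bases coordinates to global reference positions, timing four
  phases: get data, query split, align, store. Tasks can spill intermediate
  records as JSONL. With `workers > 1` tasks run in a
  `ProcessPoolExecutor`; results are collected by task index so ordering is
  deterministic.
- **Shuffle**: intermediate records sort by
  `(r_start, −score, chunk_id, strand, q_start, r_end, ops)` — a total
  order, so output is invariant under input permutation.
- **Reduce**: greedy sweep that drops exact duplicates (identical alignment
  from two overlapping chunks) and same-strand overlaps where the shorter
  record is covered beyond `redundancy_fraction` (default 0.5) by a
  better-scoring one. `early_reduce` runs the same function per chunk first;
  final output is identical either way.
- **Makespan**: per-worker phase timings; the summary reports the mean map
  worker total `t_map`, mean reduce total `t_reduce`, and
  `total = t_map + t_reduce` (VM-setup term fixed at zero for local runs).

Tested invariances: final records identical for workers ∈ {1, 2, 4},
chunked (overlap ≥ max alignment span) vs unchunked, and early-reduce
on/off.

## Simulation (`seedwave.simulate`)

Deterministic per seed. References are i.i.d. draws honoring a GC fraction.
Reads are uniform slices mutated by per-position substitution (forced to a
different base) and insertion/deletion events with geometric(½) lengths,
then reverse-complemented with probability `strand_mix`. Truth records
carry the originating interval, strand, and the exact edit list, so
`apply_edits` round-trips every read.

## Verification summary

- SW scores equal exhaustive affine-gap path enumeration on thousands of
  short pairs (alphabet incl. `N`).
- Wavefront matrices/tracebacks bit-identical to serial for lanes
  {1, 2, 4, 8}; ≥1.8× faster at 2000×2000 (acceptance bound: ≤1.1× serial
  time).
- Suffix arrays and backward-search widths match naive oracles on random
  texts; LF walks reconstruct the text.
- Heuristics-off seeding DP equals full SW on random query/reference pairs.
- Pipeline output invariant to parallelism and chunking.
- 100/100 mutated 1 kb reads (2 % substitutions, 0.5 % indels, mixed
  strands) from a 50 kb reference recover their true origin within ±20 bp
  on the correct strand.
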