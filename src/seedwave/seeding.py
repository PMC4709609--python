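"""Seed-and-extend alignment: DP over DAWG(query) x prefix-trie(reference).

The seeding dynamic programme walks the query prefix DAWG in topological
(reverse-postorder) order while lazily expanding reference prefix-trie
nodes by FM-index backward extension.  Each state pairs a DAWG node ``a``
with a trie node (a reference substring) and carries the three affine-gap
scores

    E  best score over all leftmost-column choices (the Z analogue),
    F  best score with the leftmost column a gap in the reference
       (query symbol consumed), and
    K  best score with the leftmost column a gap in the query,

with the usual affine charges (``gap_open`` for the first gapped column,
``gap_extend`` per further column, identical to the SW matrices).  Only
strictly positive values are ever stored: a partial alignment whose
running score has dropped to zero or below is dominated by its own suffix,
so discarding it never changes any retained maximum (the argument that
lets Smith-Waterman clamp at zero).  States whose score passes the seed
threshold and whose trie interval is narrow enough become seed interval
pairs; the suffix arrays of both sequences turn those into concrete seeds,
which a windowed Smith-Waterman extends into alignment records.

Seeds are anchors, not alignments, so by default the DP is bounded to
short states (``max_seed_len``): without a bound, one strong long match
surrounds itself with a halo of positive gap/mismatch states whose size
approaches full-matrix SW, defeating the purpose of seeding.  Setting
``max_seed_len=None`` (and widening the other thresholds) disables every
heuristic, in which case the best DP score provably equals the best local
SW score.
"""

from __future__ import annotations

from dataclasses import dataclass

from .index import FmIndex, PrefixDawg, SaInterval, build_prefix_dawg
from .records import AlignmentRecord
from .sequence import SENTINEL, Sequence, ensure_sentinel, reverse_complement
from .sw import ScoringScheme, sw_align

__all__ = [
    "SeedParams",
    "SeedIntervalPair",
    "Seed",
    "bwasw_dp",
    "seeds_from_pairs",
    "thin_seeds",
    "extend_seed",
    "align_long_read",
]


@dataclass(frozen=True)
class SeedParams:
    """Seeding and extension thresholds.

    max_interval_width  largest reference-interval width a seed pair may
                        have (occurrences of the seed string in the chunk);
    min_seed_score      smallest DP score that forms a seed pair; the
                        default (20, about a 20 bp clean anchor) makes a
                        random chunk-sized chance seed vanishingly
                        unlikely while reads at a few percent error still
                        carry many qualifying stretches;
    max_seed_len        DP states are not extended beyond this anchor
                        length on either sequence (None = unbounded);
    seed_diag_bucket    before extension, keep one best seed per
                        (diagonal band, reference bucket of this size)
                        (0 = keep every seed);
    seed_diag_band      width of the diagonal bands used by that
                        thinning; nearby diagonals collapse because gap
                        states shift an anchor's diagonal by one per gap
                        column, so one strong match litters a band of
                        adjacent diagonals with sub-anchors that all
                        extend to the same alignment;
    extension_window    flanking length, in bp, of the Smith-Waterman
                        window around a seed;
    min_report_score    smallest score of a reported alignment record;
    adaptive_window     extend inside a window spanning the whole query
                        and the seed's reference diagonal band padded by
                        extension_window (doubled if the alignment hits
                        the padded edge), so long alignments are never
                        truncated; off = the fixed flanking window.
    """

    max_interval_width: int = 3
    min_seed_score: float | None = 20.0
    max_seed_len: int | None = 50
    seed_diag_bucket: int = 500
    seed_diag_band: int = 32
    extension_window: int = 100
    min_report_score: float = 30.0
    adaptive_window: bool = True

    def __post_init__(self):
        if self.max_interval_width < 1:
            raise ValueError("max_interval_width must be positive")
        if self.min_seed_score is not None and self.min_seed_score <= 0:
            raise ValueError("min_seed_score must be positive")
        if self.max_seed_len is not None and self.max_seed_len < 1:
            raise ValueError("max_seed_len must be positive or None")
        if self.seed_diag_bucket < 0:
            raise ValueError("seed_diag_bucket must be nonnegative")
        if self.seed_diag_band < 1:
            raise ValueError("seed_diag_band must be positive")
        if self.extension_window < 1:
            raise ValueError("extension_window must be positive")

    def resolved_min_seed_score(self, scheme: ScoringScheme) -> float:
        return self.min_seed_score if self.min_seed_score is not None else scheme.match


@dataclass(frozen=True)
class SeedIntervalPair:
    """A (DAWG node, reference trie node) state that passed the thresholds."""

    dawg_node: int
    trie_interval: SaInterval
    score: float
    ref_len: int


@dataclass(frozen=True)
class Seed:
    """A concrete anchor: query start, reference start, matched span."""

    q_pos: int
    r_pos: int
    length: int
    score: float


def bwasw_dp(
    dawg: PrefixDawg,
    index: FmIndex,
    scheme: ScoringScheme,
    params: SeedParams,
) -> list[SeedIntervalPair]:
    """Collect seed interval pairs from the DAWG x trie dynamic programme.

    With the heuristics disabled (``max_seed_len=None``, huge
    ``max_interval_width``, tiny ``min_seed_score``) the best pair score
    equals the best local SW score between query and reference under the
    same scheme.
    """
    go = float(scheme.gap_open)
    ge = float(scheme.gap_extend)
    match = float(scheme.match)
    mismatch = float(scheme.mismatch)
    min_seed = params.resolved_min_seed_score(scheme)
    max_width = params.max_interval_width
    n = index.n
    cap = params.max_seed_len
    rl_cap = cap if cap is not None else n  # ref strings never exceed the text

    counts = index._counts
    occs = index._occ
    letters = [s for s in index.symbols if s != SENTINEL]
    edge_symbols = {sym for trans in dawg.transitions for sym in trans}
    ext_for = {
        x: [
            (counts[y], occs[y], match if (x == y and x != "N") else mismatch)
            for y in letters
        ]
        for x in edge_symbols
    }
    plain_ext = [(counts[y], occs[y]) for y in letters]

    NEG = float("-inf")
    root = dawg.root
    min_len = dawg.min_len
    # state key packs (lo * (n+1) + hi); value = [E, F, K, lo, hi, rlen]
    n1 = n + 1
    tables: list[dict[int, list[float]] | None] = [None] * len(dawg)
    tables[root] = {0 * n1 + n: [0.0, NEG, NEG, 0, n, 0]}
    pending_children = [len(t) for t in dawg.transitions]
    pairs: list[SeedIntervalPair] = []

    for a in dawg.order:
        if a == root:
            continue
        if cap is not None and min_len[a] > cap:
            tables[a] = {}
            # release parents regardless, so memory stays bounded
            for ap, _x in dawg.parents[a]:
                pending_children[ap] -= 1
                if pending_children[ap] == 0 and ap != root:
                    tables[ap] = None
            continue
        acc: dict[int, list[float]] = {}
        levels: list[list[int]] = [[] for _ in range(rl_cap + 2)]
        acc_get = acc.get
        for ap, x in dawg.parents[a]:
            tab = tables[ap]
            if not tab:
                continue
            exts = ext_for[x]
            for key, st in tab.items():
                E = st[0]
                # gap in the reference: consume query symbol x, same trie node
                f = st[1] - ge
                f2 = E - go
                if f2 > f:
                    f = f2
                lo = st[3]
                hi = st[4]
                rl = st[5]
                if f > 0.0:
                    ent = acc_get(key)
                    if ent is None:
                        acc[key] = [NEG, f, NEG, lo, hi, rl]
                        levels[rl].append(key)
                    elif f > ent[1]:
                        ent[1] = f
                # diagonal: consume x and one reference symbol
                if rl < rl_cap:
                    rl1 = rl + 1
                    for cy, oy, sxy in exts:
                        ed = E + sxy
                        if ed <= 0.0:
                            continue
                        lo2 = cy + oy[lo]
                        hi2 = cy + oy[hi]
                        if lo2 < hi2:
                            key2 = lo2 * n1 + hi2
                            ent = acc_get(key2)
                            if ent is None:
                                acc[key2] = [ed, NEG, NEG, lo2, hi2, rl1]
                                levels[rl1].append(key2)
                            elif ed > ent[0]:
                                ent[0] = ed

        table: dict[int, list[float]] = {}
        if acc:
            for rl in range(rl_cap + 1):
                bucket = levels[rl]
                if not bucket:
                    continue
                rl1 = rl + 1
                for key in bucket:
                    ent = acc[key]
                    E = ent[0]
                    if ent[1] > E:
                        E = ent[1]
                    if ent[2] > E:
                        E = ent[2]
                    ent[0] = E
                    table[key] = ent
                    lo = ent[3]
                    hi = ent[4]
                    if E >= min_seed and hi - lo <= max_width:
                        pairs.append(SeedIntervalPair(a, SaInterval(lo, hi), E, rl))
                    if rl >= rl_cap:
                        continue
                    # gap in the query: consume one reference symbol
                    k = ent[2] - ge
                    k2 = E - go
                    if k2 > k:
                        k = k2
                    if k > 0.0:
                        for cy, oy in plain_ext:
                            lo2 = cy + oy[lo]
                            hi2 = cy + oy[hi]
                            if lo2 < hi2:
                                key2 = lo2 * n1 + hi2
                                ent2 = acc_get(key2)
                                if ent2 is None:
                                    acc[key2] = [NEG, NEG, k, lo2, hi2, rl1]
                                    levels[rl1].append(key2)
                                elif k > ent2[2]:
                                    ent2[2] = k
        tables[a] = table
        for ap, _x in dawg.parents[a]:
            pending_children[ap] -= 1
            if pending_children[ap] == 0 and ap != root:
                tables[ap] = None
    return pairs


def seeds_from_pairs(
    pairs: list[SeedIntervalPair], index: FmIndex, dawg: PrefixDawg
) -> list[Seed]:
    """Expand interval pairs into concrete (q_pos, r_pos) seeds.

    Reference positions come from locating the trie interval in the
    reference suffix array; query positions from the DAWG node's own
    occurrence set.  Duplicate (q_pos, r_pos) anchors keep the
    highest-scoring pair.
    """
    ordered = sorted(
        pairs,
        key=lambda p: (-p.score, p.dawg_node, p.trie_interval.lo, p.ref_len),
    )
    seen: set[tuple[int, int]] = set()
    seeds: list[Seed] = []
    for pair in ordered:
        q_positions = dawg.positions(pair.dawg_node)
        r_positions = index.locate(pair.trie_interval)
        length = min(dawg.min_len[pair.dawg_node], pair.ref_len)
        for qp in q_positions:
            for rp in r_positions:
                if (qp, rp) in seen:
                    continue
                seen.add((qp, rp))
                seeds.append(Seed(qp, rp, length, pair.score))
    return seeds


def thin_seeds(seeds: list[Seed], bucket: int, band: int = 32) -> list[Seed]:
    """Keep the best seed per (diagonal band, reference bucket).

    Anchors on nearby diagonals within a bucket lead the extension step to
    the same local alignment (each gap column shifts an anchor's diagonal
    by one, so a single strong match spreads sub-anchors over a band of
    adjacent diagonals); keeping one of them (the highest-scoring, then
    the leftmost) trims that quadratic pile-up.  The extension window
    re-discovers the alignment from any surviving anchor in the band.
    ``bucket == 0`` disables thinning.
    """
    if bucket <= 0:
        return list(seeds)
    best: dict[tuple[int, int], Seed] = {}
    for s in sorted(seeds, key=lambda s: (-s.score, -s.length, s.r_pos, s.q_pos)):
        key = ((s.r_pos - s.q_pos) // band, s.r_pos // bucket)
        if key not in best:
            best[key] = s
    return sorted(best.values(), key=lambda s: (s.r_pos, s.q_pos))


def extend_seed(
    seed: Seed,
    q_chunk,
    r_chunk,
    scheme: ScoringScheme,
    params: SeedParams,
) -> AlignmentRecord | None:
    """Smith-Waterman extension of one seed inside a window.

    Returns a record in chunk-local coordinates when the windowed local
    alignment reaches ``min_report_score``.  With ``adaptive_window`` on
    (default) the window spans the whole query and, on the reference, the
    seed's diagonal band padded by ``extension_window`` on both sides, so
    an alignment can never be query-truncated and is reference-truncated
    only when its net indel excursion exceeds the padding (in which case
    the padding doubles and the alignment is retried).  With it off, the
    window is the fixed ``extension_window`` flank around the seed on both
    sequences.
    """
    q = q_chunk.residues if isinstance(q_chunk, Sequence) else str(q_chunk)
    r = r_chunk.residues if isinstance(r_chunk, Sequence) else str(r_chunk)
    w = params.extension_window
    diag = seed.r_pos - seed.q_pos
    while True:
        if params.adaptive_window:
            q_lo, q_hi = 0, len(q)
            r_lo = max(0, diag - w)
            r_hi = min(len(r), diag + len(q) + w)
        else:
            q_lo = max(0, seed.q_pos - w)
            q_hi = min(len(q), seed.q_pos + seed.length + w)
            r_lo = max(0, seed.r_pos - w)
            r_hi = min(len(r), seed.r_pos + seed.length + w)
        # the wavefront fill is bit-identical to the serial one and faster
        aln = sw_align(q[q_lo:q_hi], r[r_lo:r_hi], scheme, mode="wavefront")
        if not params.adaptive_window or aln.is_empty:
            break
        touches = (aln.q1_interval[0] == 0 and r_lo > 0) or (
            aln.q1_interval[1] == r_hi - r_lo and r_hi < len(r)
        )
        if not touches:
            break
        w *= 2
    if aln.is_empty or aln.score < params.min_report_score:
        return None
    q_name = q_chunk.name if isinstance(q_chunk, Sequence) else ""
    r_name = r_chunk.name if isinstance(r_chunk, Sequence) else ""
    return AlignmentRecord(
        query=q_name,
        q_start=q_lo + aln.q0_interval[0],
        q_end=q_lo + aln.q0_interval[1],
        ref=r_name,
        r_start=r_lo + aln.q1_interval[0],
        r_end=r_lo + aln.q1_interval[1],
        strand="+",
        score=aln.score,
        ops=aln.ops,
    )


def align_long_read(
    q_chunk,
    r_chunk,
    scheme: ScoringScheme | None = None,
    params: SeedParams | None = None,
    both_strands: bool = True,
) -> list[AlignmentRecord]:
    """Full seed-and-extend alignment of one query chunk against one
    reference chunk.

    Builds the reference FM-index once, then for each strand builds the
    query prefix DAWG, runs the seeding DP, expands and thins seeds and
    extends them.  Reverse-strand records carry query coordinates in the
    forward (read) orientation.  Exact duplicate records collapse; output
    is sorted by (r_start, -score).
    """
    scheme = scheme or ScoringScheme()
    params = params or SeedParams()
    q = q_chunk if isinstance(q_chunk, Sequence) else Sequence("query", str(q_chunk))
    r = r_chunk if isinstance(r_chunk, Sequence) else Sequence("ref", str(r_chunk))
    if not len(q) or not len(r):
        raise ValueError("chunks must be nonempty")
    index = FmIndex(ensure_sentinel(r.residues), name=r.name)
    strands = [("+", q.residues)]
    if both_strands:
        strands.append(("-", reverse_complement(q.residues)))
    out: dict[tuple, AlignmentRecord] = {}
    for strand, qres in strands:
        dawg = build_prefix_dawg(qres)
        pairs = bwasw_dp(dawg, index, scheme, params)
        seeds = thin_seeds(
            seeds_from_pairs(pairs, index, dawg),
            params.seed_diag_bucket,
            params.seed_diag_band,
        )
        oriented = Sequence(q.name, qres)
        covered: list[tuple[int, int, int, int, int]] = []
        band = params.seed_diag_band
        for seed in seeds:
            # a seed sitting inside an already-found alignment on (nearly)
            # its diagonal would just re-derive that alignment; skip it
            diag = seed.r_pos - seed.q_pos
            if any(
                q0 <= seed.q_pos and seed.q_pos + seed.length <= q1
                and r0 <= seed.r_pos and seed.r_pos + seed.length <= r1
                and abs(diag - d0) <= band
                for q0, q1, r0, r1, d0 in covered
            ):
                continue
            rec = extend_seed(seed, oriented, r, scheme, params)
            if rec is None:
                continue
            covered.append(
                (rec.q_start, rec.q_end, rec.r_start, rec.r_end,
                 rec.r_start - rec.q_start)
            )
            if strand == "-":
                L = len(qres)
                rec = AlignmentRecord(
                    query=rec.query,
                    q_start=L - rec.q_end,
                    q_end=L - rec.q_start,
                    ref=rec.ref,
                    r_start=rec.r_start,
                    r_end=rec.r_end,
                    strand="-",
                    score=rec.score,
                    ops=rec.ops,
                )
            out.setdefault(rec.identity_key(), rec)
    return sorted(
        out.values(), key=lambda t: (t.r_start, -t.score, t.strand, t.q_start, t.ops)
    )
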