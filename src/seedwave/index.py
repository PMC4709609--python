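"""Text indexes: suffix array, BWT/FM-index, and the query prefix DAWG.

The reference prefix trie is never materialised: each trie node is a
suffix-array interval of the reference index, and child navigation is
FM-index backward extension (prepending one symbol).  The query-side prefix
DAWG is the collapse of the query's own prefix trie: nodes with identical
suffix-array intervals (identical occurrence-start sets) merge, yielding a
suffix-automaton-sized graph that accepts exactly the substrings of the
query.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .sequence import DNA_ALPHABET, SENTINEL, Sequence, ensure_sentinel

__all__ = [
    "SaInterval",
    "build_suffix_array",
    "FmIndex",
    "build_fm_index",
    "backward_extend",
    "locate",
    "PrefixDawg",
    "build_prefix_dawg",
]


def _residues(seq) -> str:
    return seq.residues if isinstance(seq, Sequence) else str(seq)


@dataclass(frozen=True)
class SaInterval:
    """Half-open rank interval [lo, hi) of suffix-array rows sharing a prefix.

    Width equals the number of occurrences of the represented string; an
    empty interval (lo == hi) means the string does not occur.
    """

    lo: int
    hi: int

    @property
    def width(self) -> int:
        return self.hi - self.lo

    @property
    def is_empty(self) -> bool:
        return self.hi <= self.lo


def _suffix_array_codes(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), numpy lexsort)."""
    n = codes.size
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = np.unique(codes, return_inverse=True)[1].astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        diff = np.empty(n, dtype=np.int64)
        diff[0] = 0
        diff[1:] = (rank[sa][1:] != rank[sa][:-1]) | (key2[sa][1:] != key2[sa][:-1])
        ranks_sorted = np.cumsum(diff)
        if ranks_sorted[-1] == n - 1:
            break
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[sa] = ranks_sorted
        rank = new_rank
        k *= 2
        if k >= n:
            break
    return sa


def _validate_indexable(text: str) -> None:
    if not text.endswith(SENTINEL):
        raise ValueError("indexed text must be sentinel-terminated ('$')")
    if SENTINEL in text[:-1]:
        raise ValueError("sentinel '$' must occur exactly once, at the end")
    if len(text) < 2:
        raise ValueError("indexed text must be nonempty before the sentinel")
    for pos, ch in enumerate(text[:-1]):
        if not ("A" <= ch <= "Z"):
            raise ValueError(
                f"illegal symbol {ch!r} at position {pos} "
                "(uppercase letters plus terminal '$' only)"
            )


def build_suffix_array(seq) -> list[int]:
    """Suffix array of a sentinel-terminated text.

    Returns the 0-based start positions of all suffixes in lexicographic
    order, with ``$`` collating strictly smallest.
    """
    text = _residues(seq)
    _validate_indexable(text)
    codes = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    # '$' (36) already sorts below 'A'..'Z' in ASCII.
    return _suffix_array_codes(codes.astype(np.int64)).tolist()


class FmIndex:
    """FM-index of a sentinel-terminated text.

    Holds the suffix array (for locating hits), the BWT, per-symbol smaller
    counts and full rank (occ) tables.  Represents the prefix trie of the
    text implicitly: a trie node is an :class:`SaInterval` and its children
    are reached with :meth:`backward_extend`.
    """

    def __init__(self, seq, name: str | None = None):
        text = _residues(seq)
        _validate_indexable(text)
        self.name = name or (seq.name if isinstance(seq, Sequence) else "")
        self.text = text
        self.n = len(text)
        sa = np.asarray(build_suffix_array(text), dtype=np.int64)
        self.sa = sa
        chars = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
        bwt_codes = chars[(sa - 1) % self.n]
        self.bwt = bwt_codes.tobytes().decode("ascii")
        self.symbols = sorted(set(text))
        # symbols queryable even if absent from the text
        self._query_symbols = set(self.symbols) | set(DNA_ALPHABET)
        counts: dict[str, int] = {}
        occ: dict[str, list[int]] = {}
        smaller = 0
        freq = {s: text.count(s) for s in self.symbols}
        for s in self.symbols:
            counts[s] = smaller
            smaller += freq[s]
        for s in self._query_symbols:
            if s in self.symbols:
                cum = np.concatenate(
                    ([0], np.cumsum(bwt_codes == ord(s), dtype=np.int64))
                )
                occ[s] = cum.tolist()
                continue
            counts[s] = self.n  # absent: empty interval at the top
            occ[s] = [0] * (self.n + 1)
        self._counts = counts
        self._occ = occ

    # -- trie navigation -------------------------------------------------
    def full_interval(self) -> SaInterval:
        """Root trie node: the interval of the empty string."""
        return SaInterval(0, self.n)

    def extend(self, interval: SaInterval, symbol: str) -> SaInterval:
        """Backward extension: interval of ``symbol + s`` from interval of s."""
        if symbol not in self._query_symbols:
            raise ValueError(f"symbol {symbol!r} outside the index alphabet")
        c = self._counts[symbol]
        o = self._occ[symbol]
        return SaInterval(c + o[interval.lo], c + o[interval.hi])

    def interval_of(self, s: str) -> SaInterval:
        """Interval of an arbitrary string (folding backward extensions)."""
        iv = self.full_interval()
        for ch in reversed(s):
            iv = self.extend(iv, ch)
            if iv.is_empty:
                break
        return iv

    def locate(self, interval: SaInterval) -> list[int]:
        """Sorted text positions of the interval's occurrences."""
        if interval.lo < 0 or interval.hi > self.n or interval.lo > interval.hi:
            raise ValueError(f"interval {interval} invalid for index of size {self.n}")
        return sorted(self.sa[interval.lo : interval.hi].tolist())

    def occ(self, symbol: str, prefix_len: int) -> int:
        """Occurrences of ``symbol`` in ``bwt[:prefix_len]``."""
        return self._occ[symbol][prefix_len]

    @property
    def counts(self) -> dict[str, int]:
        """For each symbol, the number of strictly smaller symbols in the text."""
        return dict(self._counts)

    # -- serialization ---------------------------------------------------
    FORMAT = "seedwave-fmindex"
    VERSION = 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": self.FORMAT,
                "version": self.VERSION,
                "name": self.name,
                "text": self.text,
                "sa": self.sa.tolist(),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "FmIndex":
        doc = json.loads(payload)
        if doc.get("format") != cls.FORMAT:
            raise ValueError("not a seedwave FM-index container")
        if doc.get("version") != cls.VERSION:
            raise ValueError(f"unsupported index version {doc.get('version')!r}")
        idx = cls(doc["text"], name=doc.get("name", ""))
        if doc.get("sa") != idx.sa.tolist():
            raise ValueError("stored suffix array inconsistent with text")
        return idx


def build_fm_index(seq, name: str | None = None) -> FmIndex:
    """Build the FM-index of a sentinel-terminated sequence."""
    return FmIndex(seq, name=name)


def backward_extend(index: FmIndex, interval: SaInterval, symbol: str) -> SaInterval:
    """Prefix-trie child navigation (module-level convenience)."""
    return index.extend(interval, symbol)


def locate(index: FmIndex, interval: SaInterval) -> list[int]:
    """Text positions of a trie node's occurrences (module-level convenience)."""
    return index.locate(interval)


class PrefixDawg:
    """Prefix DAWG of a query: collapsed prefix-trie over the query's index.

    Nodes are equivalence classes of query substrings sharing one
    suffix-array interval in the query's own FM-index (one occurrence-start
    set).  Edges prepend a symbol, mirroring prefix-trie navigation, so
    :meth:`accepts` reads its argument right to left.  ``order`` lists nodes
    in reverse postorder of a DFS from the root, i.e. topologically (every
    parent precedes its children).
    """

    def __init__(self, query: str, q_index: FmIndex):
        self.query = query
        self.q_index = q_index
        n = q_index.n
        letters = sorted(set(query))
        root_iv = q_index.full_interval()
        key0 = (root_iv.lo, root_iv.hi)
        node_of: dict[tuple[int, int], int] = {key0: 0}
        self.intervals: list[SaInterval] = [root_iv]
        self.min_len: list[int] = [0]
        self.transitions: list[dict[str, int]] = [{}]
        self.parents: list[list[tuple[int, str]]] = [[]]
        frontier = [0]
        while frontier:
            nxt: list[int] = []
            for a in frontier:
                iv = self.intervals[a]
                for ch in letters:
                    child = q_index.extend(iv, ch)
                    if child.is_empty:
                        continue
                    key = (child.lo, child.hi)
                    b = node_of.get(key)
                    if b is None:
                        b = len(self.intervals)
                        node_of[key] = b
                        self.intervals.append(child)
                        self.min_len.append(self.min_len[a] + 1)
                        self.transitions.append({})
                        self.parents.append([])
                        nxt.append(b)
                    self.transitions[a][ch] = b
                    self.parents[b].append((a, ch))
            frontier = nxt
        self.root = 0
        self.order = self._reverse_postorder()

    def _reverse_postorder(self) -> list[int]:
        post: list[int] = []
        seen = [False] * len(self.intervals)
        stack: list[tuple[int, int]] = [(self.root, 0)]
        seen[self.root] = True
        # iterative DFS with deterministic (symbol-sorted) child order
        children = [
            [t[1] for t in sorted(trans.items())] for trans in self.transitions
        ]
        while stack:
            node, i = stack[-1]
            if i < len(children[node]):
                stack[-1] = (node, i + 1)
                c = children[node][i]
                if not seen[c]:
                    seen[c] = True
                    stack.append((c, 0))
            else:
                post.append(node)
                stack.pop()
        post.reverse()
        return post

    def __len__(self) -> int:
        return len(self.intervals)

    def accepts(self, s: str) -> bool:
        """Whether ``s`` is a substring of the query (walked right to left)."""
        node = self.root
        for ch in reversed(s):
            node = self.transitions[node].get(ch)
            if node is None:
                return False
        return True

    def positions(self, node: int) -> list[int]:
        """Sorted query start positions of the node's substrings."""
        return self.q_index.locate(self.intervals[node])


def build_prefix_dawg(query) -> PrefixDawg:
    """Prefix DAWG of a nonempty, sentinel-free query."""
    residues = _residues(query)
    if not residues:
        raise ValueError("query must be nonempty")
    if SENTINEL in residues:
        raise ValueError("query must be sentinel-free")
    q_index = FmIndex(ensure_sentinel(residues))
    return PrefixDawg(residues, q_index)
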