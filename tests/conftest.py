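"""Shared oracles and helpers for the test suite.

Everything here is deliberately naive and independent of the package's own
algorithms: suffix sorting by Python's string sort, substring counting by
scanning, and local affine-gap alignment by exhaustive path enumeration.
"""

from __future__ import annotations

import numpy as np
import pytest

from seedwave.sw import ScoringScheme

BASES = "ACGT"
BASES_N = "ACGTN"


def random_dna(rng: np.random.Generator, n: int, alphabet: str = BASES) -> str:
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(0, len(alphabet), size=n)])


def naive_suffix_array(text: str) -> list[int]:
    """Sort all suffixes lexicographically; '$' (ASCII 36) < 'A'..'Z'."""
    return sorted(range(len(text)), key=lambda i: text[i:])


def naive_count(text: str, s: str) -> int:
    """Occurrences of s in text, overlapping included."""
    if not s:
        return len(text)
    return sum(1 for i in range(len(text) - len(s) + 1) if text[i : i + len(s)] == s)


def naive_substrings(text: str, max_len: int) -> set[str]:
    out: set[str] = set()
    for i in range(len(text)):
        for j in range(i + 1, min(i + max_len, len(text)) + 1):
            out.add(text[i:j])
    return out


def brute_force_local_sw(a: str, b: str, scheme: ScoringScheme) -> float:
    """Best local affine-gap alignment score by exhaustive path enumeration.

    Walks every monotone path through the DP grid from every start cell,
    charging gap_open for the first column of a gap run and gap_extend for
    each further column (a direction switch opens a new gap).  The running
    score is recorded at every step; the empty alignment scores 0.  An
    optimal local alignment never begins with a gap (trimming a leading gap
    raises the score), so paths start with a match/mismatch column.
    """
    match, mismatch = scheme.match, scheme.mismatch
    go, ge = scheme.gap_open, scheme.gap_extend
    la, lb = len(a), len(b)
    best = 0.0

    def walk(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < la and j < lb:
            r = match if (a[i] == b[j] and a[i] != "N") else mismatch
            walk(i + 1, j + 1, score + r, "M")
        if i < la:
            walk(i + 1, j, score - (ge if last == "A" else go), "A")
        if j < lb:
            walk(i, j + 1, score - (ge if last == "B" else go), "B")

    for i0 in range(la):
        for j0 in range(lb):
            r0 = match if (a[i0] == b[j0] and a[i0] != "N") else mismatch
            walk(i0 + 1, j0 + 1, r0, "M")
    return best


def biopython_local_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Independent mid-size oracle via Bio.Align.PairwiseAligner."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = -scheme.gap_open
    aligner.extend_gap_score = -scheme.gap_extend
    if not a or not b:
        return 0.0
    return float(aligner.score(a, b))


@pytest.fixture
def scheme() -> ScoringScheme:
    return ScoringScheme()
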