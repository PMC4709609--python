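"""Affine-gap local alignment: serial and wavefront fills, backtracking.

The similarity matrix Z and the two gap matrices I, J follow the classic
three-state (Gotoh) recurrence:

    Z[a,b] = max(0, Z[a-1,b-1] + R(a,b), I[a,b], J[a,b])
    I[a,b] = max(I[a,b-1] - G_E, Z[a,b-1] - G_F)   (gap in q0, consumes q1)
    J[a,b] = max(J[a-1,b] - G_E, Z[a-1,b] - G_F)   (gap in q1, consumes q0)

so a length-k gap costs G_F + (k-1) * G_E.  The first row and column of Z
are zero; I and J boundaries are an impossible-state surrogate.  The
wavefront fill computes cells anti-diagonal by anti-diagonal (every cell on
diagonal d depends only on diagonals d-1 and d-2), splitting each diagonal
into ``lanes`` contiguous blocks; it is cell-for-cell identical to the
serial fill.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .sequence import Sequence

__all__ = [
    "ScoringScheme",
    "SwMatrices",
    "Alignment",
    "sw_fill_serial",
    "sw_fill_wavefront",
    "sw_backtrack",
    "sw_align",
    "score_cigar",
]

NEG_INF = -1.0e30
_N_CODE = ord("N")


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch values and two-level affine gap penalties.

    Shared by the SW fill and the seeding DP.  ``gap_open`` is the cost of
    the first gapped column (charged when leaving the match state) and
    ``gap_extend`` the cost of each further column, so a length-k gap costs
    ``gap_open + (k - 1) * gap_extend``.  N never matches positively.
    Defaults follow common long-read practice: +1 / -3 / 5 / 2.
    """

    match: float = 1.0
    mismatch: float = -3.0
    gap_open: float = 5.0
    gap_extend: float = 2.0

    def __post_init__(self):
        if not self.match > 0:
            raise ValueError("match score must be positive")
        if not self.mismatch < 0:
            raise ValueError("mismatch score must be negative")
        if not self.gap_open >= self.gap_extend > 0:
            raise ValueError("require gap_open >= gap_extend > 0")

    def score(self, x: str, y: str) -> float:
        """Pairwise symbol score; N is never a positive match."""
        return self.match if (x == y and x != "N") else self.mismatch

    def gap_cost(self, length: int) -> float:
        return self.gap_open + (length - 1) * self.gap_extend if length else 0.0


@dataclass
class SwMatrices:
    """Filled similarity and gap matrices with the best cell."""

    Z: np.ndarray
    I: np.ndarray
    J: np.ndarray
    best_cell: tuple[int, int]
    best_score: float


@dataclass
class Alignment:
    """One local alignment between q0 and q1.

    Intervals are half-open 0-based.  ``ops`` is a CIGAR-compatible string
    over {=, X, I, D}: I consumes q0 only, D consumes q1 only.
    """

    q0_interval: tuple[int, int]
    q1_interval: tuple[int, int]
    ops: str
    score: float

    @property
    def is_empty(self) -> bool:
        return not self.ops


def _residues(seq) -> str:
    return seq.residues if isinstance(seq, Sequence) else str(seq)


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8).astype(np.int64)


@njit(cache=True, inline="always")
def _cell(Z, I, J, c0, c1, a, b, match, mismatch, go, ge, ncode):  # pragma: no cover
    i1 = I[a, b - 1] - ge
    i2 = Z[a, b - 1] - go
    I[a, b] = i1 if i1 > i2 else i2
    j1 = J[a - 1, b] - ge
    j2 = Z[a - 1, b] - go
    J[a, b] = j1 if j1 > j2 else j2
    x = c0[a - 1]
    y = c1[b - 1]
    r = match if (x == y and x != ncode) else mismatch
    z = Z[a - 1, b - 1] + r
    if I[a, b] > z:
        z = I[a, b]
    if J[a, b] > z:
        z = J[a, b]
    if z < 0.0:
        z = 0.0
    Z[a, b] = z


@njit(cache=True)
def _fill_serial(c0, c1, match, mismatch, go, ge, Z, I, J, ncode):  # pragma: no cover
    X = c0.size
    Y = c1.size
    for a in range(1, X + 1):
        for b in range(1, Y + 1):
            _cell(Z, I, J, c0, c1, a, b, match, mismatch, go, ge, ncode)


@njit(cache=True)
def _fill_wavefront(
    c0, c1, match, mismatch, go, ge, Z, I, J, ncode, lanes
):  # pragma: no cover
    # Recurrence reads come from contiguous per-diagonal buffers indexed by
    # row (cell (a, d-a) of diagonal d depends only on diagonals d-1, d-2),
    # so only the result stores walk the matrices with a row stride.  The
    # arithmetic per cell is the same as _cell, hence bit-identical fills.
    X = c0.size
    Y = c1.size
    z1 = np.zeros(X + 1, dtype=np.float64)  # Z on diagonal d-1
    z2 = np.zeros(X + 1, dtype=np.float64)  # Z on diagonal d-2
    i1 = np.full(X + 1, NEG_INF, dtype=np.float64)  # I on diagonal d-1
    j1 = np.full(X + 1, NEG_INF, dtype=np.float64)  # J on diagonal d-1
    z0 = np.empty(X + 1, dtype=np.float64)
    i0 = np.empty(X + 1, dtype=np.float64)
    j0 = np.empty(X + 1, dtype=np.float64)
    for d in range(2, X + Y + 1):
        alo = d - Y
        if alo < 1:
            alo = 1
        ahi = d - 1
        if ahi > X:
            ahi = X
        m = ahi - alo + 1
        if m <= 0:
            continue
        base = m // lanes
        rem = m % lanes
        start = alo
        for lane in range(lanes):
            cnt = base + (1 if lane < rem else 0)
            for a in range(start, start + cnt):
                b = d - a
                if b == 1:
                    i_left = NEG_INF
                    z_left = 0.0
                else:
                    i_left = i1[a]
                    z_left = z1[a]
                if a == 1:
                    j_up = NEG_INF
                    z_up = 0.0
                else:
                    j_up = j1[a - 1]
                    z_up = z1[a - 1]
                if a == 1 or b == 1:
                    z_diag = 0.0
                else:
                    z_diag = z2[a - 1]
                iv1 = i_left - ge
                iv2 = z_left - go
                iv = iv1 if iv1 > iv2 else iv2
                jv1 = j_up - ge
                jv2 = z_up - go
                jv = jv1 if jv1 > jv2 else jv2
                x = c0[a - 1]
                y = c1[b - 1]
                r = match if (x == y and x != ncode) else mismatch
                z = z_diag + r
                if iv > z:
                    z = iv
                if jv > z:
                    z = jv
                if z < 0.0:
                    z = 0.0
                z0[a] = z
                i0[a] = iv
                j0[a] = jv
                Z[a, b] = z
                I[a, b] = iv
                J[a, b] = jv
            start += cnt
        for a in range(alo, ahi + 1):
            z2[a] = z1[a]
            z1[a] = z0[a]
            i1[a] = i0[a]
            j1[a] = j0[a]


def _alloc(X: int, Y: int):
    Z = np.zeros((X + 1, Y + 1), dtype=np.float64)
    I = np.full((X + 1, Y + 1), NEG_INF, dtype=np.float64)
    J = np.full((X + 1, Y + 1), NEG_INF, dtype=np.float64)
    return Z, I, J


def _finish(Z, I, J) -> SwMatrices:
    flat = int(np.argmax(Z))  # row-major argmax = smallest (row, col) tie-break
    cell = np.unravel_index(flat, Z.shape)
    return SwMatrices(Z, I, J, (int(cell[0]), int(cell[1])), float(Z[cell]))


def sw_fill_serial(q0, q1, scheme: ScoringScheme) -> SwMatrices:
    """Row-by-row fill of Z, I, J for two sentinel-free sequences."""
    s0, s1 = _residues(q0), _residues(q1)
    Z, I, J = _alloc(len(s0), len(s1))
    if s0 and s1:
        _fill_serial(
            _encode(s0), _encode(s1),
            float(scheme.match), float(scheme.mismatch),
            float(scheme.gap_open), float(scheme.gap_extend),
            Z, I, J, _N_CODE,
        )
    return _finish(Z, I, J)


def sw_fill_wavefront(q0, q1, scheme: ScoringScheme, lanes: int = 1) -> SwMatrices:
    """Anti-diagonal fill, identical cell-by-cell to the serial fill."""
    if lanes < 1:
        raise ValueError("lanes must be >= 1")
    s0, s1 = _residues(q0), _residues(q1)
    Z, I, J = _alloc(len(s0), len(s1))
    if s0 and s1:
        _fill_wavefront(
            _encode(s0), _encode(s1),
            float(scheme.match), float(scheme.mismatch),
            float(scheme.gap_open), float(scheme.gap_extend),
            Z, I, J, _N_CODE, int(lanes),
        )
    return _finish(Z, I, J)


def _runs_to_cigar(ops: list[str]) -> str:
    out = []
    i = 0
    while i < len(ops):
        j = i
        while j < len(ops) and ops[j] == ops[i]:
            j += 1
        out.append(f"{j - i}{ops[i]}")
        i = j
    return "".join(out)


def sw_backtrack(m: SwMatrices, q0, q1, scheme: ScoringScheme) -> Alignment:
    """Trace the optimal path from the best cell back to a zero cell.

    Tie-break precedence: diagonal > vertical (consume q0) > horizontal
    (consume q1); the best cell itself is the smallest (row, column) among
    maxima of Z.
    """
    s0, s1 = _residues(q0), _residues(q1)
    Z, I, J = m.Z, m.I, m.J
    a, b = m.best_cell
    if m.best_score <= 0.0:
        return Alignment((0, 0), (0, 0), "", 0.0)
    end_a, end_b = a, b
    ops_rev: list[str] = []
    state = "Z"
    while True:
        if state == "Z":
            if Z[a, b] == 0.0:
                break
            if a > 0 and b > 0:
                x, y = s0[a - 1], s1[b - 1]
                r = scheme.score(x, y)
                if Z[a, b] == Z[a - 1, b - 1] + r:
                    ops_rev.append("=" if (x == y and x != "N") else "X")
                    a -= 1
                    b -= 1
                    continue
            if Z[a, b] == J[a, b]:
                state = "J"
            elif Z[a, b] == I[a, b]:
                state = "I"
            else:  # pragma: no cover - fill/backtrack mismatch
                raise AssertionError("inconsistent matrices during backtrack")
        elif state == "J":
            ops_rev.append("I")  # consumes q0
            if J[a, b] == Z[a - 1, b] - scheme.gap_open:
                state = "Z"
            a -= 1
        else:  # state == "I"
            ops_rev.append("D")  # consumes q1
            if I[a, b] == Z[a, b - 1] - scheme.gap_open:
                state = "Z"
            b -= 1
    ops_rev.reverse()
    return Alignment((a, end_a), (b, end_b), _runs_to_cigar(ops_rev), m.best_score)


def sw_align(q0, q1, scheme: ScoringScheme | None = None, mode: str = "serial",
             lanes: int = 1) -> Alignment:
    """Fill and backtrack in one call."""
    scheme = scheme or ScoringScheme()
    if mode == "serial":
        m = sw_fill_serial(q0, q1, scheme)
    elif mode == "wavefront":
        m = sw_fill_wavefront(q0, q1, scheme, lanes=lanes)
    else:
        raise ValueError(f"unknown mode {mode!r} (serial|wavefront)")
    return sw_backtrack(m, q0, q1, scheme)


def score_cigar(ops: str, scheme: ScoringScheme) -> float:
    """Re-score a {=,X,I,D} CIGAR string under a scheme."""
    import re

    total = 0.0
    for count, op in re.findall(r"(\d+)([=XID])", ops):
        k = int(count)
        if op == "=":
            total += k * scheme.match
        elif op == "X":
            total += k * scheme.mismatch
        else:
            total -= scheme.gap_cost(k)
    return total
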