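"""Deterministic synthetic references, reads and truth sets.

The mutation model is deliberately minimal: independent per-base
substitutions (the replacement drawn uniformly from the three other
bases), and per-position insertions/deletions with geometrically
distributed lengths (mean 2).  Reads are uniform over valid start
positions; a configurable fraction is reverse-complemented.  Every edit is
recorded so the read is re-derivable from the reference slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence import Sequence, reverse_complement

__all__ = ["ReadTruth", "generate_reference", "sample_reads", "apply_edits"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ReadTruth:
    """Ground truth for one simulated read.

    ``start``/``end`` delimit the originating reference slice (0-based,
    half-open, forward coordinates); ``edits`` lists (op, slice_position,
    payload) triples applied left to right to the forward slice before any
    reverse complementing: op "S" substitutes payload at the position, "I"
    inserts payload before it, "D" deletes len(payload) bases from it.
    """

    read_id: str
    start: int
    end: int
    strand: str
    substitutions: int
    insertions: int
    insertion_bases: int
    deletions: int
    deletion_bases: int
    edits: tuple[tuple[str, int, str], ...] = field(default_factory=tuple)


def generate_reference(length: int, gc_fraction: float = 0.5, seed: int = 0,
                       name: str = "ref") -> Sequence:
    """Random reference with the requested GC composition; deterministic."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    draws = rng.choice(4, size=length, p=[at, gc, gc, at])
    return Sequence(name, "".join(_BASES[draws]))


def apply_edits(slice_residues: str, edits) -> str:
    """Re-derive the (forward-orientation) read from a slice and its edits."""
    out = []
    pos = 0
    for op, at, payload in edits:
        out.append(slice_residues[pos:at])
        if op == "S":
            out.append(payload)
            pos = at + 1
        elif op == "I":
            out.append(payload)
            pos = at
        elif op == "D":
            pos = at + len(payload)
        else:
            raise ValueError(f"unknown edit op {op!r}")
    out.append(slice_residues[pos:])
    return "".join(out)


def sample_reads(
    ref: Sequence,
    n_reads: int,
    read_len: int,
    sub_rate: float = 0.0,
    ins_rate: float = 0.0,
    del_rate: float = 0.0,
    strand_mix: float = 0.5,
    seed: int = 0,
) -> tuple[list[Sequence], list[ReadTruth]]:
    """Draw mutated reads with exact truth records; deterministic per seed."""
    if read_len > len(ref):
        raise ValueError("read_len exceeds the reference length")
    for nm, rate in (("sub_rate", sub_rate), ("ins_rate", ins_rate),
                     ("del_rate", del_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{nm} must lie in [0, 1]")
    if ins_rate + del_rate >= 1.0:
        raise ValueError("ins_rate + del_rate must stay below 1")
    rng = np.random.default_rng(seed)
    reads: list[Sequence] = []
    truths: list[ReadTruth] = []
    base_index = {b: i for i, b in enumerate("ACGT")}
    for i in range(n_reads):
        start = int(rng.integers(0, len(ref) - read_len + 1))
        end = start + read_len
        piece = ref.residues[start:end]
        edits: list[tuple[str, int, str]] = []
        n_sub = n_ins = n_del = ins_bases = del_bases = 0
        pos = 0
        while pos < len(piece):
            u = rng.random()
            if del_rate and u < del_rate:
                k = min(int(rng.geometric(0.5)), len(piece) - pos)
                edits.append(("D", pos, piece[pos:pos + k]))
                n_del += 1
                del_bases += k
                pos += k
                continue
            if ins_rate and u < del_rate + ins_rate:
                k = int(rng.geometric(0.5))
                ins = "".join(_BASES[rng.integers(0, 4, size=k)])
                edits.append(("I", pos, ins))
                n_ins += 1
                ins_bases += k
                # fall through: the original base still gets a substitution draw
            if sub_rate and rng.random() < sub_rate:
                orig = piece[pos]
                alt = _BASES[
                    (base_index.get(orig, 0) + 1 + int(rng.integers(0, 3))) % 4
                ]
                edits.append(("S", pos, str(alt)))
                n_sub += 1
            pos += 1
        mutated = apply_edits(piece, edits)
        strand = "-" if rng.random() < strand_mix else "+"
        residues = reverse_complement(mutated) if strand == "-" else mutated
        read_id = f"read{i:05d}"
        reads.append(Sequence(read_id, residues))
        truths.append(
            ReadTruth(
                read_id=read_id,
                start=start,
                end=end,
                strand=strand,
                substitutions=n_sub,
                insertions=n_ins,
                insertion_bases=ins_bases,
                deletions=n_del,
                deletion_bases=del_bases,
                edits=tuple(edits),
            )
        )
    return reads, truths


def write_truth_tsv(truths: list[ReadTruth], path) -> None:
    """Truth table companion for simulated read FASTA files."""
    cols = ["read_id", "start", "end", "strand", "substitutions",
            "insertions", "insertion_bases", "deletions", "deletion_bases"]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for t in truths:
            fh.write(
                "\t".join(
                    str(v)
                    for v in [t.read_id, t.start, t.end, t.strand,
                              t.substitutions, t.insertions, t.insertion_bases,
                              t.deletions, t.deletion_bases]
                )
                + "\n"
            )
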