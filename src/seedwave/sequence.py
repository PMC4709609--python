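"""Sequences and alphabet conventions.

The working alphabet is DNA (A, C, G, T) plus the ambiguity symbol N, which
is indexed like any other symbol but never scores as a match.  Indexed texts
carry a single terminal sentinel ``$`` that collates strictly before every
other symbol.
"""

from __future__ import annotations

from dataclasses import dataclass

SENTINEL = "$"
DNA_ALPHABET = "ACGTN"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Sequence:
    """A named residue string.

    ``residues`` is uppercase.  Library index structures accept any
    uppercase-letter alphabet; DNA validation is enforced at the FASTA
    boundary (:func:`seedwave.io.read_fasta`).
    """

    name: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, item):
        return self.residues[item]


def reverse_complement(residues: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return residues.translate(_COMPLEMENT)[::-1]


def validate_dna(residues: str, name: str = "sequence") -> None:
    """Raise ``ValueError`` naming the first residue outside {A,C,G,T,N}."""
    for pos, ch in enumerate(residues):
        if ch not in DNA_ALPHABET:
            raise ValueError(
                f"{name}: illegal symbol {ch!r} at residue position {pos + 1} "
                f"(allowed: {DNA_ALPHABET})"
            )


def ensure_sentinel(residues: str) -> str:
    """Append the sentinel if absent; reject misplaced sentinels."""
    if residues.endswith(SENTINEL):
        if SENTINEL in residues[:-1]:
            raise ValueError("sentinel '$' may occur only once, at the end")
        return residues
    if SENTINEL in residues:
        raise ValueError("sentinel '$' may occur only at the end")
    return residues + SENTINEL
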