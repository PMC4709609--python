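"""Alignment record shared by the seeding layer, the pipeline and I/O."""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class AlignmentRecord:
    """One local alignment of a query against a reference.

    Intervals are half-open and 0-based; ``r_start``/``r_end`` are global
    reference coordinates once emitted by a map task.  Query coordinates
    always refer to the forward orientation of the read, whatever the
    strand.  ``ops`` is a {=,X,I,D} CIGAR string (I consumes the query).
    """

    query: str
    q_start: int
    q_end: int
    ref: str
    r_start: int
    r_end: int
    strand: str  # "+" or "-"
    score: float
    ops: str
    chunk_id: str = ""

    def identity_key(self) -> tuple:
        """Key under which records from overlap zones are exact duplicates."""
        return (self.query, self.strand, self.q_start, self.q_end,
                self.r_start, self.r_end, self.score, self.ops)

    def with_chunk(self, chunk_id: str) -> "AlignmentRecord":
        return replace(self, chunk_id=chunk_id)

    @property
    def r_length(self) -> int:
        return self.r_end - self.r_start
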