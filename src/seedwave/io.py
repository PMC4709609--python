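"""FASTA input, TSV/SAM alignment output, and run configuration files."""

from __future__ import annotations

import json
from dataclasses import asdict

import pysam
import yaml
from Bio import SeqIO

from .mapreduce import RunConfig
from .records import AlignmentRecord
from .seeding import SeedParams
from .sequence import Sequence, validate_dna
from .sw import ScoringScheme

__all__ = [
    "read_fasta",
    "write_alignments",
    "read_alignments",
    "load_config",
]

_TSV_COLUMNS = [
    "query", "q_start", "q_end", "ref", "r_start", "r_end",
    "strand", "score", "ops", "chunk_id",
]


def read_fasta(path) -> list[Sequence]:
    """Read a (possibly wrapped, mixed-case) FASTA file of DNA sequences.

    Residues are folded to uppercase; symbols outside {A,C,G,T,N}
    (including ``*`` and ``-``) are rejected with an error naming the
    record and residue position.  An empty file yields an empty list.
    """
    out: list[Sequence] = []
    try:
        for record in SeqIO.parse(str(path), "fasta"):
            residues = str(record.seq).upper()
            validate_dna(residues, name=f"record {record.id!r}")
            out.append(Sequence(record.id, residues))
    except ValueError as exc:
        if str(exc).startswith("record "):  # our own validation message
            raise
        raise ValueError(f"{path}: malformed FASTA ({exc})") from exc
    if not out:
        with open(path) as fh:
            body = fh.read().strip()
        if body and not body.startswith(">"):
            raise ValueError(f"{path}: malformed FASTA (no '>' header found)")
    return out


def write_alignments(
    records: list[AlignmentRecord],
    path,
    fmt: str = "tsv",
    reference_lengths: dict[str, int] | None = None,
) -> None:
    """Write records as TSV (canonical, lossless) or SAM (interoperability).

    SAM uses 1-based POS, FLAG bit 0x10 for reverse strand, and the
    {=,X,I,D} CIGAR; query intervals travel in ``ZS``/``ZE`` tags because
    the read sequence itself is not stored.
    """
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(_TSV_COLUMNS) + "\n")
            for r in records:
                row = [r.query, r.q_start, r.q_end, r.ref, r.r_start, r.r_end,
                       r.strand, repr(r.score), r.ops, r.chunk_id]
                fh.write("\t".join(str(v) for v in row) + "\n")
        return
    if fmt != "sam":
        raise ValueError(f"unknown output format {fmt!r} (tsv|sam)")
    lengths = dict(reference_lengths or {})
    for r in records:
        lengths.setdefault(r.ref, r.r_end)
        lengths[r.ref] = max(lengths[r.ref], r.r_end)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": int(n)} for name, n in sorted(lengths.items())],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
        for r in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.query
            seg.flag = 16 if r.strand == "-" else 0
            seg.reference_id = tid[r.ref]
            seg.reference_start = r.r_start
            seg.mapping_quality = 255
            seg.cigarstring = r.ops if r.ops else None
            seg.set_tag("AS", int(round(r.score)))
            seg.set_tag("ZS", r.q_start)
            seg.set_tag("ZE", r.q_end)
            out.write(seg)


def read_alignments(path) -> list[AlignmentRecord]:
    """Read back the TSV dialect written by :func:`write_alignments`."""
    out: list[AlignmentRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            vals = line.split("\t")
            if len(vals) != len(_TSV_COLUMNS):
                raise ValueError(f"{path}: malformed TSV row: {line!r}")
            out.append(
                AlignmentRecord(
                    query=vals[0],
                    q_start=int(vals[1]),
                    q_end=int(vals[2]),
                    ref=vals[3],
                    r_start=int(vals[4]),
                    r_end=int(vals[5]),
                    strand=vals[6],
                    score=float(vals[7]),
                    ops=vals[8],
                    chunk_id=vals[9],
                )
            )
    return out


def _build(section: dict, cls, where: str):
    try:
        return cls(**section)
    except TypeError as exc:
        raise ValueError(f"config section {where!r}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load a YAML/JSON run configuration.

    Recognised sections: ``scoring`` (ScoringScheme fields), ``seeding``
    (SeedParams fields) and top-level pipeline fields (chunk_len, overlap,
    workers, ...).  Violations raise ``ValueError`` naming the field.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    scoring = _build(doc.pop("scoring", {}) or {}, ScoringScheme, "scoring")
    seeding = _build(doc.pop("seeding", {}) or {}, SeedParams, "seeding")
    try:
        return RunConfig(scoring=scoring, seeding=seeding, **doc)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from exc


def config_to_dict(config: RunConfig) -> dict:
    doc = asdict(config)
    return doc


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
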