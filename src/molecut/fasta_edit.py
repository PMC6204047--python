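"""Split draft-assembly sequences at planned cut positions.

Every contig with k cuts yields k + 1 segments that tile the parent exactly;
the poorly-supported middle piece between a cut pair is retained as its own
segment, never discarded.  Uncut contigs pass through byte-for-byte with
their original name.  Split segments are renamed ``<parent>-<ordinal>`` with
the parent interval recorded in the description, and sequences are written
wrapped at a fixed 60 columns so identical inputs give byte-identical
output.  Softmasked (lowercase) bases are preserved verbatim.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO

from .cuts import CutPlan

LINE_WIDTH = 60


@dataclass(frozen=True)
class ContigSegment:
    """One output piece of a parent contig, in parent coordinates."""

    parent: str
    ordinal: int
    start: int
    end: int
    name: str
    sequence: str


def split_sequence(name: str, sequence: str, cuts: Sequence[int]) -> list[ContigSegment]:
    """Split ``sequence`` at ``cuts`` (sorted, strictly inside the contig).

    With no cuts the single segment keeps the parent name.
    """
    length = len(sequence)
    for pos in cuts:
        if not 0 < pos < length:
            raise ValueError(f"cut {pos} outside contig {name} of length {length}")
    if not cuts:
        return [ContigSegment(name, 1, 0, length, name, sequence)]
    bounds = [0, *sorted(cuts), length]
    return [
        ContigSegment(
            parent=name,
            ordinal=i + 1,
            start=bounds[i],
            end=bounds[i + 1],
            name=f"{name}-{i + 1}",
            sequence=sequence[bounds[i] : bounds[i + 1]],
        )
        for i in range(len(bounds) - 1)
    ]


def _open_fasta(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> list[tuple[str, str]]:
    """(name, sequence) pairs in file order; gzip honoured by suffix."""
    with _open_fasta(path) as handle:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]


def write_fasta(records: Iterable[tuple[str, str, str]], sink) -> None:
    """Write (name, description, sequence) records wrapped at 60 columns."""
    own = not hasattr(sink, "write")
    handle = open(sink, "w") if own else sink
    try:
        for name, description, sequence in records:
            header = f">{name} {description}" if description else f">{name}"
            handle.write(header + "\n")
            for i in range(0, len(sequence), LINE_WIDTH):
                handle.write(sequence[i : i + LINE_WIDTH] + "\n")
    finally:
        if own:
            handle.close()


def apply_cuts(fasta_in, plans: Sequence[CutPlan], fasta_out) -> list[ContigSegment]:
    """Split the draft FASTA according to ``plans`` and write the result.

    All plans are validated against the FASTA (contig present, matching
    length) before any output is written; output order follows input FASTA
    order.  Returns the segments written.
    """
    records = read_fasta(fasta_in)
    lengths = {name: len(seq) for name, seq in records}
    by_contig: dict[str, CutPlan] = {}
    for plan in plans:
        if plan.contig not in lengths:
            raise ValueError(f"cut plan references unknown contig {plan.contig!r}")
        if plan.contig in by_contig:
            raise ValueError(f"duplicate cut plan for contig {plan.contig!r}")
        if plan.contig_length != lengths[plan.contig]:
            raise ValueError(
                f"cut plan for {plan.contig!r} assumes length "
                f"{plan.contig_length}, FASTA has {lengths[plan.contig]}"
            )
        by_contig[plan.contig] = plan

    segments: list[ContigSegment] = []
    out_records: list[tuple[str, str, str]] = []
    for name, sequence in records:
        plan = by_contig.get(name)
        cuts = plan.cut_positions if plan else ()
        for seg in split_sequence(name, sequence, cuts):
            segments.append(seg)
            description = (
                f"{seg.parent}:{seg.start}-{seg.end}" if seg.name != seg.parent else ""
            )
            out_records.append((seg.name, description, seg.sequence))
    write_fasta(out_records, fasta_out)
    return segments
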