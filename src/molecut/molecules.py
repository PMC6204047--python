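"""Group same-barcode reads into inferred molecules and read/write molecule BED.

A "molecule" here is the genomic extent delimited by the leftmost and
rightmost alignments of reads that share a barcode on one contig, chained
while consecutive reads fall within a maximum distance of each other
(50 kbp by default, the value used by 10x Genomics' Long Ranger/Lariat).
The adjacency rule is measured between the *start* coordinates of
consecutive same-barcode reads after sorting.  Molecules are per-contig:
same-barcode reads on different contigs always yield separate molecules
(barcode collisions between physical molecules are tolerated, not resolved).

Unusually small molecules (< 2 kbp by default) and molecules composed of too
few reads (< 4 by default) are filtered out as alignment noise before
coverage analysis.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Sequence

from .alignments import AlignedRead


@dataclass(frozen=True)
class MoleculeParams:
    """Molecule grouping and filtering thresholds (bp / read counts)."""

    max_read_gap: int = 50_000
    min_molecule_size: int = 2_000
    min_reads_per_molecule: int = 4

    def __post_init__(self) -> None:
        if self.max_read_gap <= 0 or self.min_molecule_size <= 0:
            raise ValueError("distance and size thresholds must be positive")
        if self.min_reads_per_molecule <= 0:
            raise ValueError("min_reads_per_molecule must be positive")


@dataclass(frozen=True)
class Molecule:
    """Inferred extent of one DNA molecule on one contig (0-based half-open)."""

    contig: str
    start: int
    end: int
    barcode: str
    read_count: int

    @property
    def length(self) -> int:
        return self.end - self.start


def group_into_molecules(
    reads: Iterable[AlignedRead], params: MoleculeParams
) -> list[Molecule]:
    """Chain same-barcode reads on each contig into molecules.

    Reads are sorted by (barcode, contig, start, end) internally, so the
    result is independent of input order.  Within a (barcode, contig) group a
    read extends the current chain when its start lies within
    ``max_read_gap`` of the previous read's start; each maximal chain becomes
    one molecule spanning min read start to max read end, carrying the chain
    length as its read count.  Output is sorted by (contig, start, end,
    barcode).

    Raises ``ValueError`` if any read lacks a barcode (such reads should have
    been filtered out upstream).
    """
    ordered = sorted(
        reads, key=lambda r: (_require_barcode(r), r.contig, r.start, r.end)
    )
    molecules: list[Molecule] = []
    for (barcode, contig), group in groupby(
        ordered, key=lambda r: (r.barcode, r.contig)
    ):
        chain_start = chain_end = prev_start = None
        count = 0
        for read in group:
            if prev_start is not None and read.start - prev_start > params.max_read_gap:
                molecules.append(
                    Molecule(contig, chain_start, chain_end, barcode, count)
                )
                chain_start = chain_end = None
                count = 0
            if chain_start is None:
                chain_start = read.start
                chain_end = read.end
            else:
                chain_end = max(chain_end, read.end)
            prev_start = read.start
            count += 1
        if count:
            molecules.append(Molecule(contig, chain_start, chain_end, barcode, count))
    molecules.sort(key=lambda m: (m.contig, m.start, m.end, m.barcode))
    return molecules


def _require_barcode(read: AlignedRead) -> str:
    if read.barcode is None:
        raise ValueError(
            f"read on {read.contig}:{read.start} has no barcode; filter "
            "barcode-less reads before molecule grouping"
        )
    return read.barcode


def filter_molecules(
    molecules: Iterable[Molecule], params: MoleculeParams
) -> list[Molecule]:
    """Keep molecules of length >= min size and read count >= min reads.

    A molecule of exactly ``min_molecule_size`` bp is retained ("shorter
    than" semantics); order is preserved.
    """
    return [
        m
        for m in molecules
        if m.length >= params.min_molecule_size
        and m.read_count >= params.min_reads_per_molecule
    ]


def _open_maybe_gzip(path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_molecule_bed(
    molecules: Sequence[Molecule], sink, header: str | None = None
) -> None:
    """Write molecules as BED6: contig, start, end, barcode, read count, '.'.

    ``sink`` may be a path (``.gz`` honoured) or a text file object.
    ``header`` lines (without leading '#') are written as comments.
    """
    own = not hasattr(sink, "write")
    handle = _open_maybe_gzip(sink, "w") if own else sink
    try:
        if header:
            for line in header.splitlines():
                handle.write(f"#{line}\n")
        for m in molecules:
            handle.write(f"{m.contig}\t{m.start}\t{m.end}\t{m.barcode}\t{m.read_count}\t.\n")
    finally:
        if own:
            handle.close()


def read_molecule_bed(source) -> list[Molecule]:
    """Parse a molecule BED written by :func:`write_molecule_bed`.

    Comment (#), ``track`` and ``browser`` lines are skipped.  Malformed
    lines raise ``ValueError`` with the line number.
    """
    own = not hasattr(source, "read")
    handle = _open_maybe_gzip(source, "r") if own else source
    molecules: list[Molecule] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(
                    f"molecule BED line {lineno}: expected >= 5 fields, got "
                    f"{len(fields)}"
                )
            try:
                molecules.append(
                    Molecule(
                        contig=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        barcode=fields[3],
                        read_count=int(fields[4]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"molecule BED line {lineno}: {exc}") from exc
    finally:
        if own:
            handle.close()
    return molecules
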