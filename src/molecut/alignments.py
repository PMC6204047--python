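"""Barcoded linked-read alignment parsing and per-read quality filtering.

Linked-read protocols (10x Genomics Chromium and kin) tag each short read
with the barcode of the droplet partition it came from, so reads that share
a barcode derive from a small number of long DNA molecules.  This module
reads alignments of such reads against a draft assembly (SAM/BAM, barcode in
an auxiliary string tag, ``BX`` by default) and applies the per-read quality
thresholds used before molecule inference: edit distance ``NM`` strictly
below a maximum, and alignment score ``AS`` at or above a fixed fraction of
the read length ``l``.

Coordinates are 0-based half-open everywhere in this package; SAM's 1-based
positions are converted at this parse boundary (pysam already does so).
Only primary mapped alignments are kept: secondary, supplementary and
duplicate records would let one read contribute to two molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

logger = logging.getLogger(__name__)

DEFAULT_BARCODE_TAG = "BX"


@dataclass(frozen=True)
class AlignedRead:
    """One primary mapped alignment of a barcoded read on a draft contig.

    ``start``/``end`` are the 0-based half-open reference-aligned span.
    ``read_length`` is the full read length l; ``mismatches`` and
    ``align_score`` mirror the NM and AS auxiliary tags.
    """

    contig: str
    start: int
    end: int
    barcode: str | None
    read_length: int
    mismatches: int
    align_score: int
    mapq: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"mapped read must have start < end, got [{self.start}, {self.end})"
            )
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.mismatches < 0:
            raise ValueError("mismatches (NM) must be non-negative")


@dataclass(frozen=True)
class ReadFilterParams:
    """Per-read quality thresholds.

    Defaults keep reads with NM < 5 (strict) and AS >= 0.65*l (inclusive).
    ``min_mapq`` defaults to 0, i.e. no mapping-quality filter; barcode-less
    reads are unusable for molecule inference and are dropped by default.
    """

    max_mismatches: int = 5
    min_score_ratio: float = 0.65
    min_mapq: int = 0
    require_barcode: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_score_ratio <= 1.0:
            raise ValueError("min_score_ratio must be in [0, 1]")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be non-negative")


def parse_barcoded_alignments(
    source, barcode_tag: str = DEFAULT_BARCODE_TAG
) -> Iterator[AlignedRead]:
    """Yield one :class:`AlignedRead` per primary mapped record of a SAM/BAM.

    Unmapped, secondary, supplementary and duplicate records are excluded
    before any quality filtering.  The barcode is taken from ``barcode_tag``
    (default ``BX``); a record lacking the tag yields ``barcode=None``.
    A missing NM tag is treated as 0 mismatches and a missing AS tag as a
    perfect score (equal to the read length), so untagged inputs pass the
    score/mismatch filters rather than vanishing silently.

    Raises ``ValueError`` for malformed records, naming the offending record.
    """
    with pysam.AlignmentFile(str(source), check_sq=False) as handle:
        record_no = 0
        iterator = iter(handle)
        while True:
            try:
                aln = next(iterator)
            except StopIteration:
                break
            except (ValueError, OSError) as exc:
                raise ValueError(
                    f"malformed alignment record #{record_no + 1} in {source}: {exc}"
                ) from exc
            record_no += 1
            if (
                aln.is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or aln.is_duplicate
            ):
                continue
            if aln.reference_name is None:
                raise ValueError(
                    f"record #{record_no} ({aln.query_name}) is mapped but its "
                    "contig is not named in the header"
                )
            read_length = aln.infer_read_length() or aln.infer_query_length()
            if not read_length and aln.query_sequence:
                read_length = len(aln.query_sequence)
            if not read_length:
                raise ValueError(
                    f"record #{record_no} ({aln.query_name}): cannot determine "
                    "read length from CIGAR or SEQ"
                )
            try:
                barcode = aln.get_tag(barcode_tag)
            except KeyError:
                barcode = None
            try:
                nm = int(aln.get_tag("NM"))
            except KeyError:
                nm = 0
            try:
                score = int(aln.get_tag("AS"))
            except KeyError:
                score = int(read_length)
            yield AlignedRead(
                contig=aln.reference_name,
                start=int(aln.reference_start),
                end=int(aln.reference_end),
                barcode=str(barcode) if barcode is not None else None,
                read_length=int(read_length),
                mismatches=nm,
                align_score=score,
                mapq=int(aln.mapping_quality),
            )


def passes_filters(read: AlignedRead, params: ReadFilterParams) -> bool:
    """True iff ``read`` survives the per-read quality thresholds.

    NM is compared strictly (``NM < max``); the score threshold is inclusive
    (``AS >= ratio * l``).
    """
    if params.require_barcode and read.barcode is None:
        return False
    return (
        read.mismatches < params.max_mismatches
        and read.align_score >= params.min_score_ratio * read.read_length
        and read.mapq >= params.min_mapq
    )


def filter_reads(
    reads: Iterable[AlignedRead], params: ReadFilterParams
) -> list[AlignedRead]:
    """Retain reads passing :func:`passes_filters`; logs drop counts."""
    kept: list[AlignedRead] = []
    dropped_barcode = 0
    dropped_quality = 0
    for read in reads:
        if params.require_barcode and read.barcode is None:
            dropped_barcode += 1
            continue
        if passes_filters(read, params):
            kept.append(read)
        else:
            dropped_quality += 1
    if dropped_barcode:
        logger.info("dropped %d reads without a barcode tag", dropped_barcode)
    if dropped_quality:
        logger.info("dropped %d reads failing quality thresholds", dropped_quality)
    return kept


def write_alignments_sam(
    reads: Sequence[AlignedRead],
    contig_lengths: Mapping[str, int],
    path,
    barcode_tag: str = DEFAULT_BARCODE_TAG,
) -> None:
    """Write reads as a headered SAM file.

    The CIGAR is reconstructed as an all-match span plus a trailing soft clip
    when the read is longer than its reference span; alignments whose
    reference span exceeds the read length (i.e. containing deletions) cannot
    be round-tripped exactly and are written as pure matches.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": int(length)} for name, length in contig_lengths.items()
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, read in enumerate(reads):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = f"read{i}"
            seg.flag = 0
            seg.reference_name = read.contig
            seg.reference_start = read.start
            seg.mapping_quality = read.mapq
            span = read.end - read.start
            if read.read_length > span:
                seg.cigarstring = f"{span}M{read.read_length - span}S"
            else:
                seg.cigarstring = f"{span}M"
            seg.query_sequence = None
            tags = [("NM", read.mismatches), ("AS", read.align_score)]
            if read.barcode is not None:
                tags.append((barcode_tag, read.barcode))
            seg.set_tags(tags)
            out.write(seg)
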