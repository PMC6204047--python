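"""Convert well-covered profiles into cut coordinates and a breakpoints BED.

A contig is cut around every maximal run of poorly-covered windows that is
flanked by well-covered windows on *both* sides: once after the last base of
the preceding well-covered window, and once before the first base of the
following well-covered window.  For a poor run spanning window starts
[p, q] this places cuts at ``(p - 1) + window`` and ``q + 1``.

Runs touching a contig end produce no cuts — every contig end is preceded by
poorly-covered windows simply because no molecule can extend past the
sequence, and trimming there would discard sequence without evidence of
misassembly.  Likewise an all-poor profile (no well-covered window at all)
leaves the contig intact.

When the poor run is shorter than the window the two cut formulas cross;
the pair collapses to the single midpoint position.  Exact coincidence is
the clean-junction case: a sharp molecule-coverage break at position j
yields the poor run [j - window + 1, j - 1] and both cuts land on j itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .coverage import ScanParams, SupportProfile


@dataclass(frozen=True)
class CutPlan:
    """Sorted cut coordinates for one contig plus the regions behind them.

    ``regions`` holds one (start, end) pair per interior poorly-supported
    run; a collapsed (single-cut) run appears as a zero-length (c, c) pair.
    Cut positions are strictly inside (0, contig_length), so every resulting
    segment is non-empty.
    """

    contig: str
    contig_length: int
    cut_positions: tuple[int, ...] = ()
    regions: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        for pos in self.cut_positions:
            if not 0 < pos < self.contig_length:
                raise ValueError(
                    f"cut {pos} outside (0, {self.contig_length}) on {self.contig}"
                )
        if list(self.cut_positions) != sorted(set(self.cut_positions)):
            raise ValueError("cut positions must be strictly increasing")


def find_cut_points(profile: SupportProfile, params: ScanParams) -> CutPlan:
    """Derive cut positions from a support profile.

    Raises ``ValueError`` when ``params.window`` differs from the window the
    profile was computed with.
    """
    if params.window != profile.window:
        raise ValueError(
            f"profile was computed with window={profile.window}, "
            f"cut parameters say window={params.window}"
        )
    wc = profile.well_covered
    n = len(wc)
    cuts: set[int] = set()
    regions: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if wc[i]:
            i += 1
            continue
        p = i
        while i + 1 < n and not wc[i + 1]:
            i += 1
        q = i
        i += 1
        if p == 0 or q == n - 1:
            continue  # run touches a contig end: not cut
        left = (p - 1) + profile.window  # after last base of preceding window
        right = q + 1  # before first base of following window
        if left < right:
            cuts.update((left, right))
            regions.append((left, right))
        else:
            mid = (left + right) // 2
            cuts.add(mid)
            regions.append((mid, mid))
    return CutPlan(
        contig=profile.contig,
        contig_length=profile.contig_length,
        cut_positions=tuple(sorted(cuts)),
        regions=tuple(regions),
    )


def write_breakpoints_bed(
    plans: Sequence[CutPlan], sink, header: str | None = None
) -> None:
    """Write one BED record per poorly-supported region, in plan order.

    Collapsed cut pairs appear as single-position (zero-length) records.
    """
    own = not hasattr(sink, "write")
    handle = open(sink, "w") if own else sink
    try:
        if header:
            for line in header.splitlines():
                handle.write(f"#{line}\n")
        for plan in plans:
            for start, end in plan.regions:
                handle.write(f"{plan.contig}\t{start}\t{end}\n")
    finally:
        if own:
            handle.close()


def read_breakpoints_bed(source) -> list[tuple[str, int, int]]:
    """Parse a breakpoints BED into (contig, start, end) records."""
    own = not hasattr(source, "read")
    handle = open(source) if own else source
    records: list[tuple[str, int, int]] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"breakpoints BED line {lineno}: expected >= 3 fields"
                )
            records.append((fields[0], int(fields[1]), int(fields[2])))
    finally:
        if own:
            handle.close()
    return records


def cut_positions_from_regions(
    records: Sequence[tuple[str, int, int]],
) -> list[tuple[str, int]]:
    """Expand breakpoint regions back into individual cut coordinates."""
    cuts: set[tuple[str, int]] = set()
    for contig, start, end in records:
        cuts.add((contig, start))
        if end != start:
            cuts.add((contig, end))
    return sorted(cuts)
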