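"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths they check: counting is a plain scan
over all molecules (vectorised with numpy broadcasting but still O(n*L)
work), molecule grouping is a direct re-derivation from sorted read starts,
and cut finding is a separate run-length scan over the boolean profile.
"""

from __future__ import annotations

import numpy as np


def brute_count(intervals, win_start: int, win_end: int) -> int:
    """Molecules containing [win_start, win_end), by scanning every interval."""
    return sum(1 for s, e in intervals if s <= win_start and e >= win_end)


def brute_profile(intervals, contig_length: int, window: int, min_spanning: int):
    """Well-covered vector by evaluating every window against every molecule."""
    n = contig_length - window + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    wstarts = np.arange(n)
    if not intervals:
        return np.zeros(n, dtype=bool)
    starts = np.array([s for s, _ in intervals])[:, None]
    ends = np.array([e for _, e in intervals])[:, None]
    counts = ((starts <= wstarts) & (ends >= wstarts + window)).sum(axis=0)
    return counts >= min_spanning


def brute_group(reads, max_read_gap: int):
    """Re-derive molecule tuples (contig, start, end, barcode, n) from reads."""
    by_key: dict[tuple[str, str], list] = {}
    for r in reads:
        by_key.setdefault((r.barcode, r.contig), []).append(r)
    out = []
    for (barcode, contig), group in by_key.items():
        group.sort(key=lambda r: (r.start, r.end))
        chains = [[group[0]]]
        for prev, cur in zip(group, group[1:]):
            if cur.start - prev.start > max_read_gap:
                chains.append([])
            chains[-1].append(cur)
        for chain in chains:
            out.append(
                (
                    contig,
                    min(r.start for r in chain),
                    max(r.end for r in chain),
                    barcode,
                    len(chain),
                )
            )
    return sorted(out)


def runlength_cuts(well_covered, window: int):
    """Cut positions from a boolean profile via an explicit run-length pass.

    Mirrors the cutting contract: a maximal poor run over window starts
    [p, q] flanked by well-covered windows on both sides yields cuts at
    (p - 1) + window and q + 1; a crossed/coincident pair collapses to the
    single midpoint.  Runs touching either end of the profile yield nothing.
    """
    flags = list(bool(x) for x in well_covered)
    n = len(flags)
    runs = []
    start = None
    for i, flag in enumerate(flags + [True]):  # sentinel terminates a final run
        if not flag and start is None:
            start = i
        elif flag and start is not None:
            runs.append((start, i - 1))
            start = None
    cuts = set()
    for p, q in runs:
        if p == 0 or q == n - 1:
            continue
        left, right = (p - 1) + window, q + 1
        if left < right:
            cuts.update((left, right))
        else:
            cuts.add((left + right) // 2)
    return sorted(cuts)
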