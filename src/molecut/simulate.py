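"""Desk-scale synthetic linked-read misassembly scenarios and cut evaluation.

The generator builds a random "true" genome, injects misassembly junctions
by partitioning the genome into segments and concatenating them in a
shuffled order in which consecutive draft segments are never adjacent in the
true genome, and then simulates barcoded linked-read molecules *on the true
genome*.  Each molecule carries a unique barcode and a Poisson number of
uniformly placed reads; every read coordinate is mapped through the segment
map onto the draft.  A molecule that crosses a junction in true-genome space
therefore lands on two discontiguous draft loci — two draft-local molecules
whose extents both stop at the junction — so no simulated molecule spans a
junction on the draft.  This reproduces exactly the spanning-coverage
dropout the detector keys on.

Reads are emitted as valid SAM records (all-match CIGAR, NM/AS/BX tags) so
the real parser and filters are exercised end to end.  There is no
sequencing-error model; instead ``noise_read_fraction`` marks a random
subset of reads with an elevated NM and depressed AS so the quality filters
have something to reject.

:func:`evaluate_cuts` scores detected cut coordinates against the injected
junction truth with a bp tolerance, reporting precision (matched cuts over
all cuts) and recall (recovered junctions over all junctions).  This
substitutes injected-junction truth for the reference-alignment-based
misassembly truth used at genome scale, which needs external reference
genomes and evaluation tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alignments import AlignedRead
from .molecules import Molecule

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DRAFT_CONTIG = "draft_1"
TRUE_CONTIG = "genome"


@dataclass(frozen=True)
class SimParams:
    """Scenario parameters; ``seed`` fully determines every output.

    ``molecule_coverage`` is the mean number of molecule extents overlapping
    a point of the true genome.  Molecule lengths follow a shifted
    exponential (minimum + Exponential(scale), the exact "truncated below"
    exponential), capped at ``max_molecule_length``; reads per molecule are
    Poisson with mean proportional to molecule length.  Segments between
    junctions are at least ``min_segment_length`` long so every junction is
    far from contig ends and flanked by well-coverable sequence.
    """

    genome_length: int = 1_000_000
    n_junctions: int = 10
    molecule_mean_length: int = 60_000
    molecule_coverage: float = 100.0
    reads_per_molecule_mean: int = 60
    read_length: int = 150
    seed: int = 0
    min_molecule_length: int = 2_000
    max_molecule_length: int = 200_000
    min_segment_length: int = 50_000
    noise_read_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "genome_length",
            "molecule_mean_length",
            "reads_per_molecule_mean",
            "read_length",
            "min_molecule_length",
            "max_molecule_length",
            "min_segment_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_junctions < 0:
            raise ValueError("n_junctions must be >= 0")
        if self.molecule_coverage <= 0:
            raise ValueError("molecule_coverage must be positive")
        if not 0.0 <= self.noise_read_fraction <= 1.0:
            raise ValueError("noise_read_fraction must be in [0, 1]")
        if self.genome_length < 10 * self.molecule_mean_length:
            raise ValueError(
                "genome_length must be at least 10x the mean molecule length"
            )


@dataclass(frozen=True)
class TruthSet:
    """Draft contigs and the injected junction coordinates on them."""

    contig_lengths: dict[str, int]
    junctions: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for contig, pos in self.junctions:
            if not 0 < pos < self.contig_lengths[contig]:
                raise ValueError(f"junction {pos} not strictly inside {contig}")


@dataclass(frozen=True)
class Scenario:
    """A simulated true genome, misassembled draft and segment bookkeeping.

    ``segment_bounds`` are the true-genome partition boundaries
    (b_0=0 < ... < b_S=L); ``draft_order`` the permutation in which segments
    were concatenated; ``draft_offsets[i]`` the draft coordinate where true
    segment i begins.
    """

    params: SimParams
    true_genome: dict[str, str]
    draft: dict[str, str]
    truth: TruthSet
    segment_bounds: tuple[int, ...]
    draft_order: tuple[int, ...]
    draft_offsets: tuple[int, ...] = field(repr=False)

    def to_draft(self, true_pos: int) -> int:
        """Map a true-genome coordinate onto the draft (affine per segment)."""
        seg = int(np.searchsorted(self.segment_bounds, true_pos, side="right")) - 1
        return self.draft_offsets[seg] + (true_pos - self.segment_bounds[seg])

    def segment_of(self, true_pos: int) -> int:
        return int(np.searchsorted(self.segment_bounds, true_pos, side="right")) - 1


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def _segment_boundaries(rng: np.random.Generator, params: SimParams) -> list[int]:
    s = params.n_junctions + 1
    mingap = params.min_segment_length
    slack = params.genome_length - s * mingap
    if slack < 0:
        raise ValueError(
            f"{params.n_junctions} junctions with minimum segment length "
            f"{mingap} do not fit in a {params.genome_length} bp genome"
        )
    offsets = np.sort(rng.uniform(0, slack, size=params.n_junctions))
    bounds = [int(round(u)) + (i + 1) * mingap for i, u in enumerate(offsets)]
    if len(set(bounds)) != len(bounds):  # astronomically unlikely collision
        raise ValueError("degenerate junction placement; use another seed")
    return bounds


# default molecule-chaining distance of the grouping stage; used as slack
# when deciding whether a long molecule could bridge a draft junction
CHAIN_GAP = 50_000


def _bridge_distance(lengths: Sequence[int], a: int, b: int) -> int:
    """Minimum true-genome span a molecule needs to put reads on both sides
    of the draft junction formed by placing segment ``b`` right after ``a``.

    For a forward jump (b > a) the molecule must cover every true segment
    strictly between them; for a backward jump it must reach from the head
    of ``b`` to the tail of ``a``, i.e. cover the whole stretch b..a, minus
    up to one chaining gap of slack shared between the two read groups.
    """
    if b > a:
        return sum(lengths[a + 1 : b])
    return sum(lengths[b : a + 1]) - CHAIN_GAP


def _draft_order(
    rng: np.random.Generator, lengths: Sequence[int], max_molecule_length: int
) -> list[int]:
    """Shuffle segments so no junction can be bridged by a single molecule.

    Consecutive draft segments must not be true-adjacent (that would not be
    a misassembly at all), and the bridging distance of every consecutive
    pair must be at least the maximum molecule length — otherwise a long
    molecule covering the intervening true sequence would chain reads across
    the junction and mask the spanning-coverage dropout the detector needs.
    A randomized greedy construction with restarts finds such an order; if
    the segment geometry makes it infeasible, only direct adjacency is
    forbidden and a warning notes that some junctions may be bridgeable.
    """
    n = len(lengths)
    if n == 1:
        return [0]

    def ok(a: int, b: int) -> bool:
        if b == a + 1:
            return False
        return _bridge_distance(lengths, a, b) >= max_molecule_length

    for _ in range(5000):
        remaining = list(range(n))
        cur = remaining.pop(int(rng.integers(n)))
        perm = [cur]
        while remaining:
            choices = [s for s in remaining if ok(cur, s)]
            if not choices:
                break
            cur = choices[int(rng.integers(len(choices)))]
            perm.append(cur)
            remaining.remove(cur)
        if not remaining:
            return perm
    for _ in range(2000):
        perm = rng.permutation(n)
        if not np.any(np.diff(perm) == 1):
            logger.warning(
                "segment geometry admits no bridge-proof order; long molecules "
                "may span some junctions"
            )
            return [int(x) for x in perm]
    raise ValueError("could not shuffle segments into a misassembled order")


def simulate_scenario(params: SimParams) -> Scenario:
    """Generate the true genome, the misassembled draft and the truth set.

    With ``n_junctions = 0`` the draft equals the true genome.  Deterministic
    given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    genome = _random_sequence(rng, params.genome_length)
    if params.n_junctions == 0:
        bounds = (0, params.genome_length)
        order = (0,)
        offsets = (0,)
        draft_seq = genome
        junctions: tuple[tuple[str, int], ...] = ()
    else:
        inner = _segment_boundaries(rng, params)
        bounds = (0, *inner, params.genome_length)
        seg_lengths = [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]
        order = tuple(
            _draft_order(
                rng,
                seg_lengths,
                min(params.max_molecule_length, params.genome_length),
            )
        )
        offsets_list = [0] * len(seg_lengths)
        pos = 0
        junction_list = []
        for k, seg in enumerate(order):
            offsets_list[seg] = pos
            pos += seg_lengths[seg]
            if k < len(order) - 1:
                junction_list.append((DRAFT_CONTIG, pos))
        offsets = tuple(offsets_list)
        draft_seq = "".join(genome[bounds[s] : bounds[s + 1]] for s in order)
        junctions = tuple(junction_list)
    truth = TruthSet(
        contig_lengths={DRAFT_CONTIG: params.genome_length}, junctions=junctions
    )
    return Scenario(
        params=params,
        true_genome={TRUE_CONTIG: genome},
        draft={DRAFT_CONTIG: draft_seq},
        truth=truth,
        segment_bounds=bounds,
        draft_order=order,
        draft_offsets=offsets,
    )


def _barcode(index: int) -> str:
    letters = []
    x = index
    for _ in range(16):
        letters.append("ACGT"[x & 3])
        x >>= 2
    return "".join(reversed(letters)) + "-1"


def _draw_molecules(
    rng: np.random.Generator, params: SimParams
) -> list[tuple[int, int]]:
    """True-genome molecule extents [start, end), clipped to the genome.

    Starts are uniform over all placements intersecting the genome, so a
    molecule of length l covers any fixed interior point with probability
    l / (L + l - 1); molecules are drawn until those probabilities sum to
    the target mean point coverage, making coverage uniform along the whole
    genome (clipped overhangs appear as shorter molecules at the ends).
    """
    length_cap = min(params.max_molecule_length, params.genome_length)
    extents: list[tuple[int, int]] = []
    total = 0.0
    while total < params.molecule_coverage:
        lengths = params.min_molecule_length + rng.exponential(
            params.molecule_mean_length, size=256
        ).astype(np.int64)
        np.minimum(lengths, length_cap, out=lengths)
        starts = rng.integers(-(lengths - 1), params.genome_length)
        for l, s in zip(lengths, starts):
            total += l / (params.genome_length + l - 1)
            cs = max(int(s), 0)
            ce = min(int(s) + int(l), params.genome_length)
            extents.append((cs, ce))
            if total >= params.molecule_coverage:
                break
    return extents


def simulate_molecule_alignments(
    scenario: Scenario, params: SimParams | None = None
) -> tuple[list[AlignedRead], list[Molecule]]:
    """Simulate barcoded reads on the draft plus the true molecule extents.

    Returns draft-space read alignments (ready for
    :func:`molecut.alignments.write_alignments_sam`) and the ground-truth
    draft-local molecules: one record per (molecule, true segment) piece that
    received at least one read, with extents clipped at segment boundaries.
    Reads straddling a segment boundary are dropped, as a real aligner would
    split or clip them.

    Reads draw from ``params.seed + 1`` so molecule placement is independent
    of the genome sequence draw.
    """
    params = params or scenario.params
    rng = np.random.default_rng(params.seed + 1)
    L = params.genome_length
    mean_len = params.min_molecule_length + params.molecule_mean_length
    bounds = np.asarray(scenario.segment_bounds)

    reads: list[AlignedRead] = []
    truth_molecules: list[Molecule] = []
    noise_as = int(0.55 * params.read_length)
    for mol_idx, (cs, ce) in enumerate(_draw_molecules(rng, params)):
        span = ce - cs
        if span < params.read_length:
            continue
        n_reads = int(rng.poisson(params.reads_per_molecule_mean * span / mean_len))
        if n_reads == 0:
            continue
        barcode = _barcode(mol_idx)
        starts = np.sort(rng.integers(cs, ce - params.read_length + 1, size=n_reads))
        seg_first = np.searchsorted(bounds, starts, side="right") - 1
        seg_last = (
            np.searchsorted(bounds, starts + params.read_length - 1, side="right") - 1
        )
        keep = seg_first == seg_last  # drop junction-straddling reads
        starts = starts[keep]
        segs = seg_first[keep]
        if starts.size == 0:
            continue
        noisy = (
            rng.random(starts.size) < params.noise_read_fraction
            if params.noise_read_fraction > 0
            else np.zeros(starts.size, dtype=bool)
        )
        offs = np.asarray(scenario.draft_offsets)[segs]
        draft_starts = offs + (starts - bounds[segs])
        for ds, is_noisy in zip(draft_starts, noisy):
            reads.append(
                AlignedRead(
                    contig=DRAFT_CONTIG,
                    start=int(ds),
                    end=int(ds) + params.read_length,
                    barcode=barcode,
                    read_length=params.read_length,
                    mismatches=7 if is_noisy else 0,
                    align_score=noise_as if is_noisy else params.read_length,
                    mapq=60,
                )
            )
        for seg in np.unique(segs):
            piece_start = max(cs, int(bounds[seg]))
            piece_end = min(ce, int(bounds[seg + 1]))
            off = scenario.draft_offsets[int(seg)] - int(bounds[seg])
            truth_molecules.append(
                Molecule(
                    contig=DRAFT_CONTIG,
                    start=piece_start + off,
                    end=piece_end + off,
                    barcode=barcode,
                    read_count=int(np.sum(segs == seg)),
                )
            )
    reads.sort(key=lambda r: (r.barcode, r.start))
    truth_molecules.sort(key=lambda m: (m.contig, m.start, m.end, m.barcode))
    return reads, truth_molecules


@dataclass(frozen=True)
class CutEvaluation:
    """Precision/recall of detected cuts against injected junctions."""

    precision: float
    recall: float
    n_cuts: int
    n_matched_cuts: int
    n_junctions: int
    n_recovered: int


def evaluate_cuts(
    detected: Sequence[tuple[str, int]], truth: TruthSet, tolerance: int
) -> CutEvaluation:
    """Score detected cut coordinates against the truth junctions.

    A cut is matched when its nearest junction on the same contig lies
    within ``tolerance`` bp (each cut matches at most one junction); a
    junction is recovered when at least one cut matches it.  With zero
    detected cuts precision is undefined and reported as 1.0 with a
    warning; with zero junctions recall is vacuously 1.0.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    by_contig: dict[str, np.ndarray] = {}
    junction_ids: dict[str, list[int]] = {}
    for jid, (contig, pos) in enumerate(truth.junctions):
        by_contig.setdefault(contig, []).append(pos)  # type: ignore[union-attr]
        junction_ids.setdefault(contig, []).append(jid)
    for contig in by_contig:
        order = np.argsort(by_contig[contig])
        by_contig[contig] = np.asarray(by_contig[contig])[order]
        junction_ids[contig] = [junction_ids[contig][i] for i in order]

    matched_cuts = 0
    recovered: set[int] = set()
    for contig, pos in detected:
        junctions = by_contig.get(contig)
        if junctions is None or len(junctions) == 0:
            continue
        i = int(np.searchsorted(junctions, pos))
        best, best_d = None, None
        for j in (i - 1, i):
            if 0 <= j < len(junctions):
                d = abs(int(junctions[j]) - pos)
                if best_d is None or d < best_d:
                    best, best_d = j, d
        if best is not None and best_d <= tolerance:
            matched_cuts += 1
            recovered.add(junction_ids[contig][best])

    n_cuts = len(detected)
    n_junctions = len(truth.junctions)
    if n_cuts == 0:
        if n_junctions:
            logger.warning("no cuts detected; precision undefined, reported as 1.0")
        precision = 1.0
    else:
        precision = matched_cuts / n_cuts
    recall = len(recovered) / n_junctions if n_junctions else 1.0
    return CutEvaluation(
        precision=precision,
        recall=recall,
        n_cuts=n_cuts,
        n_matched_cuts=matched_cuts,
        n_junctions=n_junctions,
        n_recovered=len(recovered),
    )


def write_truth_bed(truth: TruthSet, sink) -> None:
    """Write junctions as single-base BED records named junction_<i>."""
    own = not hasattr(sink, "write")
    handle = open(sink, "w") if own else sink
    try:
        for i, (contig, pos) in enumerate(truth.junctions):
            handle.write(f"{contig}\t{pos}\t{pos + 1}\tjunction_{i}\n")
    finally:
        if own:
            handle.close()


def read_truth_bed(source, contig_lengths: dict[str, int]) -> TruthSet:
    """Rebuild a :class:`TruthSet` from a junction BED and contig lengths."""
    own = not hasattr(source, "read")
    handle = open(source) if own else source
    junctions: list[tuple[str, int]] = []
    try:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            junctions.append((fields[0], int(fields[1])))
    finally:
        if own:
            handle.close()
    return TruthSet(contig_lengths=contig_lengths, junctions=tuple(junctions))
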