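"""Synthetic scenario generator structure and the cut evaluator."""

from __future__ import annotations

import numpy as np
import pytest

from molecut.simulate import (
    DRAFT_CONTIG,
    SimParams,
    TruthSet,
    evaluate_cuts,
    read_truth_bed,
    simulate_molecule_alignments,
    simulate_scenario,
    write_truth_bed,
)

SMALL = SimParams(
    genome_length=400_000,
    n_junctions=4,
    molecule_mean_length=30_000,
    molecule_coverage=40.0,
    reads_per_molecule_mean=30,
    min_segment_length=40_000,
    max_molecule_length=100_000,
    seed=11,
)


@pytest.fixture(scope="module")
def small_scenario():
    return simulate_scenario(SMALL)


class TestScenario:
    def test_no_junctions_gives_identity_draft(self):
        params = SimParams(genome_length=400_000, n_junctions=0, seed=3,
                           molecule_mean_length=30_000)
        scenario = simulate_scenario(params)
        assert scenario.truth.junctions == ()
        assert scenario.draft[DRAFT_CONTIG] == scenario.true_genome["genome"]

    def test_junction_structure(self, small_scenario):
        truth = small_scenario.truth
        assert len(truth.junctions) == 4
        length = truth.contig_lengths[DRAFT_CONTIG]
        for contig, pos in truth.junctions:
            assert contig == DRAFT_CONTIG
            assert SMALL.min_segment_length <= pos <= length - SMALL.min_segment_length
        # consecutive draft segments are never adjacent in the true genome,
        # and every junction is too wide for a single molecule to bridge:
        # the true-genome span separating the two sides of each junction
        # exceeds the maximum molecule length
        order = small_scenario.draft_order
        bounds = small_scenario.segment_bounds
        seg_len = [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]
        for a, b in zip(order, order[1:]):
            assert b != a + 1
            if b > a:
                distance = sum(seg_len[a + 1 : b])
            else:
                distance = sum(seg_len[b : a + 1]) - 50_000
            assert distance >= SMALL.max_molecule_length
        # draft is a permutation of the true segments: same base content
        assert sorted(small_scenario.draft[DRAFT_CONTIG]) == sorted(
            small_scenario.true_genome["genome"]
        )

    def test_same_seed_is_byte_identical(self):
        a = simulate_scenario(SMALL)
        b = simulate_scenario(SMALL)
        assert a.draft == b.draft and a.truth == b.truth
        reads_a, mols_a = simulate_molecule_alignments(a)
        reads_b, mols_b = simulate_molecule_alignments(b)
        assert reads_a == reads_b and mols_a == mols_b

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError, match="do not fit"):
            simulate_scenario(
                SimParams(genome_length=400_000, n_junctions=20,
                          molecule_mean_length=30_000, min_segment_length=40_000)
            )


class TestMoleculeAlignments:
    def test_molecules_crossing_junctions_split_at_the_junction(self, small_scenario):
        _, truth_molecules = simulate_molecule_alignments(small_scenario)
        by_barcode: dict[str, list] = {}
        for m in truth_molecules:
            by_barcode.setdefault(m.barcode, []).append(m)
        length = small_scenario.truth.contig_lengths[DRAFT_CONTIG]
        boundaries = {pos for _, pos in small_scenario.truth.junctions} | {0, length}
        split = [pieces for pieces in by_barcode.values() if len(pieces) > 1]
        assert split, "some molecules must cross a junction"
        for pieces in split:
            # every piece of a split molecule stops at a junction (or, for
            # the piece reaching a true-genome end, at a contig end)
            for piece in pieces:
                assert piece.start in boundaries or piece.end in boundaries

    def test_no_simulated_molecule_spans_a_junction(self, small_scenario):
        _, truth_molecules = simulate_molecule_alignments(small_scenario)
        for m in truth_molecules:
            for _, pos in small_scenario.truth.junctions:
                assert not (m.start < pos < m.end)

    def test_reads_lie_within_their_molecule_piece(self, small_scenario):
        reads, truth_molecules = simulate_molecule_alignments(small_scenario)
        pieces: dict[str, list] = {}
        for m in truth_molecules:
            pieces.setdefault(m.barcode, []).append((m.start, m.end))
        for read in reads[:2_000]:
            assert any(
                s <= read.start and read.end <= e for s, e in pieces[read.barcode]
            )

    def test_point_coverage_calibration(self, small_scenario):
        """Mean molecule count over random points matches the target coverage.

        Coverage at points closer than a molecule length is correlated, so
        the standard error uses the effective number of independent molecule
        stacks (genome length / mean molecule length), not the raw number of
        probed points.
        """
        _, truth_molecules = simulate_molecule_alignments(small_scenario)
        rng = np.random.default_rng(99)
        length = small_scenario.truth.contig_lengths[DRAFT_CONTIG]
        points = rng.integers(0, length, size=1_000)
        starts = np.array([m.start for m in truth_molecules])
        ends = np.array([m.end for m in truth_molecules])
        counts = [
            int(np.sum((starts <= p) & (ends > p))) for p in points
        ]
        target = SMALL.molecule_coverage
        n_eff = SMALL.genome_length / (
            SMALL.min_molecule_length + SMALL.molecule_mean_length
        )
        se = np.sqrt(target / n_eff)
        assert abs(np.mean(counts) - target) <= 3 * se

    def test_noise_reads_carry_failing_tags(self):
        params = SimParams(
            genome_length=400_000, n_junctions=0, molecule_mean_length=30_000,
            molecule_coverage=20.0, noise_read_fraction=0.3, seed=5,
        )
        reads, _ = simulate_molecule_alignments(simulate_scenario(params), params)
        noisy = [r for r in reads if r.mismatches >= 5]
        frac = len(noisy) / len(reads)
        assert 0.25 < frac < 0.35
        assert all(r.align_score < 0.65 * r.read_length for r in noisy)


class TestEvaluateCuts:
    TRUTH = TruthSet(
        contig_lengths={"d": 1_000_000},
        junctions=tuple(("d", 50_000 * (i + 1)) for i in range(10)),
    )

    def test_exact_detection_is_perfect(self):
        detected = [(c, p) for c, p in self.TRUTH.junctions]
        result = evaluate_cuts(detected, self.TRUTH, tolerance=1_000)
        assert result.precision == 1.0 and result.recall == 1.0

    def test_no_detections(self):
        result = evaluate_cuts([], self.TRUTH, tolerance=1_000)
        assert result.precision == 1.0 and result.recall == 0.0

    def test_spurious_cuts_dilute_precision(self):
        detected = [(c, p) for c, p in self.TRUTH.junctions] + [
            ("d", 900_000 + i * 10_000) for i in range(5)
        ]
        result = evaluate_cuts(detected, self.TRUTH, tolerance=1_000)
        assert result.precision == pytest.approx(10 / 15)
        assert result.recall == 1.0

    def test_tolerance_boundary(self):
        result = evaluate_cuts([("d", 50_000 + 1_000)], self.TRUTH, tolerance=1_000)
        assert result.n_matched_cuts == 1
        result = evaluate_cuts([("d", 50_000 + 1_001)], self.TRUTH, tolerance=1_000)
        assert result.n_matched_cuts == 0

    def test_truth_bed_roundtrip(self, tmp_path):
        path = tmp_path / "truth.bed"
        write_truth_bed(self.TRUTH, path)
        again = read_truth_bed(path, dict(self.TRUTH.contig_lengths))
        assert again == self.TRUTH
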