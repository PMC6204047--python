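"""Shared fixtures: a tiny hand-written SAM and a full default-scenario run.

The default scenario (1 Mbp genome, 10 junctions, 60 kbp mean molecules,
100x molecule coverage) is simulated and pushed through the whole pipeline
once per session; several tests reuse the artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest

from molecut.alignments import write_alignments_sam
from molecut.cuts import cut_positions_from_regions, read_breakpoints_bed
from molecut.fasta_edit import write_fasta
from molecut.pipeline import PipelineConfig, run_cut, run_molecule
from molecut.simulate import (
    SimParams,
    evaluate_cuts,
    simulate_molecule_alignments,
    simulate_scenario,
)

TINY_SAM = """\
@HD\tVN:1.6\tSO:unsorted
@SQ\tSN:ctg1\tLN:10000
r_unmapped\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*
r_tagged\t0\tctg1\t101\t60\t150M\t*\t0\t0\t*\t*\tNM:i:2\tAS:i:140\tBX:Z:ACGT-1
r_untagged\t0\tctg1\t501\t60\t100M\t*\t0\t0\t*\t*\tNM:i:0\tAS:i:100
"""


@pytest.fixture
def tiny_sam(tmp_path: Path) -> Path:
    path = tmp_path / "tiny.sam"
    path.write_text(TINY_SAM)
    return path


@dataclass(frozen=True)
class ScenarioRun:
    params: SimParams
    scenario: object
    outdir: Path
    config: PipelineConfig
    molecule_stats: dict
    cut_stats: dict
    cuts: list
    evaluation: object


def run_scenario(params: SimParams, outdir: Path, **config_kwargs) -> ScenarioRun:
    """Simulate a scenario and run the full pipeline in ``outdir``."""
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = simulate_scenario(params)
    reads, _ = simulate_molecule_alignments(scenario, params)
    write_fasta([(n, "", s) for n, s in scenario.draft.items()], outdir / "draft.fa")
    write_alignments_sam(reads, scenario.truth.contig_lengths, outdir / "reads.sam")
    config = PipelineConfig(
        draft_fasta=outdir / "draft.fa",
        alignments=outdir / "reads.sam",
        molecule_bed=outdir / "molecules.bed",
        breakpoints_bed=outdir / "breakpoints.bed",
        corrected_fasta=outdir / "corrected.fa",
        **config_kwargs,
    )
    molecule_stats = run_molecule(config)
    cut_stats = run_cut(config)
    cuts = cut_positions_from_regions(read_breakpoints_bed(config.breakpoints_bed))
    evaluation = evaluate_cuts(cuts, scenario.truth, tolerance=config.scan.window)
    return ScenarioRun(
        params=params,
        scenario=scenario,
        outdir=outdir,
        config=config,
        molecule_stats=molecule_stats,
        cut_stats=cut_stats,
        cuts=cuts,
        evaluation=evaluation,
    )


@pytest.fixture(scope="session")
def default_run(tmp_path_factory) -> ScenarioRun:
    """Full pipeline on the default scenario with a fixed seed."""
    return run_scenario(SimParams(seed=1), tmp_path_factory.mktemp("default_run"))


@pytest.fixture(scope="session")
def null_run(tmp_path_factory) -> ScenarioRun:
    """False-positive control: same coverage, no injected junctions."""
    return run_scenario(
        SimParams(seed=1, n_junctions=0), tmp_path_factory.mktemp("null_run")
    )
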