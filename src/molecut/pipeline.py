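"""Stage orchestration: alignments -> molecule BED -> cuts -> corrected FASTA.

Every stage boundary is a plain file in a standard format (SAM/BAM, BED6,
FASTA), so any stage can be rerun in isolation with identical results.  BED
outputs carry a comment line recording the tool version and the exact
parameter set (no timestamps, keeping reruns byte-identical); the corrected
FASTA gets a small JSON sidecar with the same metadata.
"""

from __future__ import annotations

import json
import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .alignments import ReadFilterParams, filter_reads, parse_barcoded_alignments
from .coverage import ScanParams, build_interval_index, compute_support_profile
from .cuts import find_cut_points, write_breakpoints_bed
from .fasta_edit import apply_cuts, read_fasta
from .molecules import (
    MoleculeParams,
    filter_molecules,
    group_into_molecules,
    read_molecule_bed,
    write_molecule_bed,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths plus the per-stage parameter sets (defaults match the method's)."""

    draft_fasta: Path | None = None
    alignments: Path | None = None
    molecule_bed: Path | None = None
    breakpoints_bed: Path | None = None
    corrected_fasta: Path | None = None
    barcode_tag: str = "BX"
    read_filter: ReadFilterParams = field(default_factory=ReadFilterParams)
    molecule: MoleculeParams = field(default_factory=MoleculeParams)
    scan: ScanParams = field(default_factory=ScanParams)
    # optional shell-outs; never reimplemented here
    reads_fastq: Path | None = None
    aligner_cmd: str | None = None
    post_hook: str | None = None

    def metadata(self) -> str:
        p = self
        return (
            f"molecut {__version__} nm={p.read_filter.max_mismatches} "
            f"as_ratio={p.read_filter.min_score_ratio} mapq={p.read_filter.min_mapq} "
            f"bx_tag={p.barcode_tag} dist={p.molecule.max_read_gap} "
            f"minsize={p.molecule.min_molecule_size} "
            f"min_reads={p.molecule.min_reads_per_molecule} "
            f"window={p.scan.window} span={p.scan.min_spanning}"
        )


def run_molecule(config: PipelineConfig) -> dict:
    """Parse alignments, filter reads, group and filter molecules, write BED."""
    if config.alignments is None or not Path(config.alignments).exists():
        raise FileNotFoundError(
            f"alignment input {config.alignments!r} not found; provide a SAM/BAM "
            "with per-read barcode tags"
        )
    if config.molecule_bed is None:
        raise ValueError("molecule_bed output path is required")
    reads = list(
        parse_barcoded_alignments(config.alignments, barcode_tag=config.barcode_tag)
    )
    kept = filter_reads(reads, config.read_filter)
    if reads and not kept:
        logger.warning(
            "all %d reads were filtered out (missing %s tags?)",
            len(reads),
            config.barcode_tag,
        )
    grouped = group_into_molecules(kept, config.molecule)
    retained = filter_molecules(grouped, config.molecule)
    write_molecule_bed(retained, config.molecule_bed, header=config.metadata())
    stats = {
        "reads_in": len(reads),
        "reads_retained": len(kept),
        "molecules_grouped": len(grouped),
        "molecules_retained": len(retained),
    }
    logger.info(
        "molecule stage: %(reads_in)d reads in, %(reads_retained)d retained, "
        "%(molecules_grouped)d molecules, %(molecules_retained)d after filtering",
        stats,
    )
    return stats


def run_cut(config: PipelineConfig) -> dict:
    """Scan each draft contig for unsupported runs, cut, and write outputs."""
    for name, path in (
        ("draft_fasta", config.draft_fasta),
        ("molecule_bed", config.molecule_bed),
    ):
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"{name} input {path!r} not found")
    if config.breakpoints_bed is None or config.corrected_fasta is None:
        raise ValueError("breakpoints_bed and corrected_fasta outputs are required")

    contigs = read_fasta(config.draft_fasta)
    lengths = {name: len(seq) for name, seq in contigs}
    molecules = read_molecule_bed(config.molecule_bed)
    unknown = {m.contig for m in molecules} - set(lengths)
    if unknown:
        raise ValueError(
            f"molecule BED references contigs absent from the FASTA: "
            f"{sorted(unknown)}"
        )
    index = build_interval_index(molecules)
    plans = []
    per_contig_cuts = {}
    for name, _ in contigs:
        profile = compute_support_profile(index, name, lengths[name], config.scan)
        plan = find_cut_points(profile, config.scan)
        plans.append(plan)
        per_contig_cuts[name] = len(plan.cut_positions)
    write_breakpoints_bed(plans, config.breakpoints_bed, header=config.metadata())
    segments = apply_cuts(config.draft_fasta, plans, config.corrected_fasta)
    sidecar = Path(str(config.corrected_fasta) + ".meta.json")
    sidecar.write_text(
        json.dumps(
            {"metadata": config.metadata(), "cuts_per_contig": per_contig_cuts},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    total_cuts = sum(per_contig_cuts.values())
    logger.info(
        "cut stage: %d cuts across %d contigs, %d output segments",
        total_cuts,
        len(contigs),
        len(segments),
    )
    return {
        "contigs": len(contigs),
        "cuts": total_cuts,
        "segments": len(segments),
        "cuts_per_contig": per_contig_cuts,
    }


def run_all(config: PipelineConfig) -> dict:
    """Run molecule then cut stages; optionally align first / post-hook after.

    When ``alignments`` is absent but ``reads_fastq`` and ``aligner_cmd``
    are provided, the user-supplied command template is executed with
    ``{reads}``, ``{draft}`` and ``{out}`` placeholders.  ``post_hook``
    (e.g. a scaffolder invocation) runs after the corrected FASTA exists,
    with ``{fasta}`` expanded.
    """
    if config.alignments is None or not Path(config.alignments).exists():
        if config.reads_fastq is None or config.aligner_cmd is None:
            raise FileNotFoundError(
                "no alignments found and no reads + aligner command supplied"
            )
        executable = config.aligner_cmd.split()[0]
        if shutil.which(executable) is None:
            raise FileNotFoundError(
                f"external aligner {executable!r} not found on PATH"
            )
        out = config.alignments or Path(str(config.reads_fastq) + ".sam")
        cmd = config.aligner_cmd.format(
            reads=config.reads_fastq, draft=config.draft_fasta, out=out
        )
        logger.info("running external aligner: %s", cmd)
        subprocess.run(cmd, shell=True, check=True)
        config.alignments = out
    stats = {"molecule": run_molecule(config), "cut": run_cut(config)}
    if config.post_hook:
        cmd = config.post_hook.format(fasta=config.corrected_fasta)
        logger.info("running post-hook: %s", cmd)
        subprocess.run(cmd, shell=True, check=True)
    return stats
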