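# molecut

Correct misassemblies in draft genome assemblies using the physical
coverage of linked-read molecules.

Linked reads (e.g. 10x Genomics Chromium) are short reads barcoded by the
long DNA molecule they came from. Aligning them to a draft assembly lets
one reconstruct each molecule's extent: same-barcode reads that map within
50 kbp of each other are chained into an inferred molecule. At a
misassembled join no physical molecule crosses the junction, so although
read depth may look normal, the number of molecules *spanning* the region
drops to zero. molecut scans every contig with a 1 bp-step sliding window
(1000 bp wide by default), flags windows spanned by fewer than 20
molecules, and cuts the assembly after the last base of the well-covered
window preceding such a run and before the first base of the well-covered
window following it. Runs touching contig ends — where spanning coverage
must fall off — are left alone.

For a window of size w starting at position i, the spanning count is

    n(i) = #{ molecules m : m.start <= i  and  m.end >= i + w }

and position i is well-covered when n(i) ≥ s (default s = 20). Read-level
filters NM < 5 and AS ≥ 0.65·l are applied before molecule inference;
molecules shorter than 2 kbp or with fewer than 4 reads are discarded.

The package is aimed at assembly workflows with linked-read data at hand:
correcting a draft before scaffolding typically costs little contiguity and
removes a large fraction of large-scale misassemblies, which in turn lets a
barcode-based scaffolder join far more aggressively.

A synthetic scenario generator (`molecut simulate`) builds a random genome,
a draft with injected misassembly junctions and the corresponding barcoded
read alignments, so the whole pipeline can be exercised and scored without
any external data.

## Worked example

Simulate a 400 kbp genome whose draft contains 3 misassembly junctions,
run the pipeline, and score the detected breakpoints against the truth:

```sh
molecut simulate --outdir sim --genome-length 400000 --junctions 3 \
    --molecule-length 30000 --coverage 40 --max-molecule-length 100000 --seed 4
molecut run sim/draft.fa sim/reads.sam --outdir out
molecut evaluate out/breakpoints.bed sim/truth.bed sim/draft.fa
```

which prints

```
wrote scenario with 3 junctions, 28737 reads to sim
INFO molecule stage: 28737 reads in, 28737 retained, 713 molecules, 661 after filtering
INFO cut stage: 6 cuts across 1 contigs, 7 output segments
precision	recall	cuts	matched_cuts	junctions	recovered
1.0000	1.0000	6	6	3	3
```

Each injected junction produced a pair of cuts tightly flanking it (a
clean coverage break collapses to a single cut exactly at the junction),
every cut matched a true junction (precision 1.0) and every junction was
recovered (recall 1.0). `out/corrected.fa` contains the 7 segments; pieces
of a split contig are named `draft_1-1`, `draft_1-2`, … with the parent
interval in the description, and concatenating them reproduces the draft
exactly.

With real data, replace `sim/reads.sam` with your barcode-tagged BAM
(barcode in the `BX` tag, e.g. from Long Ranger) aligned to the draft, and
tune `--window`/`--span` if desired (`--window 2000` is a good setting for
human-scale assemblies). Stages can also be run separately as
`molecut molecule` and `molecut cut`, with the molecule BED as the
intermediate artifact.

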