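# Methods

## The model

Linked-read sequencing partitions long DNA molecules (tens to hundreds of
kilobases) into droplets, tags all fragments from a partition with a shared
barcode, and sequences them as short reads. Reads carrying the same barcode
therefore trace the extents of a handful of long molecules. When a draft
assembly joins two loci that are not adjacent in the genome, no physical
molecule crosses the join: molecules approaching from the left end at it,
molecules on the right start at it. Read-level depth can look perfectly
normal across such a join (especially at repeats), but *molecule spanning
coverage* — the number of inferred molecules whose extent contains a whole
region — collapses. molecut detects these collapses and cuts the draft
there.

The pipeline is four stages, each a pure file-to-file transformation:

1. **Read filtering** (`alignments`). Primary mapped alignments with a
   barcode tag (`BX` by default) are kept when the edit distance satisfies
   NM < 5 (strict) and the alignment score satisfies AS ≥ 0.65·l (inclusive),
   where l is the read length. Secondary, supplementary and duplicate
   records are dropped so a read can support at most one molecule;
   mate-pair relationships are ignored and each read end is treated
   independently. No mapping-quality filter is applied by default
   (`--mapq 0`), but the gate exists for noisy aligners.
2. **Molecule inference** (`molecules`). Same-barcode reads on one contig
   are sorted by start and chained while consecutive starts are within
   50 kbp (the partitioning distance used by 10x's own tools; values
   between 20 and 100 kbp behave similarly). The chain's min start / max
   end become the molecule extent, written as BED6 with the barcode as name
   and the read count as score. Molecules shorter than 2 kbp, or with fewer
   than 4 reads, are discarded as alignment noise. The 50 kbp rule is
   measured between *start* coordinates of consecutive reads; measuring
   inter-read gaps instead would differ only by one read length and is not
   exposed.
3. **Spanning scan** (`coverage`). A molecule spans a window when its
   extent contains the window entirely — inclusive at both ends, so
   molecule (100, 5000) spans window [100, 1100). This is the natural
   extension of "a molecule spans a point when it has reads on both sides"
   to fixed windows, since extents are delimited by read alignments. Every
   contig is scanned with a window of 1000 bp at a step of 1 bp; a window
   is well-covered when at least 20 molecules span it. The scan is computed
   with a difference vector over window start positions (a molecule (s, e)
   supports starts s … e−w), in O(molecules + contig length); an interval
   tree answers ad-hoc window queries. Both paths are verified against an
   O(n·L) brute-force scan in the tests. Contigs shorter than the window
   have an empty profile and are never cut; the trailing partial windows of
   a contig are not evaluated.
4. **Cutting** (`cuts`, `fasta_edit`). For each maximal run of
   poorly-covered window starts [p, q] flanked by well-covered windows on
   *both* sides, the contig is cut after the last base of the preceding
   well-covered window — position (p−1)+w — and before the first base of
   the following one — position q+1. Runs touching a contig end are
   ignored: ends are always poorly covered (no molecule extends past the
   sequence) and trimming them would delete sequence without evidence.
   When the poor run is shorter than the window the two formulas cross and
   collapse to their midpoint; a sharp coverage break at position j
   produces the run [j−w+1, j−1] and both cuts land exactly on j, so clean
   junctions yield a single cut at the junction. Each excised region
   becomes one breakpoints-BED record (zero-length for collapsed pairs).
   The FASTA splitter retains every piece, including the poorly-supported
   middle, renames split pieces `<parent>-<ordinal>`, and guarantees that
   concatenating a parent's segments reproduces it byte-for-byte.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `--nm` | 5 | keep reads with NM strictly below |
| `--as-ratio` | 0.65 | keep reads with AS ≥ ratio·read length |
| `--mapq` | 0 | minimum mapping quality (0 = off) |
| `--dist` | 50 000 bp | max start-to-start distance chaining same-barcode reads |
| `--minsize` | 2 000 bp | minimum molecule extent |
| `--min-reads` | 4 | minimum reads per molecule |
| `--window` | 1 000 bp | spanning window size w |
| `--span` | 20 | minimum spanning molecules per window |

For real human-scale data a window of 2000 bp with span 20 is a robust
choice; a smaller window (1000 bp) makes markedly fewer, more precise cuts
at a small cost in sensitivity. Results are insensitive to `--dist` between
20 and 100 kbp and to `--span` up to ~50 at typical molecule coverages.

## The synthetic scenario generator

`simulate` builds a uniform-random genome, partitions it into segments
(each at least `min_segment_length`, 50 kbp by default, so junctions stay
far from contig ends and from each other), and concatenates the segments in
a shuffled order to form the draft; every boundary between shuffled
segments is an injected misassembly junction. The shuffle is constrained so
that no junction can be *bridged*: for each consecutive pair of draft
segments, the true-genome span a molecule would need in order to place
reads on both sides of the junction (the intervening true sequence for a
forward jump; the whole covered stretch minus one chaining gap for a
backward jump) must be at least the maximum molecule length. Without this
constraint a long molecule covering an entire intervening segment chains
reads across the junction and masks the dropout, making the junction
undetectable by construction rather than by the method's limits. A
randomized greedy order with restarts satisfies the constraint; if the
segment geometry admits no such order the generator falls back to
forbidding direct adjacency only and warns.

Molecules are placed on the *true* genome: lengths are minimum + Exp(mean)
(the exact exponential-truncated-below distribution, LRSim-like), capped at
`max_molecule_length`; starts are uniform over all placements intersecting
the genome, and molecules are drawn until their point-coverage
probabilities sum to the target mean coverage, which makes expected
coverage uniform along the genome. Each molecule gets a unique barcode and
a Poisson number of uniformly placed reads proportional to its length.
Read coordinates are mapped through the segment map onto the draft, so a
molecule crossing a junction in true space yields two draft-local read
groups that both stop at the junction. Reads straddling a segment boundary
are dropped, as an aligner would split or clip them. Reads are emitted as
valid SAM (all-match CIGAR, NM=0, AS=l, BX tag) so the real parser and
filters run end to end; `noise_read_fraction` marks a random read subset
with NM=7 and AS=0.55·l to exercise the filters. There is no base-level
error model, no barcode collision between molecules, no mapping ambiguity
and no inversion of segment orientation — so passing tests demonstrate the
coverage logic and coordinate bookkeeping, not robustness to alignment
artifacts of real repeat-rich genomes.

Default scenario: 1 Mbp genome, 10 junctions, 60 kbp mean molecules at
100× molecule coverage, 60 reads per molecule of 150 bp (≈ 15× read
depth). At these settings the expected spanning count of a 1 kbp window is
≈ 95, far above the threshold of 20, so interior windows essentially never
dip spuriously, while windows overlapping a junction are spanned by ≈ 0
molecules — the detection margin is wide by design, as it is in real
linked-read data at recommended coverage.

## Evaluation

`evaluate_cuts` matches each detected cut to its nearest truth junction on
the same contig; the cut is matched when that distance is within a
tolerance (default: one window). Precision is matched cuts over all cuts,
recall is junctions with at least one matched cut over all junctions. With
zero cuts precision is reported as 1.0 (with a warning); with zero
junctions recall is vacuously 1.0. This uses injected-junction truth; at
genome scale the analogous evaluation would use reference-alignment-defined
misassemblies, which requires external references and evaluation tools.

Problem sizes used throughout the tests and the acceptance script — 1 Mbp
genomes (400 kbp for structural unit tests, with molecule lengths capped at
100 kbp to stay proportionate), 20 seeds for the recall average, 100 random
instances for oracle equivalence — were chosen so each property is measured
with comfortable statistical margin at desk scale.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere; SAM positions convert at
  the parse boundary, BED records are written as stored.
* Reads at identical positions chain normally; grouping output is sorted by
  (contig, start, end, barcode) and is invariant to input read order.
* Missing NM is read as 0 and missing AS as a perfect score, so untagged
  SAM files pass the filters instead of silently vanishing.
* An unknown contig in a spanning query returns 0 with a warning (contigs
  without molecules are legal); an empty molecule set yields an all-poor
  profile and hence no cuts.
* Identical molecule extents from different barcodes are indexed as
  distinct intervals and each counts toward spanning coverage.
* Outputs carry the tool version and full parameter set in BED comment
  lines and a JSON sidecar next to the corrected FASTA, never timestamps,
  so reruns are byte-identical.

## Known limitations

* Misassemblies smaller than a typical molecule — collapsed repeats, small
  relocations and inversions — do not interrupt molecule spanning coverage
  and cannot be detected by this approach.
* Cut placement is resolved to roughly the spacing of reads within
  molecules (a few hundred bp at default coverage), not to the base.
* The generator's drafts are single-contig and orientation-preserving;
  inversions and multi-contig drafts exercise no additional code paths in
  the detector (molecules are per-contig) but are not emulated.
* `run` can shell out to a user-supplied aligner command and post-hook
  (e.g. a scaffolder); neither is bundled or reimplemented.
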