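# Methods

## Repeat-period spectrum (GRM)

For a sequence S and key length k (default 8), every k-mer occurring at
least twice on the forward strand contributes the start-to-start
distances between its consecutive occurrences to a histogram restricted
to a window [length_min, length_max] (default [1,000, 6,000] bp for
NBPF-scale work; any window with length_min ≥ k is accepted for surveys).
Keys containing N are skipped. Aggregating over *all* repeated keys
rather than one chosen key makes the spectrum robust to mutations in any
single key: a tandem array with unit L and m copies concentrates mass at
L, 2L, … (m−1)L, each phase of the unit contributing independently.
Only the forward strand is scanned — tandem periodicity is
strand-symmetric, so the reverse strand would double cost without moving
peak positions.

Peak calling smooths the dense histogram with a centered moving sum
(default 21 bins) and takes local maxima with prominence ≥ a threshold
(default 5× the median nonzero bin count) via `scipy.signal.find_peaks`,
sorted by descending prominence with ties broken by ascending length.
A maximum sitting exactly on the window boundary is not called; widen the
window if a period of interest sits at its edge. The defaults are
explicit, configurable choices — qualitative "pronounced/weak/absent"
judgements need a stated criterion to be reproducible.

## Monomer scanning

Each consensus monomer is aligned to the subject in semi-global ("infix")
mode — query fully aligned, subject ends free — with unit costs for
substitutions and indels (edlib). Both strands are searched; minus-strand
hits are reported in forward coordinates with strand `-` and a
reverse-complemented matched sequence. Hit divergence is
`edit_distance / consensus_length × 100`: normalizing by the fixed query
keeps thresholds comparable across hits whatever indels do to the hit
interval length.

Candidates up to the divergence cap are enumerated exhaustively without
windowing artifacts: take every best-scoring location, mask it with N
(N matches nothing in an ACGT query, so masked ground cannot re-align
cheaply), re-align, and repeat until the best score exceeds the cap.
Alignments whose subject interval deviates more than ±20% from the
consensus length are rejected — these are pathological gap-heavy
alignments that appear at permissive thresholds. Pooled candidates from
all consensi and strands are then reduced greedily by ascending
divergence (ties: ascending start, then label order, then `+` before
`-`); a candidate is kept iff it overlaps each kept hit by at most 10% of
its own length. The 10% tolerance matters because true neighbouring
monomers abut and boundary jitter of a few bases must not suppress one of
them. Every stage is deterministic; re-runs are bit-identical.

Degenerate inputs: a consensus longer than the subject is an error; N
runs in the subject score as mismatches, so hits spanning assembly gaps
are conservatively penalized.

## Classification and consensus

Monomers are grouped by single-linkage clustering under the symmetric
divergence `edit_distance / max(len a, len b) × 100` with a cutoff
(default 5%, the threshold conventional for alpha-satellite monomer
typing). Single linkage is the natural reading of "groups under a
divergence threshold": it is deterministic, order-independent up to
relabeling, and tolerant of the chained similarity structure of
near-periodic tandem arrays. Classes are labelled m1, m2, … by their
first member's position, so identical inputs give identical outputs.
Raising the cutoff can only merge classes, never split them.

The per-class consensus aligns every member semi-globally to the medoid
(the member minimizing summed divergence to all others; ties go to the
earliest member), then votes per medoid column over {A, C, G, T, gap}.
Gap wins a column only on strict majority over the best base (and the
column is then dropped); base ties break in the fixed order A < C < G <
T; insertions relative to the medoid are not voted — each is private to
one member and would lose a gap-majority vote anyway. This makes the
consensus idempotent (a class containing only its consensus reproduces
it exactly) and recovers a planted ancestor to within ~0.1% from 20
members at 2% noise.

Two divergence definitions coexist deliberately: hit divergence is
query-relative (thresholds comparable across hits), consensus/clustering
divergence is max-length-normalized (symmetric, zero iff identical, as
the divergence-table symmetry invariant requires).

The divergence table emits within-species cross-label records (m1/m2,
m1/m3, m2/m3), cross-species same-label records, and one mean record per
species pair (mean over the shared labels, labelled `<species>-mean`).
Record-level output lets users recompute any aggregate they prefer.

## HOR parsing and tandem arrays

Sorted hits are chained: consecutive same-strand hits with gap
(next.start − prev.end) ≤ gap_max (default 500 bp — NBPF monomers abut,
and "separated" arrays are megabases apart, so any value in the
hundreds-to-thousands range gives the same partition) belong to one
chain; minus-strand chains are read right-to-left, their reading
orientation. Within a chain the parse is greedy left-to-right: a copy is
a maximal run ascending the canonical order one step at a time, so
(m1, m2, m3) is canonical, while (m1, m2), (m2, m3) or a lone monomer are
variants. Greedy parsing anchored on ascending runs reproduces observed
canonical/variant decompositions without combinatorial search, and it
partitions the hits — no hit is dropped or counted twice.

Chains of parsed copies with inter-copy gap ≤ gap_max and ≥ min_copies
(default 2) become tandem arrays A1, A2, … in positional order; shorter
chains are "individual" copies, excluded from arrays. The headline count,
canonical copies in tandem, is the sum of canonical copies over arrays;
with a run filter r > 0 only maximal canonical runs longer than r are
counted. Because "more than three copies" admits two readings, the
summary JSON reports both the per-run filter (runs > 3) and the
per-array filter (arrays with > 3 copies); they differ whenever long
arrays contain short canonical runs.

The rendered scheme prints one row per copy — 1-based start position,
`(-)` for reverse-complement copies, monomer types in aligned columns
with blanks for absent types — with arrays separated by blank lines, plus
machine-readable TSV/JSON with identical content.

## MD diagram

For hits grouped per array in reading order, each hit with a later
same-type hit in the *same* array within max_period positions (default
10) yields a point (enumeration, period, bp distance); enumeration is
global and 1-based over tandemly arrayed monomers. Successor search does
not cross array boundaries: together with variant insertions this
produces the blank spaces that split period-3 segments, and a pure n-mer
tandem of c copies yields exactly n·(c−1) points at period n.
`period_segments` counts maximal consecutive-enumeration runs at a given
period (≥ 2 points), the "horizontal line segments" of the diagram.

## Synthetic genomes

The generator plants tandem arrays of monomers with exact truth records.
Ancestral types are independent uniform-random sequences
rejection-sampled to ≥ 10% mutual divergence, so classification at the 5%
working threshold has a unique correct answer; each planted monomer is an
i.i.d.-mutated copy of its ancestor (per-base substitutions, insertions
and deletions each at half the indel rate), and indels shift all
downstream truth coordinates exactly because instances are concatenated
as generated. Minus-strand arrays are built in reading orientation and
reverse-complemented whole. Arrays are separated by uniform-random
spacers (default 2,000 bp, comfortably above gap_max). Identical specs,
including the seed, give bit-identical output.

Default noise is 2% substitutions + 0.2% indels — the intra-type
variation level at which full-pipeline recovery is exact — and the
species presets encode, at copy-level resolution, the canonical/variant
inventories reported for the four complete chromosome-1 assemblies: six
human arrays (A3 split 4 canonical / 4 2mer variants / 10 canonical /
1 variant; one array reverse-complemented to exercise strand handling),
gorilla's one 3-canonical and three 2-canonical short tandems (9
canonical in tandem), chimpanzee's 2mer variants only, orangutan's single
monomer. The published record gives A1 = 5 and A2 = 9 copies but not
their canonical/variant split; with A3–A6 contributing 50 canonical
copies, a total of 61 forces 11 canonical among A1+A2, and the preset
realizes this as A1 = 5 canonical, A2 = 6 canonical + 3 2mer variants —
the simplest split consistent with all published counts.

What the generator does not emulate: divergent monomer relatives beyond
the 5% cap (so the 20%-threshold counts, which on real chromosomes rise
above the 5% counts, have no synthetic counterpart), GC/composition
structure, segmental duplication or gene-conversion history, and
correlated within-type similarity. The last point has a visible
consequence: under i.i.d. noise, intra-type *pairwise* divergence
concentrates near twice the per-copy rate (~4.4% at default noise), so
single-linkage clustering at 5% occasionally splits an outlier monomer
into a singleton class on unlucky seeds, where real arrays, with chained
similarity, classify cleanly. Passing tests on synthetic data therefore
demonstrate correctness of the machinery under the stated noise model,
not performance on real chromosomes.

## Problem sizes

The test suite and acceptance script run on synthetic chromosomes of
~5 kb–350 kb (up to ~205 planted monomers of 1,600 bp), with brute-force
oracle comparisons on instances up to ~50 kb — sizes at which quadratic
reference implementations remain exact and fast. The detection stack
itself streams chromosome-scale FASTA; the chromosome-1 reproduction
tests activate when the corresponding assemblies are placed under
`data/`.
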