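# horkit

Detection and annotation of NBPF-like higher-order repeats (Olduvai
triplets) in chromosome-scale sequences.

## The problem

NBPF genes on human chromosome 1 are built from ~1.6 kb tandem repeat
units ("NBPF monomers", or Olduvai sequences). Three monomer types —
m1, m2, m3 (HLS1/HLS2/HLS3 in the alternative nomenclature) — recur in
the fixed order (m1, m2, m3), forming a ~4.8 kb **canonical 3mer
higher-order repeat (HOR)**, the Olduvai triplet. Copies deviating from
the canonical pattern (a 2mer m1,m2 or a lone m1) are **variant HOR
copies**. Runs of adjacent copies form **tandem arrays**, and the number
of canonical copies organized in tandem differs sharply between humans
and the other great apes, which makes it an interesting evolutionary
signature. Quantifying it requires a complete detection stack, which this
package provides as a library and a `horkit` CLI:

* **grm** — the *global repeat map* (GRM) spectrum: a histogram of
  distances between consecutive occurrences of every repeated k-mer key.
  A tandem repeat of unit L puts mass at L and its multiples, so peaks
  reveal repeat periods (~1.6 kb monomer, ~3.2 kb 2mer, ~4.8 kb 3mer HOR)
  without any prior model.
* **scan** (monfinder) — semi-global alignment of consensus monomers
  against both strands of a subject sequence (edlib, unit edit costs),
  reporting every occurrence with divergence
  `edit_distance / consensus_length × 100 ≤` a cap (default 5%), with
  greedy resolution of overlapping candidates.
* **classify** — single-linkage clustering of extracted monomers at a
  divergence threshold (`edit_distance / max(len) × 100`), majority-vote
  consensus per class, and within/cross-species consensus divergence
  tables (**divtable**).
* **hor** — greedy parsing of the ordered hit list into canonical/variant
  HOR copies, grouping into tandem arrays (A1, A2, … in positional
  order), canonical-copy counts with run-length filters, and the aligned
  monomeric scheme (one row per copy, 1-based start positions,
  reverse-complement copies marked).
* **md** — the monomer-distance (MD) diagram: for each monomer in a
  tandem array, the number of monomer positions (the *period*) to the
  next monomer of the same type, against its enumeration index. An n-mer
  HOR appears as a horizontal segment at height n.
* **simulate** — planted-truth synthetic genomes with configurable HOR
  architecture (copy numbers, variant insertions, reverse-complement
  arrays, substitution/indel noise), used throughout the test suite.

## Worked example

Simulate a human-like chromosome segment (six tandem arrays, 61 canonical
copies planted, 2% substitution + 0.2% indel noise) and run the full
pipeline using the simulation's ancestral monomers as consensus queries:

```
$ horkit simulate --preset human --seed 1 --out-prefix human
342002 bp, 205 planted monomers
$ horkit run --fasta human.fa --consensus human.ancestors.fa --out-dir out
{"monomer_hits": 205, "n_arrays": 6, "canonical_in_tandem": 61}
```

All 205 planted monomers are recovered, grouped into six tandem arrays
containing 61 canonical 3mer copies in total. `out/scheme.txt` holds the
aligned monomeric scheme:

```
# A1  copies=5 canonical=5 variant=0
        2001  m1 m2 m3
        6798  m1 m2 m3
       11596  m1 m2 m3
       16401  m1 m2 m3
       21198  m1 m2 m3
```

Each row is one HOR copy: its 1-based genomic start (suffixed `(-)` for
reverse-complement copies) and its monomer types in aligned columns —
variant copies leave blank columns. Per-array composition lands in
`out/summary.json`:

```
A1 5 copies, 5 canonical, runs [5]      A4 13 copies, 13 canonical, runs [13]
A2 9 copies, 6 canonical, runs [6]      A5 13 copies, 11 canonical, runs [11]
A3 19 copies, 14 canonical, runs [4,10] A6 13 copies, 12 canonical, runs [12]
```

`out/md.tsv` is the MD diagram: here its points form seven horizontal
segments at period 3 (array A3 contributes two, split by its block of
four 2mer variants). `horkit grm --fasta human.fa --out spectrum.tsv`
computes the repeat-period spectrum, whose top peak sits at ~4800 bp —
the 3mer HOR period.

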