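# Methods

## Model and assumptions

`methdirect` targets directional WGBS libraries: reads derive from the
two bisulfite-converted genomic strands, not their PCR complements.
Forward-strand reads show C→T conversions against the forward reference;
reverse-strand reads, after reverse complementation, show G→A. Matching
is therefore asymmetric — a read T is a free match on a reference C (and
read A on reference G for the reverse strand), while the opposite
direction costs one edit. CpG methylation is treated as strand-symmetric:
evidence from the C (forward reads) and from the G at pos+1 (reverse
reads) is pooled into a single rate per CpG. Non-CpG (CHH/CHG) calling,
PBAT/non-directional protocols, soft clipping and mapping-quality scores
are out of scope.

## Index

* **Windows.** Chromosomes are tiled with non-overlapping half-open
  windows of `window_size = 2000` bp (the last window may be shorter).
  Each CpG belongs to the window containing its C. 2 kb balances
  retrieval selectivity against candidate-set size for ≤ 150 bp reads and
  ≤ 1 kb inserts; reads longer than half a window are rejected.
* **Spaced seed.** Default span 20, wildcards at offsets 4, 9, 14
  (weight 17). The interior wildcards let a k-mer survive an isolated
  base-call error (the simulator's Poisson mean is 0.5 errors per 100 bp,
  so errors are nearly always isolated); the first and last positions are
  always care positions. Configurable via `IndexConfig`/`--config`.
* **Hashing.** Rotate-XOR of fixed 64-bit per-letter constants, each
  rotated by its care-position offset from the seed end — a form that
  admits incremental (rolling) updates along the sequence; the
  implementation evaluates it vectorised per chromosome. Sequences are
  reduced C→T before hashing (both for the forward sequence and for the
  reverse complement, whose reduction corresponds to G→A on forward
  coordinates), so converted read k-mers collide with their origin.
  Hash collisions are tolerated: Phase-1 counts are upper bounds and
  Phase 2 verifies every candidate.
* **Stride.** Every second k-mer start (anchored at offset 0 of each
  strand representation) is indexed; reads are scanned at stride 1, so
  phase can never cause a miss.
* **Optimizations.** (1) Entries of one cell sharing (window, strand)
  are merged; their T-bitmasks are combined with AND, which is
  conservative — a bit survives only if *every* merged occurrence has a
  genuine reference T there, so the later rejection test can never
  produce a false rejection. (2) Cells with more than `filter_t = 1500`
  post-merge entries are emptied (repeat regions). (3) Each entry's
  T-bitmask marks care positions that are T in the unconverted
  reference; a read with C at such a position cannot originate there and
  the entry is skipped before counting.
* **N handling.** k-mers whose span overlaps an N are never indexed or
  queried; CG dinucleotides with literal C and G are CpGs regardless of
  flanking Ns. All coordinates are 0-based half-open.

## Alignment

* **Phase 1.** Distinct read-k-mer hashes are tallied per (window,
  strand); a window passes with ≥ `q = 5` hits, alone or pooled with an
  adjacent same-strand window (both pass), which guarantees reads
  straddling a window boundary still reach q. Because both strand
  representations are in the index, a single lookup pass over the read's
  own reduced k-mers retrieves candidates for both strands.
* **Phase 2.** A Wu–Manber-style k-error Shift-And automaton
  (`max_errors = 5` by default — ample for Poisson(0.5) errors on
  ≤ 150 bp reads while bounding automaton depth) runs over each candidate
  window extended by (read length − 1) bp on both sides. Bitvectors are
  arrays of 64-bit words, so read length is unbounded. Reverse-strand
  candidates are verified by matching the reverse-complemented read
  against the forward reference under the G-asymmetry.
* **Uniqueness.** A read is used only if exactly one genomic placement
  attains the minimal error count. Equal-cost hits at adjacent end
  positions (a mismatch at the read's last base is reachable as a
  substitution or as a trailing insertion) are resolved by computing each
  tied hit's alignment *start*: hits sharing (chrom, strand, start) are
  one placement. Genuinely distinct placements tie ⇒ the read is
  ambiguous and contributes nothing.
* **Paired-end.** Candidates of one mate survive only if the other mate
  has a candidate in the same or an adjacent window on the opposite
  strand. The selected pair minimises total errors among opposite-strand
  combinations whose 5′-to-5′ distance lies within
  [`insert_min` = 0, `insert_max` = 1000]; ties make both mates
  ambiguous and there is no single-end rescue. "Insert size" is the
  distance between the mates' 5′-most reference coordinates (the
  simulator's 100–400 bp bound is start-to-start of the leftmost
  coordinates; with 100 bp reads the 5′-to-5′ distance is then
  199–499 bp, inside the default bounds).
* **Phase 3.** The unique hit is re-aligned to the original, unreduced
  reference with a banded semi-global Levenshtein DP under the same
  asymmetric costs; the band width equals the hit's error count, centred
  on the hit diagonal. Traceback prefers substitution over
  deletion-from-read over insertion-in-read on ties; among equal-cost end
  columns the leftmost is taken. If the band cannot reproduce the
  Phase-2 cost an internal consistency error is raised (bug trap). When
  the pure-diagonal (band-0) cost already equals the Phase-2 error count
  the DP is skipped — the diagonal alignment is exactly what the
  tie-break would return, so results are identical; this is the common
  case because the only free substitutions lie on the diagonal.
* **Counting.** Match/substitution columns over a CpG's informative base
  update the counters immediately: C ⇒ methylated / T ⇒ unmethylated on
  the forward strand, G/A on the reverse. Other bases, and CpG bases
  under indels, are ignored — never counted as unmethylated. A fragment
  contributes at most one observation per CpG: the second mate skips
  cpg_ids the first mate already counted (masking by position or by
  aligned span both miss the edge case where one mate reads the C and the
  other reads the G of the same CpG). Uncovered CpGs are emitted as NA.
* **Determinism and threading.** With `--threads n`, fixed-size chunks
  are processed into private accumulators and merged; merging is
  commutative, so the output is bit-identical to the serial run for any
  worker count or read order.

## Simulator

The generator emulates a high-quality directional WGBS experiment on any
reference: uniform read starts over positions whose read window contains
no N, uniform strand; per-CpG true rates drawn once per dataset (fair
coin between N(0.2, 0.08) and N(0.8, 0.08), clamped — not redrawn — to
[0, 1], so tests can rely on clamping); per-read methylation states drawn
per cytosine (CpG context: the site's rate; non-CpG context: 0.01);
conversion of unmethylated cytosines with success 0.99 (methylated
cytosines never convert); Poisson(0.5) base-call errors injected after
conversion at uniform positions without replacement, each replaced by a
uniformly chosen different base. Paired mates are 100–400 bp apart
(start-to-start, uniform), on opposite strands, and share the fragment's
methylation states at CpGs both cover; fragments that would run off the
chromosome are resampled. Reverse-strand reads are emitted in sequencing
orientation.

What it does **not** model: quality-score-dependent errors, PCR
duplicates, M-bias, chimeras, adapter read-through, incomplete-conversion
spike-ins, or non-uniform (GC-biased) coverage. Passing the synthetic
benchmark therefore demonstrates correct asymmetric mapping and counting
under calibrated noise, not robustness to every artefact of real
libraries.

## Evaluation

RMSE `√(Σ_c (m_c − m̂_c)² / |C|)` and Spearman correlation (average
ranks) over the mappable set — CpGs with coverage strictly greater than
5. A mappable CpG with no mapped read receives the maximally wrong
prediction (0 if truth > 0.5, else 1; truth exactly 0.5 ⇒ 0, a fixed
choice of measure zero under the continuous profile). With a single tool
defining mappability by its own coverage the penalty is vacuous; an
external mappability mask can be supplied for multi-tool comparisons.
Constant vectors yield an undefined (NaN) correlation.

## Problem sizes and numerical choices

The package's benchmark replica runs a 100 kb uniform-random genome with
100,000 single-end 100 bp reads (~100× coverage) — the scale at which the
per-CpG binomial sampling floor √(p(1−p)/cov) ≈ 0.04 sits comfortably
under the quality bar, while the whole pipeline completes in about a
minute on one CPU. Unit and property tests use 10–50 kb genomes and
hundreds to thousands of reads. Index persistence is a versioned pickle
archive embedding the configuration; loading verifies the format version
and rebuilds derived lookups, and retrieval results round-trip exactly.
All randomness flows through numpy Generators seeded from a single root
seed (SeedSequence spawning for independent streams).

## Known limitations

* The hash table keeps Python-object cells; memory is fine for the
  package's desk-scale genomes but a whole mammalian genome would want a
  packed table.
* Ambiguity resolution compares alignment starts only among tied best
  hits; placements tying at the same start but with genuinely different
  downstream alignments are treated as one placement (the counted bases
  differ only under indels, which are ignored over CpGs anyway).
* Threading shares the Python interpreter; it preserves determinism but
  yields little wall-clock gain.
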