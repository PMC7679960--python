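# Methods

## The score

Given an alignment of homologs containing the wild-type reference, each
reference position *i* maps to an alignment column. The column's residue
frequencies are computed over standard amino acids only, and the position's
score is

    score(i) = f_cons(i) / f_WT(i),

the frequency of the most frequent (consensus) amino acid over that of the
wild-type residue. By construction f_cons ≥ f_WT, so the score is at least
1, with equality exactly when the wild type is (or co-ties for) the
consensus. A construct at threshold *t* substitutes the consensus residue
at every position with score strictly greater than *t* that lies inside the
region mask. Strict inequality is the package's documented convention: a
position whose score equals the threshold is not mutated.

## Frequency estimation choices

These choices are the package's own documented defaults; they are the
points any implementation of the score must fix, and different tools could
reasonably fix them differently.

- **Gaps and ambiguity codes.** Frequencies are computed over the 20
  standard amino acids only. Gaps (`-`, `.`) and the codes B/Z/X/U/O count
  toward a column's `gap_fraction` but never toward the residue
  distribution: a gap is absence of evidence, not a 21st residue, and an
  ambiguity code cannot be assigned to a single residue. A column with no
  standard residue at all is flagged empty; its position gets an undefined
  score, is never selected, and is listed in the skipped-positions report.
- **Wild type absent from the column** (f_WT = 0). The literal ratio is
  undefined; the package reports +infinity, which exceeds every finite
  threshold — such a position is maximally non-consensus and is always
  selected. A pseudocount (below) regularizes this when finite scores are
  preferred.
- **Pseudocount** (default 0). When positive, it is added to all 20 residue
  counts of every non-empty column before normalization, leaving the
  frequency ordering unchanged. It is *not* applied to empty columns, which
  stay flagged rather than acquiring a fictitious uniform distribution.
- **Tie-breaking.** If the wild-type residue ties for the maximum
  frequency, the consensus *is* the wild type (score 1, never selected) —
  the conservative choice: never mutate a position where the wild type is
  already co-consensus. Other ties break to the alphabetically first
  residue, making scoring deterministic and independent of row order.
- **Reference row.** Included in the counts by default (the reference is
  one homolog among many); `include_reference=False` excludes it. On small
  alignments the choice visibly shifts scores — with ten homologs and a
  unanimous non-wild-type consensus, including the reference gives 10/1
  rather than infinity.
- **Sequence weighting** (default uniform, i.e. raw frequencies). The
  position-based scheme of Henikoff & Henikoff (1994) is available to damp
  redundant homolog sets: per column, a sequence carrying residue *a*
  receives 1/(r·s) where *r* is the number of distinct residues in the
  column and *s* the multiplicity of *a*; weights are normalized to mean 1.
  It is an explicit opt-in because the score as defined uses raw
  frequencies.

## Selection, constructs and the panel

Mutation positions and masks use 1-based numbering on the ungapped
reference (standard point-mutation notation, `V123L`); alignment columns
are 0-based internally, with the reference mapping mediating. The region
mask is a set of inclusive residue ranges — for membrane proteins,
typically the transmembrane segments, supplied by the user as a two-column
TSV; overlapping ranges are merged. Masks are validated against the
reference length at selection time.

The mutation load of a construct is reported as a percent of the *full*
reference length, not of the masked region, rounded to one decimal with
round-half-up; constructs in a sweep are named `<prefix>_<load>` (e.g.
`xCT_20.2`), with `--name-by-threshold` as the alternative. Selection with
a strict threshold is antitone: for t1 ≤ t2 the mutation set at t2 is a
subset of that at t1, so a descending threshold sweep yields a panel of
nested, growing mutation sets. Duplicate thresholds are collapsed with a
warning. No default threshold is offered for single-construct design: the
useful cutoff is protein-specific (2.22 for the xCT-style demo), and a
silent default would mislead.

## Synthetic alignments and what the tests show

The `synthetic` module provides two generators.

`generate_msa` samples each homolog row i.i.d. per column: a gap with the
column's gap probability, otherwise a residue from the specified
distribution — so the conditional residue distribution given non-gap is
exactly the specified one, and `expected_scores` gives the analytic
consensus, frequencies and score per column (ignoring sampling noise and
the single reference row). A single integer seed governs the whole
alignment. At 5,000 rows the empirical score of every column with true
score ≤ 5 typically lands within 10% relative error of the analytic value
(verified at a fixed seed in the suite); columns with larger true scores
have a small wild-type frequency in the denominator and correspondingly
larger relative noise.

`msa_from_column_counts` builds an alignment whose column compositions are
exact integer counts — no sampling at all — which is what a worked example
with a prescribed mutation count needs. `stabilization_demo` uses it for
the package's reference scenario: a 501-residue protein, 12
transmembrane-like mask segments of 25 residues (300 maskable positions),
ten homologs, 71 masked positions with a unanimous non-wild-type consensus
(score 10 with the reference row counted) and 30 with an 8:2 majority
(score 8/3 ≈ 2.67). Thresholds 3.0 and 2.22 therefore select exactly 71
and 101 mutations — loads 14.2% and 20.2% of 501 residues.

What passing tests do and do not show: columns are generated independently,
so the synthetic data has no phylogenetic correlation, no indel structure
beyond i.i.d. gaps, and no covariation between positions — properties real
homolog alignments always have. The tests therefore establish that the
scoring and selection machinery is exact and that empirical frequencies
converge to specified ones; they say nothing about whether a given real
alignment is deep or diverse enough for consensus frequencies to be
meaningful, nor about the actual thermostability of a designed construct
(which the originating workflow established by FSEC-TS wet screening).

## Verification strategy and problem sizes

Scoring and selection are checked two ways against independent brute-force
reimplementations (plain nested character loops sharing no code with the
package): exact agreement on 500 random alignments of up to 20 rows × 30
columns, and a property suite (score ≥ 1, row-order invariance, threshold
monotonicity on 100 random score sets, round-trips for alignment I/O,
mutation notation and construct build/diff). The statistical-recovery check
uses 30 columns at 5,000 rows. These sizes make the whole suite and the
acceptance script each run in a few seconds while keeping the randomized
checks broad enough to exercise ties, gaps, absent wild types and empty
columns.

## Known limitations

- The tool treats the alignment as given; it neither searches for homologs
  nor aligns them, and the quality of the design is bounded by the quality
  and depth of the supplied alignment.
- Scores are per-column and independent: no phylogenetic correction beyond
  optional Henikoff weighting, no covariation/entropy measures, no
  structure- or ΔΔG-based filtering.
- The mutation-load percent denominator is the full reference length even
  when a mask restricts selection; loads from differently masked runs are
  comparable only in that convention.
- When two thresholds in a sweep yield the same rounded load, load-based
  construct names collide; use `--name-by-threshold` in that case.
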