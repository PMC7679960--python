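# consmut — consensus-mutagenesis construct design

`consmut` designs thermostabilized variants of a protein — typically an
unstable membrane protein such as the cystine/glutamate antiporter light
chain xCT (SLC7A11) — by consensus mutagenesis over an alignment of
homologs.

The idea: at each position of a multiple sequence alignment, the most
frequent amino acid across homologs (the *consensus*) is, on average, the
most stabilizing choice. For every position *i* of the wild-type reference
the tool computes the score

```
score(i) = f_cons(i) / f_WT(i)
```

where `f_cons(i)` is the frequency of the most frequent amino acid in
alignment column *i* and `f_WT(i)` the frequency of the wild-type residue
there. A score of 1 means the wild type already is the consensus; large
scores flag positions where the reference deviates from a strongly
conserved majority. A construct is built by substituting, with the
consensus residue, every position whose score strictly exceeds a chosen
threshold, optionally restricted to a region mask (e.g. the transmembrane
segments). Sweeping several thresholds yields a graded panel of constructs
with increasing mutation loads, named by load — e.g. `xCT_14.2` for a
construct in which 14.2% of all residues are substituted — from which a wet
screen (FSEC / FSEC-TS) picks the best-behaved variant.

The package provides:

- alignment I/O (aligned FASTA, Clustal, Stockholm) and reference
  coordinate mapping (`consmut.msa_io`)
- column frequency profiles, optional pseudocounts and Henikoff
  position-based sequence weights, and f(cons)/f(WT) scoring
  (`consmut.profile`)
- mutation selection, construct assembly, threshold sweeps and region
  masks (`consmut.design`)
- annotated-alignment and panel reports (`consmut.reporting`)
- synthetic alignments with exactly known column statistics for
  verification (`consmut.synthetic`)
- a `consmut` command-line interface (`score`, `design`, `sweep`,
  `simulate`)

## Worked example

The built-in demo scenario is a 501-residue membrane-protein-like reference
with 12 transmembrane segments, aligned to ten exact-composition homologs
so that 71 masked positions carry a unanimous non-wild-type consensus
(score 10) and 30 more an 8:2 majority (score ≈ 2.67):

```python
from consmut import stabilization_demo, write_alignment
msa, mask = stabilization_demo()
write_alignment(msa, "demo.fasta")
with open("tm.tsv", "w") as fh:
    fh.writelines(f"{s}\t{e}\n" for s, e in mask.ranges)
```

Sweeping the thresholds 3.0 and 2.22 over the transmembrane mask:

```sh
consmut --verbose sweep --alignment demo.fasta --ref-id REF \
        --mask tm.tsv --thresholds "3.0,2.22" --out-prefix xCT
```

prints

```
INFO construct xCT_14.2: threshold 3, 71 mutations (14.2%)
INFO construct xCT_20.2: threshold 2.22, 101 mutations (20.2%)
```

and writes `xCT.panel.fasta` (the mutant sequences), `xCT.mutations.tsv`
(one row per substitution with its frequencies and score) and
`xCT.panel.tsv`:

```
construct	threshold	mutation_count	mutation_percent
xCT_14.2	3	71	14.2
xCT_20.2	2.22	101	20.2
```

Reading: at the 3.0 cutoff only the 71 unanimous-consensus positions are
substituted (71/501 = 14.2% of the sequence); dropping the cutoff to 2.22
additionally pulls in the 30 positions with an 8:2 majority, giving 101
substitutions, a 20.2% mutation load. This is the graded-panel pattern used
to stabilize xCT: the 2.22-threshold construct (101 substitutions, 20.2% of
total amino acids) is the xCTcons-style design.

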