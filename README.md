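# dcx — divergence-contrast explorer for protein kinase families

`dcx` identifies the residues that most distinguish a protein family from the
rest of its superfamily — the *co-conserved, family-distinguishing pattern* —
and follows those positions through structure and disease annotation.  It was
built around the classic ErbB-kinase analysis problem: given a multiple
sequence alignment of receptor tyrosine kinases split into a foreground
family (ErbB) and a background (all other RTKs), find the columns where the
foreground is strikingly conserved for residues the background rarely uses
(e.g. the inter-lobe-linker glutamine, Q791 in pre-mature EGFR numbering),
render them as a Contrast Hierarchical Alignment (CHA), measure how often the
corresponding residue–residue interactions occur across an ensemble of
crystal structures (N-lobe / active-site / C-lobe tether classes), and
overlay recurrent cancer mutations.

## The statistic

For an alignment column, let `n` be the weighted number of foreground
sequences (Henikoff position-based weights, so redundant sequences count
less), `k` the weighted number carrying a candidate residue set `R`, and `q`
the weighted background frequency of `R` (floored at `1/(2·n_back)`).  The
**ball-in-urn score** is the negative log tail probability of drawing at
least `k` pattern balls in `n` draws from an urn with pattern fraction `q`:

```
score(R) = −log10 P(X ≥ k),   X ~ Binomial(n, q)
```

computed in log space (no underflow for scores of many hundreds).  Each
column's pattern is the residue set (size ≤ 3) maximising the score; a column
is a **pattern position** when `score ≥ 10` and the foreground conserves the
set at ≥ 60%.  When the foreground/background split is not given, a
Gibbs-style sampler alternates pattern selection with sequence reassignment
to infer it.

## Worked example

Generate a synthetic benchmark alignment (50 foreground / 200 background
sequences, 100 columns, 10 planted pattern columns conserved at 90% in the
foreground vs 5% background frequency) and run the contrast:

```sh
dcx synth msa --seed 1 --out data
dcx contrast data/alignment.fasta --partition data/labels.tsv \
    --ref fore_0001 --offset 24 --out contrast.tsv
```

prints

```
Divergence contrast results
  foreground: 50 sequences (given)
  background: 200 sequences
  effective sequences: 164.9 (position_based weighting)
  selected pattern positions: 10 of 100 columns

column refpos  pattern  fore%   p_back    score
    13     38        R 100.0%   0.0509    40.10
    89    114        G  94.1%   0.0431    36.96
    24     49        G  87.8%   0.0383    32.47
...
```

All ten planted columns are recovered and nothing else: each row is one
pattern position — the alignment column, its residue number on the chosen
reference sequence (+24 signal-peptide offset, i.e. pre-mature numbering),
the pattern residue set, its weighted foreground conservation, the floored
background frequency and the ball-in-urn score.  `dcx render` turns the same
result into a CHA text block (histogram, pattern dots, query sequences,
foreground consensus with integer-tenths weighted frequencies, background
block), `dcx tether` tabulates hydrogen-bond / van der Waals / CH-π
frequencies for the pattern positions across a PDB ensemble, and
`dcx mutations` joins a COSMIC-style table (rows like `L861Q(26)`) against
the pattern with a one-sided Fisher exact enrichment test.

The same pipeline is available as a library: `ContrastModel(alignment,
partition).fit()` returns a results object with `.calls`, `.histogram`,
`.summary()` and `.to_tsv()`; `.sample_partition(seed)` infers the split;
`.jackknife_stability(group)` re-runs the contrast without a subfamily and
reports how much the selected pattern moved.

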