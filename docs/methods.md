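# Methods

This note records the model, the defaults and the design decisions behind
`dcx`, in enough detail to reproduce or criticise any number the package
prints.

## Sequence weighting and column profiles

Sequences in a family alignment are redundant in a way that depends on
database sampling, not biology, so all column statistics use weighted
counts.  The default scheme is Henikoff & Henikoff position-based weighting:
at each column, a sequence showing residue *a* receives `1/(r·s)` where *r*
is the number of distinct residues in the column and *s* the number of
sequences showing *a*; gaps and `X` contribute nothing.  Per-sequence raw
weights are the sum over columns, rescaled so the largest weight is 1.  The
sum of weights is reported as the *effective* number of sequences.  A
`uniform` scheme is available as a fallback, and the scheme in force is
recorded in all output metadata.

Column residue frequencies are conditional on non-gap: `freq[r]` is the
weighted fraction of *aligned residues* at the column, while gaps and `X`
only enter a separate `gap_fraction`.  Rationale: the divergence statistic
compares residue composition; a column's missing data should not dilute it.
Consequence to keep in mind: weighting compensates duplications exactly per
column but the weights themselves are global, so duplicating one sequence
10× still moves individual weighted frequencies slightly — about 0.017
worst-case on 250-sequence alignments, larger on very small ones.  The
selected pattern positions are unchanged under such duplication (this is
tested for every foreground sequence).

## The ball-in-urn divergence score

For a column and a candidate residue set `R`:

* `n` — weighted count of foreground sequences aligned (non-gap) at the
  column, rounded half-up to an integer;
* `k` — weighted count of foreground sequences showing a residue of `R`,
  rounded half-up (capped at `n`);
* `q` — weighted background frequency of `R`, floored at
  `p_min = 1/(2·n_back_eff)` where `n_back_eff` is the weighted non-gap
  background count (so an unobserved residue is treated as "less frequent
  than half a sequence", never impossible).

The score is `−log10 P(X ≥ k)` for `X ~ Binomial(n, q)`: the chance of
drawing at least `k` pattern balls from an urn whose pattern fraction is the
background's.  It is 0 when `k = 0` and grows with foreground conservation
and background rarity.

Numerics: the tail is summed in log space (`gammaln` terms + log-sum-exp),
which is exact to ~1e-13 relative against integer-arithmetic reference sums
and does not underflow for scores of many hundreds.  When the tail mass
exceeds ½ the complement (head) sum is used through `log1p`, so scores
arbitrarily close to zero also keep full relative accuracy.  A
`continuous_tail` option replaces the rounded-count tail with the
regularized incomplete beta function at the unrounded counts.

## Pattern selection

Candidates for a column are all single residues observed in the foreground
plus every subset (sizes 2–3 by default) of the six most frequent foreground
residues; an `exhaustive` flag scores every residue subset instead.  The
top-6 restriction is an efficiency device: on random profiles with up to
~6 plausible residues it provably coincides with exhaustive enumeration
(any residue with zero foreground frequency only raises `q` without raising
`k`), and the equivalence is property-tested against a brute-force oracle.
Ties break toward the higher score, then the smaller set, then alphabetical
order — determinism over elegance.

A column is *selected* when `score ≥ score_threshold` (default 10.0, i.e.
tail probability ≤ 1e-10) **and** the foreground conserves the set at
`≥ min_fore_conservation` (default 0.6).  The histogram rendered above a CHA
is each selected column's score divided by the maximum selected score
(0 for unselected columns).

Defaults, recorded in every output: `max_set_size=3`,
`score_threshold=10.0`, `min_fore_conservation=0.6`, `top_candidates=6`,
sampler pseudocount `α=0.5`.

## Partition sampling

When the foreground/background split is unknown,
`ContrastModel.sample_partition(seed)` infers it by a Gibbs-style
alternation: (i) fit the contrast under the current membership; (ii)
reassign every sequence to foreground or background with probability
proportional to the product, over the current pattern columns, of the class
residue likelihoods (weighted counts with additive pseudocount α, times the
mixing proportion).  When fewer than 5 columns are selected, the top 5
columns by score are used for reassignment so the chain can move before any
column passes the threshold.

Search structure:

* **Restarts.** 3 independent restarts of 25 sweeps.  The first restart is
  initialised from the sign of the leading principal component of the
  one-hot sequence matrix — a cheap spectral guess that is usually already
  close to the true two-class split; the others start from random 50/50
  assignments.  Because the statistic is foreground-asymmetric (it looks for
  *fore*-conserved patterns), both orientations of the spectral split are
  scored and the better one is kept.  A restart stops early when a sweep
  changes no labels.
* **Best state, then polish.** The best state visited (by joint score: the
  sum of selected-column scores) is kept rather than averaged — a simpler
  acceptance surface, with the sweep trace retained for diagnostics.  The
  stochastic search can retain background sequences whose absorption happens
  to raise the joint score, so the best state is finished deterministically
  by iterated conditional modes (hard MAP reassignment to a fixed point,
  ≤ 20 iterations).  The returned partition is therefore a fixed point of
  the reassignment rule.
* **Degeneracy diagnostic.** An optimiser will find *something* even in
  noise.  A partition is flagged degenerate when its joint score is below
  the selection threshold, or — when it is below 5× the threshold — not at
  least 2× the best joint score the same optimisation achieves on
  column-permuted copies of the alignment (three permutations; permuting
  within columns preserves every column profile but destroys any consistent
  split).  Class labels are arbitrary: recovered partitions are compared to
  ground truth up to label swap.

## Jackknife stability

`jackknife_stability(group)` removes a set of foreground sequences (e.g. one
subfamily), refits, and reports the Jaccard overlap of the selected-column
sets plus per-column score deltas.  Weights are recomputed on the reduced
alignment.  Removing the empty group reproduces the original selection
exactly (overlap 1).

## CHA rendering

All rows are equal-width monospaced text.  Conventions:

* Weighted residue frequencies print as integer tenths: digit *d* covers
  `[d/10, (d+1)/10)`.  The top band is closed — a 100% conserved residue
  prints `9` — because a single character cannot show "10".  Undefined
  (all-gap) frequencies print blank.
* The histogram is compressed to one text row with the ramp `' .:|#'`:
  blank for height 0, then the four quarter-bands of (0, 1].
* The dot row marks exactly the selected columns (`*`).
* The background block shows only consensus + frequency rows, not
  background sequences.

## Structural interaction detection

All detectors run on heavy atoms only (first PDB model,
highest-occupancy altlocs, waters/ligands/hydrogens dropped) and are
invariant under rigid motion by construction.

**Hydrogen bonds** use donor/acceptor tables per residue type (backbone N
donates except proline; backbone O accepts; side-chain N/O/S per standard
chemistry) and three geometric gates:

1. donor–acceptor distance ≤ 3.5 Å;
2. the angle at the donor against *every* covalent antecedent ≥ 90°
   (antecedents are same-residue atoms within covalent range, plus the
   preceding residue's C for a backbone N);
3. when the donor has exactly two antecedents — a planar amide-type donor —
   the idealized H direction is fixed (opposite the antecedent bisector) and
   the D–H···A angle must be ≥ 120°.

The third gate matters: on an ideal α-helix (φ=−57°, ψ=−47°) the
O(i)···N(i+2) (3.37 Å) and O(i)···N(i+3) (3.21 Å) distances also pass the
distance cut; the antecedent gate removes i+2 (angle 58°) and the
idealized-H gate removes i+3 (110° vs 165° for the true i→i+4 bond), so
detection on the helix fixture returns exactly the i→i+4 ladder.  Residue
pairs closer than 2 positions on a chain are skipped unless both atoms are
side-chain atoms.

**Van der Waals contacts**: heavy-atom pairs from distinct residues with
distance ≤ r_a + r_b + 0.5 Å (Bondi radii: C 1.70, N 1.55, O 1.52, S/P
1.80), at least 2.0 Å apart (to exclude covalent neighbours), same
separation rule as above, and excluding atom pairs already counted as
hydrogen bonds.

**CH–π**: a carbon of another residue within 4.5 Å of an aromatic ring
centroid (Phe/Tyr six-ring, His five-ring, Trp both rings) with elevation
≥ 30° above the ring plane (ring normal from SVD of the centred ring
atoms).  These thresholds are common literature conventions; the original
CHAIN-suite cutoffs are not published, so ensemble frequencies here are not
expected to reproduce any specific published table numerically.

**Ensemble frequencies** are keyed by (interaction kind, residue pair in
reference numbering; chains collapsed).  A structure enters a pair's
denominator only when both positions are resolved in it (disordered
residues are reported in a coverage table); the frequency is
present/denominator, optionally stratified by user-assigned active/inactive
state labels.  Per-structure numbering offsets map author residue numbers to
reference positions (`refpos = author + offset`).  Symmetry mates are not
generated; inter-chain interactions are computed only between chains present
in the file.

Tether classification is a deterministic join of the selected pattern
positions with a user-supplied table of region labels and tether classes
(NLT = N-lobe tether, AST = active-site tether, CLT = C-lobe tether);
unannotated positions get class `none`.

## Mutation overlay

The reader accepts a five-column TSV (position, wt, variant, site, count) or
compact change strings (`L861Q(26)`), possibly several per cell.  Counts
reported more than once for the same amino-acid change are summed — source
tables sometimes carry one change per release — and this summing is a
package choice, recorded here.  The overlay joins mutated positions with the
selected pattern positions and region annotations; enrichment is a one-sided
Fisher exact test on the 2×2 table (mutated? × pattern?) over all positions
in a stated reference range.  The enrichment statistic is an extension
beyond a plain join and is labelled as such in the report metadata.
Positions outside the reference range are flagged and excluded from the 2×2.

## Synthetic data

The generators exist so that every stage is testable with known truth:

* **MSA**: per column a background profile is drawn from a symmetric
  Dirichlet (concentration 0.5 over the 20 letters).  Pattern columns get a
  planted residue: background frequency forced to `p_back_pattern`
  (remainder renormalised), foreground sequences carry it with probability
  `theta_fore`, otherwise sample the adjusted profile.  Gaps are i.i.d. at
  `gap_rate`; optional clones duplicate random foreground sequences
  verbatim to exercise weighting.  Defaults are the benchmark conditions
  used throughout the tests: 50 foreground / 200 background, 100 columns,
  10 pattern columns, `theta_fore=0.9`, `p_back_pattern=0.05`,
  `gap_rate=0.02` (a light, realistic level of missingness), no clones.
  Sequences are i.i.d. given the column profiles — there is **no
  phylogeny**: no tree correlation, no indels, no rate heterogeneity.
  Passing recovery tests therefore shows the statistics behave correctly at
  profile level; they say nothing about confounding by shared ancestry,
  which real analyses must address through the weighting and the user's
  choice of background.
* **Helix**: an ideal poly-alanine α-helix (φ=−57°, ψ=−47°, standard bond
  lengths/angles, atoms placed by internal-coordinate chaining), with the
  i→i+4 backbone O···N list as truth (n−4 bonds for n residues).
* **Mutation fixture**: a mutation table whose overlap with a designated
  pattern-position set is exact by construction, with the implied 2×2 table
  as truth.

All generators are deterministic given a seed and emit the standard formats
the pipeline readers consume.

## Problem sizes and tolerances in the test suite

The suite and `scripts/acceptance.py` use: the benchmark MSA conditions
above (20 alignments for recovery, 10 for the sampler and jackknife), score
oracle grids up to n=500, complete 2×2 enumeration to total 15 plus
margin-100 fixtures, a 12-residue helix, and 8 random rigid motions.  These
sizes keep the whole suite to a couple of minutes while exercising every
code path at the scale the statistics operate.

## Known limitations

* The two-class contrast is flat: no hierarchical multi-level partitioning,
  no Dirichlet-process prior over partitions.
* The joint score used to rank sampler states is a sum of selected-column
  tail scores, not a proper marginal likelihood; the ICM polish and the
  permutation-null diagnostic compensate in practice but carry no
  posterior-probability interpretation.
* Interaction geometry uses heavy atoms and idealized amide hydrogens only;
  rotatable hydroxyl/thiol donors are accepted on distance and antecedent
  angle alone.
* mmCIF, insertion codes and symmetry-mate reconstruction are out of scope;
  author residue numbering within a single chain is assumed unique.
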