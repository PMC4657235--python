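# Methods

This note documents the models and algorithms implemented in `flankalign`,
the parameters that matter, the numerical choices, and what the synthetic
data can and cannot show.

## PPM flank models

Each flank model is a variable-order Markov model trained by counting, for
every position of every corpus string, the (context, next-symbol) pairs at
all context lengths 0..D (default D = 4). Prediction uses the PPM-C escape
scheme without exclusions: at a context with total count `t` over `q`
distinct symbols, a symbol seen `c` times receives probability
`c / (t + q)` and the remaining mass `q / (t + q)` escapes to the
next-shorter context; unseen contexts escape with probability 1; the
recursion terminates in a uniform distribution over the 20-letter
alphabet. PPM-C was chosen because it is the canonical default of the PPM
family and keeps every probability hand-checkable from the printed counts
(the test suite does exactly that). All probabilities are strictly
positive, so window log-losses are finite and non-negative.

A window of length L = 10 is scored by the average base-2 log-loss with
the k-th term conditioned on exactly `min(k, D)` *window-internal*
predecessors; windows never reach outside themselves, so the first terms
of each window use shortened contexts. Positions `n−L+2..n` of a sequence
have no window of their own and inherit the penalty of the last windowed
position. L = 10 reflects the observation that an indel's imprint on its
neighbourhood decays within about ten residues; D = 4 is the standard
memory length for protein PPM models and must satisfy `L ≥ D + 1`.

The right-flank model reads its windows left-to-right by default;
scanning reversed windows is available (`reverse_right`) but off, since
nothing in the construction requires a reading direction and the symmetric
default keeps the two models interchangeable.

## IndelFR extraction

From the two log-loss curves, a position is a left (right) anchor when it
is a strict local minimum of LPPM (RPPM) lying below `mean − c·std` of its
curve (default c = 1.0). Each left anchor pairs greedily with the nearest
unused right anchor at most W = 30 positions downstream, spanning
`[left, right + L)`; unpaired anchors contribute an interval of length L.
Overlapping intervals are coalesced, so the result is sorted and disjoint.
The rule is deterministic; an optional width-3 moving average (off by
default) can smooth the curves first. With constant curves the standard
deviation is zero and no anchors exist, so nothing is predicted.

## The variable gap penalty in the alignment recursion

Gap opening is position-specific, `GPO_i = min(LPPM_i, RPPM_i)`; gap
extension is region-specific, zero inside predicted IndelFRs and equal to
`GPO_i` outside. Penalties are stored as non-negative magnitudes and
subtracted in the dynamic program. A gap run that consumes positions
`i0..i1` of a profile is charged `GPO_{i0} + Σ_{t=i0..i1} GPE_t` from that
profile's arrays — the profile that *has* residues in those columns pays,
so gaps are cheap opposite flank-like regions. Terminal gaps are charged
like internal ones.

The three-state recursion (match `M`, gap-in-partner states `I_A`, `I_B`)
permits a gap state to open after *either* of the other two states, each
run paying its own opening. Without the gap-to-gap openings the recursion
cannot represent alignments in which a deletion directly follows an
insertion, and it would no longer attain the maximum over all global
alignments — the property the test suite verifies by exhaustive
enumeration on small instances. Boundary conditions are `M(0,0) = 0` with
gap states fed by their own recursions, so a leading gap run over
positions `1..i` costs `GPO_1 + Σ_{t≤i} GPE_t`, consistent with the
interior scoring.

Profile columns are scored as `Σ_x Σ_y f_A(x) f_B(y) S(x, y)` with
frequencies taken over all rows (gap-containing columns are thereby
down-weighted); two single-residue columns reduce to the plain matrix
entry. When profiles merge, an aligned column's penalty is the sum of the
two contributing column penalties and a gap column copies the non-gap side
verbatim — by induction, a column's opening penalty always equals the sum
of the single-sequence penalties of the residues present in it. Merged
extension penalties follow the same rule, so a column is effectively
"inside an IndelFR" exactly when its merged extension is zero; profiles
are never re-scanned.

### Penalty units

Average log-loss is measured in bits; GONNET250 entries are log-odds
scores (the classic table, average diagonal ≈ 5.2, maximum 14.2). The two
scales are not commensurable and no conversion is implied by either
definition. The aligner therefore applies a single conversion factor,
`gap_scale` (default 3.0), to both GPO and GPE when sequences enter the
alignment stage. The default places a typical opening penalty
(≈ 4.5 bits × 3 ≈ 14 score points) at two to three times the average
diagonal score, the ratio used by standard affine-gap practice with
Gonnet-class matrices. Calibration matters: at 1:1 a gap opening costs
about one average match, gaps are nearly free everywhere, and the
position-specific structure of the penalty has no room to act. Annotated
files always store raw log-loss values; the scale is an alignment-stage
parameter.

### Substitution matrix and wildcard

GONNET250 ships as a whitespace-delimited text table and loads into a
symmetric 20×20 matrix. In permissive mode, non-standard letters
(B, J, O, U, X, Z) map to `X`, which scores as the row minimum of the
matrix against every residue — a deliberately conservative penalty that
invents no chemistry.

### Linear-space alignment

The divide-and-conquer solver splits the first profile at its middle
column, computes forward three-state score vectors to the split row and
backward suffix vectors from the end, and joins them either at a clean cut
or inside a vertical gap run that crosses the split (the crossing run pays
its opening only once, in the top block). Sub-blocks below ~4096 cells
fall back to the quadratic-memory solver with entry/exit state
constraints. Scores agree with the full-matrix solver to 1e-6 (tested on
hundreds of random instances, including zero-extension zones and forced
deep recursion); tracebacks may differ between the two solvers only among
co-optimal alignments. Full-matrix tracebacks break ties deterministically
in the order M, then I_A, then I_B.

## Distances and guide tree

Pairwise identity uses one-error word matching: every length-k word
(k = 3) of the shorter sequence is credited with the best
`(k − mismatches)/k` over the other sequence's words, counting only word
pairs with at most one mismatch; identity is the mean credit and the
distance is its complement. This weighting degrades exactly to k-tuple
identity when mismatches are disallowed and reproduces the classic
67 %-identical example pair on which exact k-tuple matching reports zero.
Normalising by the shorter sequence keeps identity within [0, 1] and
symmetric. The naive O(n·m·k) scan is used; at the input sizes this tool
targets it is not a bottleneck.

The guide tree is textbook UPGMA: merge the closest pair at height
`d_min/2`, with size-weighted average linkage and ties broken on the
lexicographically smallest cluster-index pair (determinism). Internal
nodes are visited children-first; each visit aligns the two child profiles
and merges their penalties; the root's alignment, re-ordered to the input
order, is the result.

## SP and TC scoring

A reference alignment carries a per-column core mask (absent mask: all
columns core). SP is the fraction of core residue pairs — (row pair,
residue pair) co-occurrences in a reference column — whose two residues
share a column in the test alignment; reference columns containing gaps
still contribute the pairs of their present residues. TC is the fraction
of core columns whose present residues all fall in one test column. TC
never exceeds SP, both are invariant to row and column order, and for two
sequences they coincide. Masks on disk are 1-based inclusive column
ranges.

## Synthetic families

`simdata` evolves a family from one random ancestor along a star
phylogeny: each descendant receives i.i.d. substitutions, then indels.
Indels fall inside a few *hotspot* segments of the ancestor — the
structurally tolerant loops of a fold — separated by at least two flank
lengths of conserved core, so the flanking regions of distinct indel
segments never overlap. Families sharing an ancestor and hotspot layout
form a "fold"; a predictor trained on the recorded flanks of some
families of a fold is evaluated on held-out families of the same fold,
mirroring how a fold-specific flank predictor is meant to be used. All
edits are recorded, so the true alignment and the true IndelFR intervals
are exact; ancestor sites deleted in every descendant are dropped from the
true alignment.

Default study conditions: ancestor length 240, 5 descendants,
substitution probability 0.3 per site (≈ 50–60 % pairwise identity — the
divergent regime in which gap placement, not substitution signal,
dominates alignment difficulty), 3 hotspots of width 8, per-hotspot indel
probability 0.7 per descendant, geometric indel lengths of mean 4 capped
at 15, flank length F = 10, uniform residue background. The generator is
seed-deterministic.

What the simulation does *not* emulate: real flanks have a biased
composition (loop-forming residues) that transfers across folds, whereas
simulated flank statistics are fold-specific memorised content; there is
no rate heterogeneity, no tree-shaped phylogeny, and no correlation
between substitution rate and indel tolerance. Passing the end-to-end
comparison therefore shows that the pipeline's machinery converts accurate
flank statistics into better gap placement — it does not certify accuracy
on any real protein family.

## The mechanism test

The package's central claim-of-operation test trains a predictor on the
flanks of 30 simulated families of a fold, aligns 10 held-out families of
the same fold, and compares the mean SP against the true alignments with a
control that runs the identical pipeline under a constant affine penalty
(opening = the mean of the variable openings, extension = opening, no
zero-extension regions), averaged over 20 seeds. Under the default
conditions the variable penalty wins by roughly four SP points (≈ 0.95 vs
≈ 0.90). The margin shrinks as families become either nearly identical
(nothing left to improve) or dominated by substitution noise (flank
statistics too diluted to learn), and reverses if the penalty scale is
left uncalibrated (see *Penalty units*).

## Known limitations

- Sequences shorter than L cannot be scanned; strict mode rejects them,
  permissive mode can assign a constant documented fallback penalty.
- The extraction rule's anchors are scale-dependent (mean/std of each
  sequence's own curves); sequences with no flank-like regions still get
  anchors if their curves have deep-enough local minima.
- Progressive alignment commits to each merge; there is no iterative
  refinement.
- Profile column scores weight residues by raw frequency; no sequence
  weighting scheme is applied.
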