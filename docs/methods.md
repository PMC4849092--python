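# Methods

## Matrix construction

A BLOCKS database is a set of ungapped alignment blocks; block b has width
w_b columns and n_b sequence segments.  Construction proceeds per variant:

1. **Identity threshold.**  The clustering value C (percent) maps to a
   minimum identity count k_min per block.  `legacy_truncated` uses
   k_min = ⌊C·w/100⌋; `exact_fractional` uses the smallest integer k with
   100·k ≥ C·w.  Both are evaluated with `fractions.Fraction`, so a
   decimal C (e.g. 62.5) is scaled to an exact rational and the boundary
   case is never decided by floating point.  Pairwise identity is exact
   character equality over all columns after uppercasing — non-standard
   letters participate in identity (X matches X) because identity is a
   string property; alphabet filtering happens later, during counting.

2. **Linkage.**  `fixpoint_single_linkage` takes the transitive closure of
   identity(i,j) ≥ k_min (union-find), which is invariant under sequence
   reordering.  `legacy_single_pass` emulates the order-dependent
   historical behaviour: one sweep in file order, attaching each sequence
   to the first earlier cluster containing any matching member, never
   merging existing clusters.  This emulation is a documented hypothesis
   behind a policy interface; BLOSUM-mode output should not be treated as
   a byte-faithful historical reproduction until the emulation has been
   validated against the original C code.

3. **Counting.**  For every block, column, and unordered sequence pair
   (x, y) in different clusters u ≠ v, the residue pair gains weight
   1/(|u|·|v|); within-cluster pairs contribute nothing; columns where
   either residue lies outside the 20-letter alphabet are skipped (the
   weight denominator remains the full cluster size).  The implementation
   vectorizes this per column as an outer-product identity
   (Σ_u f_u)⊗(Σ_u f_u) − Σ_u f_u⊗f_u with f_u the size-scaled residue
   tally of cluster u; the test suite checks it against a literal
   pair-loop oracle in exact rational arithmetic.  Counts are pooled
   across all blocks before normalization (global normalization).

4. **Frequencies and scores.**  q_ij = c_ij / Σ_{i≤j} c_ij,
   p_i = q_ii + Σ_{j≠i} q_ij/2, e_ii = p_i², e_ij = 2·p_i·p_j.  Relative
   entropy H = Σ_{i≤j, q>0} q_ij·log₂(q_ij/e_ij) bits.  Unrounded scores
   are n·log₂(q_ij/e_ij) in 1/n-bit units; integer scores round ties away
   from zero (this matches published integer grids at sign boundaries,
   where banker's rounding would not; the rule is isolated in one function
   so a faithful-port mode could swap it).

### Parameters

- `clustering_percent` C ∈ (0, 100]: percent identity for clustering.
  Integer in all published matrix series; rationals are supported.
- `scale_denominator` n (positive integer): scores in 1/n bit units.  If
  unset it is chosen from the entropy by a step function consistent with
  the published entropy/scale pairings (H ≥ 0.60 → 2, 0.30–0.60 → 3,
  0.20–0.30 → 4, < 0.20 → 5).  The exact historical rule is not published,
  so an explicit n always overrides and is recorded in the output header.
- `pseudocount` ε (default 0, off): added to all 210 unique count cells
  before normalization.  Zero-frequency pairs are an *error* by default —
  real BLOCKS releases never trigger it, and scores must not be silently
  fabricated for sparse toy inputs.
- Ambiguity extensions (optional): B from the marginal-weighted mean over
  {N, D}, Z over {Q, E}, X over all 20; every * entry is the minimum
  off-diagonal core score.  These are a file-compatibility convenience
  derived from the integer core grid, not from counts.

## Coverage evaluation

Relations are ordered (query → subject) pairs; self-hits are removed and
duplicates collapse to their smallest E-value.  Both search directions
count, consistent with the s_i² − s_i normalization (ordered pairs minus
self-pairs).  A relation is a true positive when query and subject share
the superfamily label (first three sccs fields); *every* other relation is
a false positive, including same-fold/different-superfamily hits, so the
coverage is a deliberate lower bound.

The epq filter retains the largest (evalue, query, subject)-sorted prefix
whose accumulated FP mass ≤ epq_limit × total query weight (inclusive, so
a budget of 72.9 admits exactly 72 integral errors).  Ties at the cutoff
are admitted in that stable order until the budget would be exceeded —
deterministic and budget-respecting; the choice matters only for tied
E-values.

Q_quad averages t_i/(s_i² − s_i) over superfamilies with s_i ≥ 2;
superfamilies of size 1 are excluded from S because no homologous relation
is possible and the denominator vanishes.

**Bootstrap.**  Weights are flat-Dirichlet (all concentration parameters
1) over the database, scaled to sum to the database size so the mean
weight is 1 and the epq budget keeps its interpretation.  Per round the
cutoff is *re-selected* under the weighted FP mass (pair weight
w_query·w_subject, budget epq × Σw) — the bootstrap equations are agnostic
on this point, so a `fixed_cutoff` switch pins the unit-weight prefix
instead for sensitivity checks.  Weighted coverage uses
Q̂_i = Σ δ(θ_j, θ_m)·w_j·w_m over retained relations and
W_i = (Σ_{k∈i} w_k)² − Σ_{k∈i} w_k²; with all weights 1 this reduces
*exactly* (not approximately) to the unweighted formula, which the tests
assert.  Defaults: epq = 0.01, 500 bootstrap rounds, significance at
Z ≥ 1.96.  The Z-score uses the sample variance (ddof = 1) of the
per-round coverages; at 500 rounds the distinction from the population
variance is negligible.  Weight vectors are drawn once from a named seed
and can be exported/imported so separate processes share them — the
"concerted" contract that makes comparisons paired.

Degenerate Z cases: both variances zero with equal means gives Z = 0;
with unequal means the result is reported as ±infinity with the
significance flag set rather than raising.

## Synthetic data

`generate_block` plants exact identity structure: derived sequences differ
from a random master at an exact number of positions, each mutated
position receiving a uniformly chosen *different* residue, so
identity(master, derived) = width − mutations holds by construction.
`generate_scenario` plants a superfamily partition (sizes list) and emits,
per superfamily, a chosen fraction of the possible ordered true-positive
relations plus a chosen number of cross-superfamily false positives;
E-values are drawn log-uniformly in [1e-50, 10] and rank-assigned so all
true positives sort below all false positives, making the planted coverage
(1/S)·Σ fraction_i recoverable exactly.  Both generators are pure
functions of their seed.

What the generators do **not** emulate: biological residue composition and
column conservation profiles, correlated mutations, realistic E-value
distributions (which depend on the scoring model), overlapping block
memberships, or superfamily-size distributions of real SCOP releases.
Passing tests therefore demonstrate algorithmic correctness (the planted
quantities are recovered, the optimized paths equal the defining
equations), not search performance on real databases.

## Problem sizes and numerics

The test and acceptance runs use small instances — blocks of ≤ 8 sequences
and width ≤ 40, benchmark databases of ≤ 7290 mostly-singleton domains,
25–200 random fixtures per oracle-equivalence check, and 5–500 bootstrap
rounds — chosen so every quantity can be cross-checked against naive
enumeration in exact arithmetic.  Frequency normalization invariants hold
to 1e-12; entropy/score-path consistency to 1e-9; threshold arithmetic is
exact.  Tiny negative dust from the vectorized outer-product counting is
clipped at zero.

## Known limitations

- The legacy single-pass linkage is an emulation (see above), not a port.
- Published matrix series use *adapted* clustering values chosen to match
  relative entropies across variants (e.g. CorBLOSUM61 versus BLOSUM62);
  that entropy-matching search is not automated here — the clustering
  value is always an explicit input.
- The package consumes search output; it does not run Smith–Waterman or
  BLAST, and gap parameters are carried as metadata only.
- Eigenvector-based matrix corrections and linear (non-quadratic) coverage
  normalization are out of scope.
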