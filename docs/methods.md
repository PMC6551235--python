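# Methods

## The two-radius motif model

The input is a set S of n sequences over an alphabet Σ (DNA by default,
the 20 amino acids optionally) and three integers l, d1, d2.  An l-mer M
is an **(l, d1, d2)-motif** iff

1. for every sequence s ∈ S there is a window v of s with Hd(M, v) ≤ d1
   (the (l, d1)-condition), and
2. for at least one sequence there is a window with Hd(M, v) ≤ d2 (the
   (l, d2)-condition),

where Hd is the hamming distance.  The model assumes 0 ≤ d2 < d1 ≤ l.
With d2 ≥ d1 the second condition is implied by the first and the
problem degrades to plain (l, d1)-motif search (LDMS); the package
supports this as an explicit *relaxed* mode rather than a silent
default, because the strictness assumption is load-bearing in LDDMS3
(see below).

Rationale for the second radius: if a conserved element accumulates a
uniform number of mutations in {0, …, l/2} independently in each of n
species, the expected minimum and maximum mutation counts

    E[Y] = Σ_k k [(h−k+1)^n − (h−k)^n] / (h+1)^n,
    E[Z] = Σ_k k [(k+1)^n − k^n] / (h+1)^n,      h = l/2,

diverge quickly (for l = 10, n = 20: E[Y] ≈ 0.026, E[Z] ≈ 4.97), and
the probability that at least one species stays within a tight radius
d2, namely 1 − (1 − (d2+1)/(h+1))^n, is already 0.9997 at
(n, l, d2) = (20, 10, 1).  These are `mutation_spread_expectations` and
`validity_probability` in `lddms.stats`.  Both E[Y] and E[Z] are the
standard tail-sum expectations of the minimum/maximum of discrete
uniforms; they satisfy the forced sanity check E[Y] = E[Z] = h/2 at
n = 1 and are validated against Monte-Carlo draws in the tests.

## Algorithms

All four solvers are exact and return the same sorted, duplicate-free
motif set; the test suite enforces this equivalence on randomized
instances against the pattern-driven oracle.

**Brute force** (`lddms.oracle.brute_force_search`) streams all |Σ|^l
patterns in lexicographic order (a vectorized base-|Σ| odometer, chunked
so no Σ^l array is ever materialized) and tests both conditions with
vectorized distance kernels.  A guard (default 10⁷ patterns) refuses
accidental week-long runs; it is overridable.

**LDDMS1** (`lddms.search.lddms1`) first solves plain LDMS at radius d1
and then filters by the (l, d2)-condition.  The LDMS step
(`ldms_solve`) is self-contained: every (l, d1)-motif lies within d1 of
some window of the reference sequence 0, so the union of
d1-neighborhoods of sequence 0's windows is a complete candidate set,
screened against the remaining sequences.  Any exact LDMS solver could
stand in this step without changing the output; the self-contained one
keeps the package dependency-free and is fast enough at the problem
sizes the tests exercise.

**LDDMS2** (`lddms.search.lddms2`) generates the d2-neighborhood of all
n(m−l+1) windows — by construction exactly the l-mers satisfying the
(l, d2)-condition — deduplicates via radix sort, and screens the
candidates against the (l, d1)-condition.  A candidate-count guard
(default 5·10⁷) protects against large-d2 blowup.

**LDDMS3** (`lddms.search.lddms3`) explores each window's
d2-neighborhood tree depth-first, maintaining for the current node x the
distance state (distance from x to every window of every sequence) and

    δ(x, i, I) = max_{q ≠ i} min_{v window of seq q} Hd(v, x),

where i is the sequence the root window came from.  A node with
δ ≤ d1 is a motif: the (l, d1)-condition holds for q ≠ i by δ, for
q = i because the node is within d2 < d1 of the root window, and the
(l, d2)-condition by construction.  This is where strict d2 < d1 is
required; in relaxed mode `lddms3` refuses and the CLI routes to
`lddms1`.

### Neighborhood tree

The tree rooted at window u has height d2; the level of a node equals
its hamming distance from u.  Children of a node mutate only positions
strictly greater than the largest already-mutated position, and only to
characters differing from the *root's* character at that position —
this makes the tree duplicate-free (each member of the neighborhood
appears exactly once) and keeps level = distance.  Child order is by
mutated position ascending, then substituted character in alphabet
order, so traversal is deterministic.

### Pruning rules

δ changes by at most one per tree edge (one character changes, so each
window's distance moves by ±1 or 0, hence each per-sequence minimum and
their maximum move by at most 1).  With deficit δ − d1 and remaining
depth budget d2 − h at level h:

* δ ≤ d1 — output the node and keep descending (descendants can also be
  motifs, so stopping would lose output; this choice is validated by the
  pruned-vs-unpruned equivalence test);
* deficit > budget — prune the subtree: no descendant can reach δ ≤ d1;
* deficit = budget — descend only into children with δ(child) = δ − 1
  (every remaining step must decrease δ);
* deficit = budget − 1 — descend only into children with
  δ(child) ≤ δ (at most one non-decreasing step is affordable).

The restricted-descent cases require each child's δ before the filter
can be applied; the child state is computed and discarded if the filter
fails.  The defining equalities are mutually exclusive, so exactly one
verdict applies per node (`prune_decision`).

### Distance-state update

Windows of all sequences are concatenated into one (T, l) matrix,
T = Σ_q (m_q − l + 1).  A node's state is the length-T vector of
distances to every window; mutating motif position p from character a to
b shifts each window's distance by (window char at p = a) − (window char
at p = b) ∈ {−1, 0, +1}, an O(T) = O(nm) update.  Per-sequence minima
come from a segmented reduction; δ is their maximum excluding the source
sequence.  Equality of the incremental update with from-scratch
recomputation is tested on hundreds of randomized root-to-leaf paths.

Identical windows produce identical trees, so `lddms3` keeps a seen-set
of root windows and builds each distinct tree once; output is unchanged.
Final deduplication across trees happens once, via the radix sort.

### Radix sort

l-mers are rank-encoded per the alphabet order and sorted
least-significant-position-first with counting passes (stable occurrence
indexing per symbol), O(N(l + |Σ|)) total — then deduplicated by
adjacent comparison.  Agreement with a comparison sort is property-
tested.

## Expected-count model

`lddms.stats.expected_counts` evaluates, for an i.i.d.-uniform
background with the windows of a sequence treated as independent l-mers
(W = m − l + 1, N(Σ, l, d) the hamming-ball size):

    p1 = N(Σ,l,d1)/|Σ|^l          p4 = N(Σ,l,d2)/|Σ|^l
    p2 = 1 − (1−p1)^W             p5 = 1 − (1−p4)^W
    p3 = p2^n                     E|C2| = |Σ|^l (1 − (1−p5)^n)
    E|C1| = |Σ|^l p3
    p6 = (N(Σ,l,d1) − N(Σ,l,d2))/|Σ|^l        (annulus (d2, d1])
    p7 = Σ_{k=1}^{W} C(W,k) p6^k (1−p4−p6)^{W−k}
    p8 = Σ_{i=1}^{n} C(n,i) p5^i p7^{n−i}
    E|O| = |Σ|^l p8

p7 is the chance a sequence has some window in the annulus and none in
the inner ball; p8 the chance every sequence is within d1 and at least
one within d2.  The p7 sum is evaluated in log space (logsumexp), since
C(588, 294)-sized coefficients overflow doubles long before the sum
does; ball sizes and Σ^l are exact integers, converted to floats only
inside ratios.  Two telescoping identities — p7 = (1−p4)^W −
(1−p4−p6)^W and p8 = (p5+p7)^n − p7^n — serve as independent
cross-checks in the tests.

Window independence is a simplification: overlapping windows share
characters.  The Monte-Carlo validation therefore targets exactly the
independent-window model the formulas assume (each sequence = W
independent uniform l-mers), where the formulas are exact and the
empirical means must agree within sampling error; agreement with
sliding-window data is approximate and not asserted.

## Planted-instance generator

`generate_instance(n, m, l, q, alphabet, seed)` draws M1 uniformly from
Σ^l, derives M2 by mutating a uniform q-subset of positions each to a
uniformly chosen different character (so Hd(M1, M2) = q exactly),
fills n background sequences with i.i.d. uniform characters, and
overwrites l consecutive characters at a uniform offset with M1 in the
first ⌈n/2⌉ sequences and M2 in the rest — overwrite-in-place keeps
every sequence at length exactly m.  All randomness flows from a single
integer seed through one `numpy` generator, making instances
reproducible byte-for-byte.

Two l-mers have a common neighbor within (da, db) iff
Hd ≤ da + db (`common_neighbor_exists`, verified exhaustively against
neighborhood intersection for all DNA 4-mer pairs).  Hence q ≤ 2·d2 is
needed for planted motifs to exist at all; the conventional settings are
q = 0 when d2 = 0 (≥ N(Σ, l, d2) motifs guaranteed) and q = 2·d2
otherwise (≥ C(2d2, d2) motifs: spend exactly d2 of the budget on the
2d2 differing positions).  `planted_motif_floor` returns these bounds.
The generator deliberately does not guard against background windows
forming additional chance motifs — they are part of what the expected-
count model predicts.

What the generator does *not* emulate: real promoter/UTR composition
(GC bias, repeats), unequal sequence lengths, more than two motif
variants, or insertions/deletions.  Passing tests therefore demonstrate
algorithmic exactness and the planted-recovery guarantee, not biological
sensitivity on real data.

## Numerical and interface choices

* Coordinates are 0-based with half-open windows [i, i+l).
* FASTA input is uppercased on read; characters outside the strict
  alphabet (including N) are rejected with record and position — exact
  hamming distance is undefined for ambiguity codes.  Output wraps at
  70 columns.
* Motif output is always uppercase, lexicographically sorted under the
  alphabet order, one per line; different algorithms on the same input
  produce byte-identical files.
* Equal-radius or inverted parameters (d2 ≥ d1) are an error unless the
  relaxed mode is explicitly requested (`relaxed=True`,
  `--allow-relaxed`).
* Guards: brute force 10⁷ patterns, LDDMS2 5·10⁷ candidates; both
  overridable flags.
* The `auto` algorithm choice takes brute force when |Σ|^l is within
  the pattern guard, else LDDMS2 for d2 ≤ 1, else LDDMS3.

## Problem sizes exercised by the tests

Randomized equivalence instances use |Σ| = 4, n ∈ {2..6}, m ∈ {15..40},
l ∈ {3..7}, d1 ∈ {1..3}, d2 < d1 — the largest sizes at which the
brute-force oracle stays instantaneous, so 100 instances (plus the
pruning-disabled replays) complete in well under a minute.  Planted
recovery runs at (l, d1, d2, n, m) = (9, 3, 1, 10, 100) over 20 seeds.
The Monte-Carlo validation uses 2000 simulated instances at
(σ, l, m, n, d1, d2) = (4, 4, 10, 3, 2, 1) and 10⁵ draws for the
min/max expectations; the three-standard-error acceptance band is the
usual bound for an estimator whose analytic target is exact under the
simulated model.

## Known limitations

* Hamming distance only; edit-distance (indel) motifs are out of scope.
* Single-threaded; the per-window trees are embarrassingly parallel but
  no parallel driver is provided.
* The brute-force oracle's pattern guard makes it unusable beyond
  l ≈ 11 (DNA) by design; the sample-driven algorithms carry no such
  ceiling but LDDMS2's memory grows with N(Σ, l, d2).
* Expected counts assume uniform background; no Markov or GC-content
  correction is implemented.
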