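# Methods

## Problem and model

Given a string *x* (or a set of records) over an alphabet Σ and a distance
bound *d*, a *gapped factor* (*y*, *z*, *d*) is a pair of solid words
required to co-occur — an occurrence of *z* following an occurrence of *y*
within distance *d* in the same record. Five distance semantics are
supported; with 1-based start positions *p* (for *y*) and *q* (for *z*):

| mode | counted pairs |
|---|---|
| head-to-head (HH) | 1 ≤ q − p ≤ d |
| tail-to-head (TH) | 0 ≤ q − (p + \|y\|) ≤ d |
| head-to-tail (HT) | q > p and q + \|z\| − 1 ≤ p + d |
| relaxed tandem | HH, but q precedes the next occurrence of y |
| tandem | y occurrences whose *closest* following z lies in the truncated window |

HH deliberately permits overlapping occurrences of *y* and *z* (the window
marking starts at p+1 and excludes nothing), and a word paired with itself
at distance 0 is excluded (marking starts after *p*). These conventions
pin down edge cases the window-marking description leaves implicit, and
the literal occurrence-list oracle `naive_count` encodes exactly the same
rules.

A sequence of *n* symbols contains Θ(n²) distinct substrings and hence
Θ(n⁴) candidate pairs. The package avoids enumerating them by working on
the generalized suffix tree: all words sharing a tree vertex (their
*locus*) share a start-position set, so counts and scores need only be
computed for the O(n) *maximal* words — one per vertex — and any other
pair inherits the value of its class representatives.

## Index construction

The suffix tree is materialized from a suffix array (numpy prefix
doubling, O(n log² n)) and its LCP array (Kasai), via the standard stack
construction over LCP values. Each record is closed by a distinct
terminal marker that sorts before every alphabet symbol, so (a) no common
prefix — and therefore no tree edge or co-occurrence window — crosses a
record boundary, and (b) the terminal-only suffixes occupy a prefix of
the suffix array and are dropped before tree building. Leaves therefore
biject with text positions; node counts are ≤ 2(n + #records). LCA
queries are answered in O(1) from an Euler tour with a sparse-table RMQ.
Coordinates are 1-based and closed everywhere a user sees them.

Leaves reached by a bare terminal edge carry an empty word class (their
longest proper word already ends at the parent); `TreeNode.has_word_class`
marks the vertices that actually represent classes, and enumeration,
pruning and scan output iterate over those only.

## Counting algorithms

*Head-to-head.* For a first component with occurrences p₁…p_k, the leaves
at positions pᵢ+1 … pᵢ+d (clipped at the record end) each get weight 1; a
bottom-up sweep then leaves I_HH(y, w(β)) at every vertex β. One pass is
O(n) for fixed d, and all O(n) first components give O(n²) total — the
package's empirical-complexity test checks the ~4× time ratio when n
doubles.

*Relaxed tandem.* Identical, with the window truncated to
d′ = min(d, pᵢ₊₁ − pᵢ − 1): no z occurrence is credited to a y occurrence
other than its closest predecessor.

*Tandem.* Starting from the relaxed marking, each window's marked leaves
are visited in **lexicographic (suffix-array rank) order** and the weight
of the LCA of each consecutive pair is decremented before the bottom-up
sweep. In that order the marked leaves lying below any vertex β form a
contiguous block, so a window with m ≥ 1 marked leaves below β
contributes m − (m − 1) = 1 — exactly the "closest z only" semantics —
simultaneously for every β. Visiting the leaves in text-position order
instead does *not* work: two z occurrences separated by an unrelated
position would never meet in a consecutive pair, and the duplicate would
survive (the relaxed value would be reproduced on the very worked
instance the tandem index is meant to correct). Internal weights may go
transiently negative between decrement and propagation; final counts are
non-negative, and the suite checks tandem ≤ relaxed ≤ HH pointwise.

*Tail-to-head.* A shift by |y| cannot simply be added to the HH marking,
because a shorter class member y′ has its tail elsewhere than the maximal
y. Instead, exact-gap tables are built — for a maximal y and gap h,
weight the leaf at p + |y| + h — and a query (y′, z′, d) sums h = 0…d,
resolving each term by case: if |y′| + h > |y| the components cannot
overlap the maximal word and the exact table of y is read at the adjusted
gap |y′| + h − |y|; otherwise the answer is the occurrence count of the
overlap concatenation y₁…y_{|y′|+h} · z′, a single locus lookup. The
boundary |y′| + h = |y| is routed to the concatenation case; a test
asserts both routes agree there. The full all-gap index would be O(n³)
time and space; tables are instead built lazily per requested (y, h) and
memoized, which leaves results identical while keeping memory
proportional to the gaps actually queried (the dyad pipeline needs
h ≤ 16).

*Head-to-tail.* For a first component y, a generalized suffix tree is
built over the windows x[p+1 … p+d] following each occurrence (distinct
end markers; clipped at record ends). A second component z then ends
within distance d of p exactly when a window suffix starts with z, so the
(weighted) leaf count below z's locus in the window tree is I_HT. An
optional flag zero-weights the leaves that start inside the occurrence of
y itself, suppressing the trivial substrings-of-y co-occurrences. The
window length is taken as d (positions p+1 … p+d), the only choice under
which "z ends within distance d of y's start" is honored exactly at the
boundary; the oracle equivalence suite pins this down.

## Scores

The expected frequency of a pair D = (y, z) under the monadic (i.i.d.,
single-symbol) background is F_e(D) = f(y) f(z), converted to an expected
count by the number of admissible placements given the component lengths,
the spacer, and the record lengths. f is either the product of background
symbol probabilities (estimated from the input or an external sequence,
reproducing the symbol histogram exactly) or — in the dyad pipeline — the
observed per-position frequency of each component ("counted" mode).

The score family is a reconstruction, defined to compare F_c with F_e and
to be monotone non-increasing in F_e at fixed F_c:

    z1 = F_c − F_e
    z2 = F_c / F_e
    z3 = (F_c − F_e) / √F_e
    z4 = (F_c − F_e) / √(F_e (1 − F_e/N))     (N = admissible positions)

and the dyad significance score follows the RSAT dyad-analysis
convention, Signif = −log₁₀(N_p · P(D, ≥ F_c)) with a binomial upper tail
over the admissible positions and N_p the number of unique candidate
dyads of the run (a Bonferroni-style multiplicity correction; no
additional FDR layer is applied). Within a class, F_c is constant while
F_e can only shrink toward the representative, so every score attains its
class maximum at the proper-locus pair — the pruning guarantee that the
dominance sweep verifies exhaustively on small strings (n = 25, all
substring pairs, HH at d = 6).

Numerical edges: F_e = 0 occurs when a pair's combined span exceeds every
record (zero admissible placements). A positive count against zero
expectation scores +inf for z2…z4 (0 against 0 is a NaN sentinel); this
keeps the monotonicity — and hence the dominance property — exact through
the boundary. Binomial tail underflow is clamped to the smallest
representable double with a warning. z4 is left undefined when
F_e ≥ N. Ranking uses competition ranks (ties share the minimal rank of
the block, 1-2-2-4), with ties ordered deterministically by (y, gap, z)
because tie order is otherwise arbitrary.

## Dyad pipeline

The discovery workflow emulates dyad-analysis-style extraction: all
length-k words actually present in the scanned set (the tree's vertices
at word depth k, not all |Σ|^k possibilities) are paired at every
tail-to-head gap in [d_min, d_max] — defaults k = 3, gaps 0–16, both
strands — and counted with the exact-gap machinery. In both-strand mode
the reverse complements of the records are appended to the scanned set,
so counting a dyad automatically pools it with its reverse complement;
only the lexicographically smaller member of each strand pair is
reported, and a palindromic dyad (e.g. CGG-N11-CCG) is its own canonical
form with each genomic site counted on both strands. Records default to
one per exact gap (the fixed-spacing dyad notion), with an aggregation
option over the whole range. N_p is the number of canonical candidates
enumerated and is echoed in the output header. `match_consensus` aligns a
dyad to an IUPAC consensus with 'n' spacers on either strand (spacer
content unconstrained), for benchmark-style "rank of the motif closest to
the known one" evaluations.

## Synthetic data

`gen_background` draws i.i.d. records (default uniform ACGT) from a
seeded numpy PCG64 generator; `plant` overwrites (never inserts) a dyad
y·gap·z at a uniformly chosen admissible position in round(fraction ×
n_records) randomly chosen records, returning ground-truth coordinates.
Overwriting keeps record lengths — and hence background statistics —
comparable between planted and unplanted sets; the spacer keeps its
background content. What the generator does *not* emulate: real promoter
composition (GC skew, repeats), degenerate motif instances, or
positional bias of binding sites relative to the transcription start —
so recovery results demonstrate the counting and ranking machinery, not
performance on real regulons.

The recovery experiment plants the Gal4p-like palindromic dyad
CGG-N11-CCG in 60% of 10 × 500 nt uniform records and requires rank 1 by
z2 and by Signif under the default emulation settings. With ~35 000
candidates and a per-candidate expectation of ~2.4, six planted sites
(counted twice by strand pooling, being palindromic) clear the background
maximum with margin but not unboundedly; the experiment is a fixed-seed
stochastic check, not a guarantee for arbitrary seeds.

## Problem sizes and determinism

The test suite runs the oracle-equivalence sweep at n ≤ 200 over 2- and
4-letter alphabets (>1000 instances), the dominance sweep at n = 25, the
complexity check at n = 400 vs 800 for the tree (ratio required in
[3, 6], best-of-3 timings) and n = 24 vs 48 for the exhaustive all-pairs
baseline (ratio required > 6); these sizes make the Θ(n⁴) baseline
feasible on a desk machine while leaving the scaling signal
unambiguous. All randomness in tests, generators and the acceptance
script flows through fixed or caller-provided integer seeds; reruns are
byte-identical.

## Known limitations

- Background models are order-0 only; no Markov or higher-order nulls.
- Components are solid words: no degenerate/approximate matching, no
  k > 2 tuples.
- The suffix array build is O(n log² n) pure-numpy rather than a linear
  construction; for the desk-scale inputs targeted here construction is
  far from the bottleneck, and the tree contract is independent of the
  construction route.
- The all-gap tail-to-head index is never materialized in full; callers
  needing thousands of distinct gaps per component would pay repeated
  O(n) table builds (memoized per component and gap).
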