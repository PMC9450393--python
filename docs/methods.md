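# Methods

## Problem and model

Given `d ≥ 2` sequences over a finite alphabet Σ, the package finds the
length `R` of their longest common subsequence and the complete set of
distinct MLCS strings. The search space is the match-point DAG: nodes are
position vectors `p = (p_1,...,p_d)` whose addressed characters agree,
edges connect a point to its immediate successors (per character `c`, the
coordinate-wise next occurrence of `c` strictly after `p` in every
sequence, found in `O(d)` from a per-sequence next-occurrence table).
Positions are 1-based; the virtual origin uses coordinate 0 everywhere.
Paths from the origin spell common subsequences character by character,
so MLCSs are exactly the longest origin-to-sink paths.

Sequences of unequal length are accepted throughout; nothing in the
method requires equal `n`. Inputs are uppercased on read. The code is
alphabet-generic: `U` is not mapped to `T`, and ambiguity codes are
rejected only when the caller declares an alphabet.

## Lower bound (beam estimate)

`Lower(R)` is the depth reached by a beam search: starting from the
origin, each step collects all immediate successors of the current beam
(deduplicated by coordinates) and keeps the `t` points with the smallest
offset `φ(p) = max(p) − min(p)`. Points with small offset tend to leave
the largest joint suffix region, hence tend to extend furthest. Ties at
the beam cut are broken uniformly at random with a seeded RNG. Every
level advanced extends a concrete common subsequence by one character, so
the estimate is a true lower bound regardless of beam behaviour.

The estimator repeats the pass with `t ← t + μ`, keeps the maximum depth
seen, and stops after `τ` consecutive non-improving restarts. Defaults:
`t0 = 4`, `μ = 5`, `τ = 3`, `seed = 0`. The estimate is deliberately
cheap (`O(d|Σ|·R·t)` per pass); a single beam of fixed small width is
*not* monotone in `t` and can tie-break onto a short chain, which is why
the escalation-and-keep-max form is the contract the tests rely on. A
beam wide enough to hold every deduplicated candidate per level is an
exhaustive level sweep and returns `R` exactly.

## Upper bounds and pruning

Three admissible bounds on `distance(p)` (the MLCS length of the suffixes
after `p`):

1. **Remaining length** — `min_i(|s_i| − p_i)`, `O(d)` per point, no
   preprocessing. For equal lengths this is the familiar `n − max(p)`;
   the `min` form is the tight generalisation to unequal lengths (the
   argument bounds by the characters remaining in the most-consumed
   sequence, and any sequence's remainder is an upper bound).
2. **Suffix character counts** — a common subsequence of the suffixes can
   use each character at most as often as its scarcest suffix does:
   `Σ_c min_i num^c(suf(s_i[p_i]))`. Preprocessed in one backward scan
   per sequence (`O(|Σ|n)` space each), `O(δ|Σ|)` per query.
3. **Pairwise suffix LCS** — any common subsequence of all suffixes is in
   particular a common subsequence of each adjacent pair, so
   `min_i m_i[p_i, p_{i+1}]` bounds it, where `m_i` is the full
   `(n_i+1)×(n_{i+1}+1)` suffix-LCS matrix computed by the standard
   backward DP (`O(n²)` per pair).

Bounds 2 and 3 run over `δ` selected sequences (default `δ = 3`, clamped
to `[2, d]`). Selection anchors the first sequence and adds the `δ − 1`
others with the largest diversity
`Σ_c (num^c_i/|s_i|)·|num^c_i − num^c_j|` (ties to the lower index); the
selection order, anchor first then descending diversity, defines the
adjacent pairs of bound 3. The metric is used as defined — asymmetric,
anchored — with no symmetrisation. Restricting to a subset only loosens
a bound, so admissibility is preserved; `δ = d` is available when the
tightest preprocessed bounds are wanted.

A candidate `q` at level `k` is cut when `k + min(enabled bounds) <
Lower(R)`, strictly. With admissible bounds and `Lower(R) ≤ R`, every
point on an optimal path satisfies `k + Upper ≥ k + distance = R ≥
Lower`, so the cut is sound — the answer (length *and* full string set)
is invariant under any subset of enabled bounds, which the test suite
checks directly. Pruning statistics attribute each cut to the first
triggering bound in the fixed order remaining-length → counts → pairwise
(cheapest first); attribution affects counters only.

## DAG construction and extraction

Levels are built one at a time. A global coordinates-to-node registry
keeps each match point once, at the greatest level reached so far:

- unseen point → create node, record predecessor, schedule for expansion;
- seen at the same level → merge (add predecessor link);
- seen at a greater level → skip (counted as duplicate);
- seen at a smaller level → re-level, reset predecessors, re-expand.

Keeping the maximum level per point is what makes longest paths correct
in the presence of points reachable at several depths; re-expansion
terminates because levels strictly increase and are bounded by `min n_i`.
A point cut at a shallow encounter is not blacklisted — if it is
re-generated deeper (where the pruning inequality may no longer hold) it
is admitted, which matters because shallow dead-end encounters of a
coordinate vector can coexist with a deep appearance on an optimal chain.

`R` is the maximum registry level; all MLCS strings are obtained by
depth-first backtracking of predecessor links from every level-`R` node,
reversing the character sequence, deduplicating (distinct point paths can
spell the same string). Path recording uses predecessor-link sets rather
than materialised strings to avoid exponential storage under many
co-optimal paths; an optional cap (`max_mlcs`) truncates enumeration and
flags the result, leaving the length exact. When the inputs share no
character the result is `R = 0` with `{""}`.

## Baselines

Three independent oracles validate the solver on small instances:

- the full prefix DP table (0 on boundary slices, diagonal +1 on an
  all-match, else max over single-axis decrements), guarded by a cell
  budget (default 2·10⁶ cells);
- the unpruned dominant-point construction: expand every level's
  successors, drop points strictly dominated by another (`≺`, duplicates
  collapsed), keep per-level predecessor links. Removal uses *strict*
  dominance: a same-level point strictly dominated by `r` has remaining
  distance at least one less than `r`'s (extend from `r` through the
  dominated point itself), so it can never end a longest path. Removing
  under weak dominance `⪯` would be unsound for the *full* string set:
  two points sharing a coordinate carry the same character and can have
  equal remaining distance while ending different co-optimal strings;
- exhaustive enumeration of the shortest sequence's subsequences, longest
  first with early exit (refused above length 18).

Brute-force remaining distance at a point — enumeration over the suffixes
— is the ground truth against which every upper bound is tested.

## Synthetic data

The generator draws `d` sequences of i.i.d. uniform characters (default
Σ = ACGT, i.e. uniform random DNA, matching how random benchmark
instances in this literature are produced), with a fixed or ranged
length and full determinism per seed. It does not emulate GC bias,
repeats, homopolymer runs or phylogenetic relatedness; real genomic
sequences are more repetitive and more correlated than these instances,
so passing tests certify algorithmic correctness and bound admissibility,
not wall-clock behaviour on biological data. Property tests run the
solver against all three oracles on 200 seeded instances with
`d ∈ {3,4,5}`, `n ∈ [5,15]` — sizes chosen so the exponential oracles
stay exhaustive while still exercising duplicate merging, re-levelling
and every pruning rule; the solver itself comfortably handles
e.g. `d = 5, n = 100` exactly.

## Numerical and design choices

- Next-occurrence tables store absence as the sentinel `|s_i| + 1`
  (strictly above any valid position), keeping lookups branch-free; a
  successor is emitted only when every coordinate is non-sentinel. The
  origin participates uniformly through column 0.
- Diversity is computed in exact rational arithmetic (`Fraction`), so
  selection ties are exact, broken by lowest index.
- Beam restarts share no state; `μ = 0` still terminates because `τ`
  non-improving repeats exhaust the patience counter.
- `Lower(R)` is fixed after estimation; it is not tightened as deeper DAG
  levels materialise. Tightening would prune more but complicates the
  soundness argument for re-levelled nodes; the estimator is cheap enough
  to be run wide instead.
- The virtual ending point is never materialised; sinks are simply nodes
  at the maximum level.

## Limitations

- All-MLCS enumeration is inherently exponential in the worst case; the
  cap bounds reporting, not the DAG.
- The DP baseline is limited by its cell budget and the brute-force
  oracle by enumeration length; both are oracles, not solvers.
- Bound quality degrades as sequences grow similar in composition
  (character counts stop discriminating) — the pairwise suffix-LCS bound
  then carries most of the pruning at `O(n²)` preprocessing cost per
  pair.
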