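# minimlcs

Exact search for **all** longest common subsequences of many sequences
(the MLCS problem), using a bound-pruned match-point DAG.

Finding an LCS of two sequences is textbook dynamic programming; finding
all LCSs of *d* ≥ 3 sequences is much harder, because both the DP table
(*n^d* cells) and the classical dominant-point DAG grow explosively with
*d* and *n*. This package implements a branch-and-bound variant of the
dominant-point approach: it first estimates a lower bound on the answer
with a cheap beam search, then builds the DAG level by level while
discarding every match point that provably cannot lie on a longest path.
On random DNA instances the surviving DAG is a small fraction of the full
one, yet the answer — the exact length *R* and the complete set of MLCS
strings — is unchanged. Intended users are bioinformaticians and string-
algorithm researchers comparing small families of DNA/protein-like
sequences, and anyone needing a verified MLCS oracle.

## The method

A *match point* of sequences `s_1..s_d` is a vector `p = (p_1,...,p_d)` of
1-based positions with `s_1[p_1] = ... = s_d[p_d]`. Match points form a
DAG under strict dominance (`p ≺ q` iff every coordinate grows), rooted at
the virtual origin `O = (0,...,0)`; paths from `O` spell common
subsequences, and longest paths spell exactly the MLCSs.

The solver prunes this DAG with three admissible upper bounds on
`distance(p)`, the MLCS length of the suffixes after `p`:

- **remaining length**: `Upper(p,∞) = min_i(|s_i| − p_i)` (equals
  `n − max(p)` for equal lengths);
- **suffix character counts**: `Upper(p,∞) = Σ_{c∈Σ} min_i num^c(suf(s_i[p_i]))`;
- **pairwise suffix LCS**: `Upper(p,∞) = min_i m_i[p_i, p_{i+1}]`, where
  `m_i` is the precomputed suffix-LCS matrix of an adjacent sequence pair.

A beam search over the same DAG (keep the `t` points with the smallest
offset `φ(p) = max(p) − min(p)` per level, restart with growing `t`, keep
the best) yields `Lower(R)`. A candidate point `q` reached at level `k`
is dropped whenever `k + Upper(q,∞) < Lower(R)`; since every bound
dominates the true remaining distance and the inequality is strict, no
optimal path is ever lost. The two precomputed bounds run over `δ`
sequences selected by a diversity metric
`diversity(s_i,s_j) = Σ_c (num^c_i/|s_i|)·|num^c_i − num^c_j|`
(anchor sequence first, most dissimilar next), keeping preprocessing at
`O(δ|Σ|n + δn²)`.

Reference implementations — the full `L[i_1,...,i_d]` DP table, the
unpruned dominant-point construction, and exhaustive subsequence
enumeration — are included as small-instance oracles and are wired into
the test suite and the `verify` subcommand.

## Worked example

The packaged example instance is three length-8 DNA sequences:

```sh
minimlcs solve src/minimlcs/data/worked_example.txt
```

```
input:
  d: 3
  lengths: [8, 8, 8]
  alphabet_size: 4
...
lower_bound: 5
mlcs_length: 5
mlcs_count: 1
mlcs: ACGTC
stats:
  nodes_created: 6
  edges: 5
  pruned_theorem1: 3
  pruned_strategy2: 5
  pruned_strategy3: 0
  duplicates_merged: 0
```

Reading: the beam estimate already equals the true answer
(`Lower(R) = 5`), the unique MLCS of `AACGTCGT`, `CGACGTCC`, `GACCGTCT`
is `ACGTC`, and the pruned DAG holds only the six nodes of the one optimal
chain — eight candidate points were cut by the bounds along the way.
`--strategies none` gives the identical answer with a larger DAG;
`--json` emits the report machine-readably; `--dot FILE` exports the DAG
for inspection. Other subcommands: `generate` writes seeded random
instances, `verify` cross-checks the solver against the oracles and exits
non-zero on any disagreement:

```sh
minimlcs generate inst.txt -d 4 -n 12 --seed 7
minimlcs verify inst.txt --oracles brute,dominant
```

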