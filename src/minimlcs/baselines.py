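"""Reference solvers used as correctness oracles on small instances.

Three independent routes to the same answer:

* the classical dynamic-programming score table over all prefix
  combinations (exact, ``O(Π(|s_i|+1))`` cells, only feasible for two or
  a handful of short sequences);
* the unpruned dominant-point construction, which expands every level's
  successors and keeps only the non-dominated points;
* exhaustive enumeration of the shortest sequence's subsequences, longest
  first.

None of these is meant for production inputs; they exist so the pruned
solver can be cross-checked on random small instances.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from .mini_dag import MLCSResult
from .sequence_io import SequenceSet
from .successor_index import MatchPoint, build_successor_table, origin

__all__ = [
    "ScoreTable",
    "dp_score_table",
    "weakly_dominates",
    "strictly_dominates",
    "non_dominated_sort",
    "dominant_point_mlcs",
    "brute_force_mlcs",
    "brute_force_distance",
    "is_subsequence",
]

#: Refuse DP tables larger than this many cells.
DEFAULT_CELL_BUDGET = 2_000_000


class ScoreTable:
    """The d-dimensional prefix score table ``L``.

    ``L[i_1, ..., i_d]`` is the MLCS length of the prefixes of lengths
    ``i_1, ..., i_d``; it is 0 whenever some index is 0, gains 1 on the
    all-match diagonal step, and otherwise takes the maximum over the
    single-axis decrements.
    """

    def __init__(self, L: np.ndarray):
        self.L = L

    def __getitem__(self, idx):
        return int(self.L[idx])

    @property
    def corner(self) -> int:
        """``L[n_1, ..., n_d]`` — the MLCS length."""
        return int(self.L[tuple(s - 1 for s in self.L.shape)])


def dp_score_table(
    seqs: SequenceSet, cell_budget: int = DEFAULT_CELL_BUDGET
) -> ScoreTable:
    """Fill the full prefix table; guarded by a cell budget."""
    shape = tuple(n + 1 for n in seqs.lengths)
    cells = math.prod(shape)
    if cells > cell_budget:
        raise MemoryError(
            f"score table would need {cells} cells (budget {cell_budget})"
        )
    L = np.zeros(shape, dtype=np.int64)
    for idx in np.ndindex(shape):
        if 0 in idx:
            continue
        chars = {seqs.sequences[k][i - 1] for k, i in enumerate(idx)}
        if len(chars) == 1:
            L[idx] = L[tuple(i - 1 for i in idx)] + 1
        else:
            L[idx] = max(
                L[idx[:k] + (idx[k] - 1,) + idx[k + 1 :]] for k in range(len(idx))
            )
    return ScoreTable(L)


def weakly_dominates(p: tuple[int, ...], q: tuple[int, ...]) -> bool:
    """True when ``p ⪯ q``: no coordinate larger, at least one smaller."""
    return all(a <= b for a, b in zip(p, q)) and any(a < b for a, b in zip(p, q))


def strictly_dominates(p: tuple[int, ...], q: tuple[int, ...]) -> bool:
    """True when ``p ≺ q``: every coordinate strictly smaller."""
    return all(a < b for a, b in zip(p, q))


def non_dominated_sort(points: set[MatchPoint] | list[MatchPoint]) -> set[MatchPoint]:
    """Points not strictly dominated by any other (duplicates collapsed).

    Removal uses strict dominance ``≺``: a same-level point strictly
    dominated by another can never end a longest path (the dominator's
    remaining distance exceeds it by at least one, via the dominated point
    itself), so the pruning is lossless for the full MLCS set.  Removing
    under weak dominance ``⪯`` would be wrong here — two points that share
    a coordinate (necessarily carrying the same character) can have equal
    remaining distance and end *different* co-optimal subsequences.

    Plain O(m²) pairwise comparison — adequate for oracle-scale inputs.
    """
    unique: dict[tuple[int, ...], MatchPoint] = {p.coords: p for p in points}
    coords = list(unique)
    keep = set()
    for c in coords:
        if not any(strictly_dominates(other, c) for other in coords):
            keep.add(unique[c])
    return keep


def dominant_point_mlcs(seqs: SequenceSet) -> MLCSResult:
    """Unpruned level-wise dominant-point construction (oracle use only).

    Each level's successor pool is reduced by non-dominated sorting;
    predecessor links are kept per level (the same coordinates may recur
    at several levels) and all MLCSs are spelled by backtracking from the
    last non-empty level.
    """
    st = build_successor_table(seqs)
    o = origin(seqs.d)
    # per level: coords -> (point, set of parent coords in previous level)
    levels: list[dict[tuple[int, ...], tuple[MatchPoint, set[tuple[int, ...]]]]] = [
        {o.coords: (o, set())}
    ]
    stats = {"nodes_created": 1, "levels": 0}
    while True:
        pool: dict[tuple[int, ...], tuple[MatchPoint, set[tuple[int, ...]]]] = {}
        for coords, (p, _) in levels[-1].items():
            for q in st.successors(p):
                entry = pool.setdefault(q.coords, (q, set()))
                entry[1].add(coords)
        if not pool:
            break
        dominant = non_dominated_sort([p for p, _ in pool.values()])
        levels.append({p.coords: pool[p.coords] for p in dominant})
        stats["nodes_created"] += len(dominant)
    r = len(levels) - 1
    stats["levels"] = r
    if r == 0:
        return MLCSResult(length=0, mlcs_set=frozenset({""}), stats=stats)
    found: set[str] = set()
    for coords in levels[r]:
        stack = [(r, coords, "")]
        while stack:
            k, c, tail = stack.pop()
            point, parents = levels[k][c]
            word = point.char + tail
            if k == 1:
                found.add(word)
            else:
                for pc in parents:
                    stack.append((k - 1, pc, word))
    return MLCSResult(length=r, mlcs_set=frozenset(found), stats=stats)


def is_subsequence(sub: str, s: str) -> bool:
    """Two-pointer subsequence test."""
    it = iter(s)
    return all(c in it for c in sub)


def _brute_force_strings(strings: list[str], max_len: int = 18) -> tuple[int, set[str]]:
    """All MLCS strings by enumerating subsequences of the shortest input."""
    shortest = min(strings, key=len)
    if len(shortest) > max_len:
        raise ValueError(
            f"instance too large for enumeration (shortest length {len(shortest)})"
        )
    others = list(strings)
    others.remove(shortest)
    for length in range(len(shortest), 0, -1):
        hits = {
            cand
            for cand in {
                "".join(combo) for combo in combinations(shortest, length)
            }
            if all(is_subsequence(cand, s) for s in others)
        }
        if hits:
            return length, hits
    return 0, {""}


def brute_force_mlcs(seqs: SequenceSet, max_len: int = 18) -> MLCSResult:
    """Exhaustive oracle: longest-first enumeration with early exit."""
    length, hits = _brute_force_strings(list(seqs.sequences), max_len=max_len)
    return MLCSResult(length=length, mlcs_set=frozenset(hits), stats={})


def brute_force_distance(p: MatchPoint, seqs: SequenceSet, max_len: int = 18) -> int:
    """Exact remaining distance at ``p``: the MLCS length of the suffixes.

    This is the ground truth every admissible upper bound must dominate.
    """
    suffixes = [s[c:] for s, c in zip(seqs.sequences, p.coords)]
    if any(not s for s in suffixes):
        return 0
    length, _ = _brute_force_strings(suffixes, max_len=max_len)
    return length
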