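"""Lower- and upper-bound estimation for branch-and-bound path elimination.

The pruning test needs two ingredients:

* ``Lower(R)`` — a cheap lower bound on the length ``R`` of the longest
  common subsequence, obtained by a beam search over the match-point DAG
  that at each level keeps the ``t`` points with the smallest position
  offset ``φ(p) = max(p) − min(p)``.  Any depth the beam reaches is the
  length of an actual common subsequence, so the estimate is always
  admissible (``Lower(R) ≤ R``).

* ``Upper(p, ∞)`` — an admissible upper bound on ``distance(p)``, the
  longest common subsequence of the suffixes after ``p``.  Three bounds of
  increasing cost are available:

  - remaining-length bound: ``min_i (|s_i| − p_i)``, which for equal
    lengths is ``n − max(p)``;
  - suffix character counts: ``Σ_c min_i num^c(suf(s_i[p_i]))``;
  - pairwise suffix-LCS: ``min_i m_i[p_i, p_{i+1}]`` over adjacent pairs
    of the selected sequences, where ``m_i`` is the full suffix-LCS matrix
    of the pair.

The count and pairwise bounds are precomputed over ``δ`` sequences chosen
to be as mutually dissimilar as possible (anchored at the first sequence),
which keeps preprocessing at ``O(δ|Σ|n)`` and ``O(δn²)`` while remaining
admissible: restricting to a subset can only loosen the bound.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .sequence_io import SequenceSet
from .successor_index import MatchPoint, SuccessorTable, origin

__all__ = [
    "BoundsConfig",
    "BoundsState",
    "ALL_STRATEGIES",
    "phi",
    "beam_lower_bound",
    "estimate_lower_bound",
    "upper_theorem1",
    "precompute_strategy2",
    "upper_strategy2",
    "precompute_strategy3",
    "upper_strategy3",
    "diversity",
    "select_diverse_subset",
    "combined_upper",
    "prepare_bounds",
]

#: The always-available remaining-length bound plus the two precomputed ones.
ALL_STRATEGIES = frozenset({"theorem1", "strategy2", "strategy3"})


@dataclass(frozen=True)
class BoundsConfig:
    """Tunable parameters of the bound machinery.

    ``t0`` is the initial beam width, ``mu`` the step added to it on each
    restart, and ``tau`` the number of consecutive non-improving restarts
    tolerated before the estimator stops.  ``delta`` is the number of
    sequences used for the precomputed upper bounds.  ``seed`` drives the
    random tie-break at the beam cut.
    """

    t0: int = 4
    mu: int = 5
    tau: int = 3
    delta: int = 3
    strategies: frozenset[str] = ALL_STRATEGIES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t0 < 1:
            raise ValueError("t0 must be >= 1")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        unknown = self.strategies - ALL_STRATEGIES
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")


@dataclass
class BoundsState:
    """Precomputed bound tables plus the estimated ``Lower(R)``.

    ``suffix_counts[i]`` (for each selected sequence index ``i``) is a
    ``(|Σ|, |s_i|+1)`` array whose column ``j`` counts each character in
    the suffix after position ``j``.  ``pair_lcs[k]`` is the suffix-LCS
    matrix of the ``k``-th adjacent pair of ``selected``.
    """

    lengths: tuple[int, ...]
    alphabet: tuple[str, ...]
    selected: tuple[int, ...]
    suffix_counts: dict[int, np.ndarray] = field(default_factory=dict)
    pair_lcs: list[np.ndarray] = field(default_factory=list)
    lower: int = 0


def phi(p: MatchPoint) -> int:
    """Position offset ``max(p) − min(p)``; small offsets are promising."""
    return max(p.coords) - min(p.coords)


def _beam_select(candidates: list[MatchPoint], t: int, rng: random.Random) -> list[MatchPoint]:
    """Keep the ``t`` smallest-φ candidates, random tie-break at the cut."""
    if len(candidates) <= t:
        return candidates
    scored = sorted(candidates, key=phi)
    cut = phi(scored[t - 1])
    kept = [p for p in scored if phi(p) < cut]
    boundary = [p for p in scored if phi(p) == cut]
    rng.shuffle(boundary)
    kept.extend(boundary[: t - len(kept)])
    return kept


def beam_lower_bound(
    seqs: SequenceSet, st: SuccessorTable, t: int, rng: random.Random | None = None
) -> int:
    """One beam pass of width ``t``: the depth reached before the beam empties.

    Each level collects every immediate successor of the current beam,
    deduplicated by coordinates, and keeps the ``t`` points with the
    smallest ``φ``.  Every level advanced extends a real common
    subsequence by one character, so the return value is admissible.
    """
    rng = rng or random.Random(0)
    beam = [origin(seqs.d)]
    lower = 0
    while True:
        pool: dict[tuple[int, ...], MatchPoint] = {}
        for p in beam:
            for q in st.successors(p):
                pool.setdefault(q.coords, q)
        if not pool:
            return lower
        beam = _beam_select(list(pool.values()), t, rng)
        lower += 1


def estimate_lower_bound(
    seqs: SequenceSet, st: SuccessorTable, cfg: BoundsConfig | None = None
) -> int:
    """Estimate ``Lower(R)`` by repeated beam passes of growing width.

    Starts at width ``t0``, adds ``mu`` per restart, keeps the maximum
    depth seen, and stops after ``tau`` consecutive restarts without
    improvement.  Restarts share no state beyond the running maximum.
    """
    cfg = cfg or BoundsConfig()
    rng = random.Random(cfg.seed)
    t = cfg.t0
    best = beam_lower_bound(seqs, st, t, rng)
    stagnant = 0
    while stagnant < cfg.tau:
        t += cfg.mu
        value = beam_lower_bound(seqs, st, t, rng)
        if value > best:
            best = value
            stagnant = 0
        else:
            stagnant += 1
    return best


def upper_theorem1(p: MatchPoint, seqs: SequenceSet) -> int:
    """Remaining-length bound ``min_i (|s_i| − p_i)``.

    No common subsequence of the suffixes after ``p`` can be longer than
    the shortest suffix.  For equal-length inputs this is ``n − max(p)``.
    """
    return min(n - c for n, c in zip(seqs.lengths, p.coords))


def precompute_strategy2(
    seqs: SequenceSet, selected: tuple[int, ...]
) -> dict[int, np.ndarray]:
    """Suffix character-count tables for the selected sequences.

    One backward scan per sequence; column ``j`` of the result counts each
    alphabet character in ``suf(s_i[j])``.
    """
    alphabet = tuple(sorted(seqs.alphabet))
    cindex = {c: k for k, c in enumerate(alphabet)}
    out: dict[int, np.ndarray] = {}
    for i in selected:
        s = seqs.sequences[i]
        n = len(s)
        counts = np.zeros((len(alphabet), n + 1), dtype=np.int64)
        for j in range(n - 1, -1, -1):
            counts[:, j] = counts[:, j + 1]
            counts[cindex[s[j]], j] += 1
        out[i] = counts
    return out


def upper_strategy2(p: MatchPoint, state: BoundsState) -> int:
    """Character-count bound: ``Σ_c min_i num^c(suf(s_i[p_i]))`` over selected i."""
    total = 0
    for ci in range(len(state.alphabet)):
        total += min(
            int(state.suffix_counts[i][ci, p.coords[i]]) for i in state.selected
        )
    return total


def _suffix_lcs_matrix(s1: str, s2: str) -> np.ndarray:
    """``m[a, b]`` = LCS length of ``s1[a:]`` and ``s2[b:]`` (backward DP)."""
    n1, n2 = len(s1), len(s2)
    m = np.zeros((n1 + 1, n2 + 1), dtype=np.int64)
    for a in range(n1 - 1, -1, -1):
        ca = s1[a]
        row = m[a]
        below = m[a + 1]
        for b in range(n2 - 1, -1, -1):
            if ca == s2[b]:
                row[b] = below[b + 1] + 1
            else:
                row[b] = below[b] if below[b] >= row[b + 1] else row[b + 1]
    return m


def precompute_strategy3(
    seqs: SequenceSet, selected: tuple[int, ...]
) -> list[np.ndarray]:
    """Suffix-LCS matrices for each adjacent pair of the selected ordering."""
    if len(selected) < 2:
        raise ValueError("strategy3 needs at least 2 selected sequences")
    return [
        _suffix_lcs_matrix(seqs.sequences[i], seqs.sequences[j])
        for i, j in zip(selected, selected[1:])
    ]


def upper_strategy3(p: MatchPoint, state: BoundsState) -> int:
    """Pairwise bound: min over adjacent selected pairs of ``m_i[p_i, p_{i+1}]``."""
    return min(
        int(m[p.coords[i], p.coords[j]])
        for m, (i, j) in zip(state.pair_lcs, zip(state.selected, state.selected[1:]))
    )


def diversity(si: str, sj: str) -> Fraction:
    """Weighted absolute character-count difference between two sequences.

    ``Σ_c (num^c_i / |s_i|) · |num^c_i − num^c_j|``.  Asymmetric in its
    arguments; characters absent from ``s_i`` carry zero weight.
    """
    ci = Counter(si)
    cj = Counter(sj)
    return sum(
        (Fraction(ci[c], len(si)) * abs(ci[c] - cj[c]) for c in ci),
        start=Fraction(0),
    )


def select_diverse_subset(seqs: SequenceSet, delta: int) -> tuple[int, ...]:
    """Pick the first sequence plus the ``delta − 1`` most dissimilar others.

    Dissimilarity is :func:`diversity` against the first sequence; ties go
    to the lower index.  The returned order — anchor first, then
    descending diversity — defines the adjacent pairs used by the
    pairwise suffix-LCS bound.
    """
    if not 1 <= delta <= seqs.d:
        raise ValueError(f"delta must be in 1..{seqs.d}, got {delta}")
    s1 = seqs.sequences[0]
    ranked = sorted(
        range(1, seqs.d),
        key=lambda j: (-diversity(s1, seqs.sequences[j]), j),
    )
    return (0, *ranked[: delta - 1])


def combined_upper(p: MatchPoint, state: BoundsState, cfg: BoundsConfig) -> int:
    """Minimum of the enabled admissible bounds at ``p``.

    The remaining-length bound is always available and serves as the
    fallback when no strategy is enabled.
    """
    theorem1 = min(n - c for n, c in zip(state.lengths, p.coords))
    values = []
    if "theorem1" in cfg.strategies:
        values.append(theorem1)
    if "strategy2" in cfg.strategies and state.suffix_counts:
        values.append(upper_strategy2(p, state))
    if "strategy3" in cfg.strategies and state.pair_lcs:
        values.append(upper_strategy3(p, state))
    return min(values) if values else theorem1


def prepare_bounds(
    seqs: SequenceSet,
    st: SuccessorTable,
    cfg: BoundsConfig | None = None,
    estimate_lower: bool = True,
) -> BoundsState:
    """Select sequences, precompute enabled tables and estimate ``Lower(R)``."""
    cfg = cfg or BoundsConfig()
    delta = max(2, min(cfg.delta, seqs.d))
    selected = select_diverse_subset(seqs, delta)
    state = BoundsState(
        lengths=seqs.lengths,
        alphabet=tuple(sorted(seqs.alphabet)),
        selected=selected,
    )
    if "strategy2" in cfg.strategies:
        state.suffix_counts = precompute_strategy2(seqs, selected)
    if "strategy3" in cfg.strategies:
        state.pair_lcs = precompute_strategy3(seqs, selected)
    if estimate_lower:
        state.lower = estimate_lower_bound(seqs, st, cfg)
    return state
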