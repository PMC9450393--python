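"""Level-by-level construction of the bound-pruned match-point DAG.

The DAG is grown one level at a time from the virtual origin.  Before a
successor ``q`` reached at level ``k+1`` is admitted, the branch-and-bound
test asks whether any origin-to-end path through ``q`` could still reach
the estimated lower bound: if ``level(q) + Upper(q, ∞) < Lower(R)`` the
point is discarded together with every path through it.  Because every
enabled upper bound is admissible and the comparison is strict, no optimal
path is ever lost, whatever subset of bounds is enabled.

A global coordinates-to-node registry keeps each match point exactly once,
at the greatest level it has been reached at; reaching a registered point
at a strictly deeper level re-levels it, resets its predecessor set and
re-expands it.  Longest paths are reconstructed from predecessor links at
extraction time rather than carried around as strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bounds import (
    BoundsConfig,
    BoundsState,
    prepare_bounds,
    upper_strategy2,
    upper_strategy3,
)
from .sequence_io import SequenceSet
from .successor_index import (
    MatchPoint,
    SuccessorTable,
    build_successor_table,
    origin,
)

__all__ = [
    "DagNode",
    "MiniDAG",
    "MLCSResult",
    "should_prune",
    "construct_mini_dag",
    "extract_mlcs",
    "mini_mlcs",
    "to_dot",
]

#: Attribution order for pruning statistics: cheapest bound first.
_RULE_ORDER = ("theorem1", "strategy2", "strategy3")


@dataclass(eq=False)
class DagNode:
    """A surviving match point with its level and predecessor links."""

    point: MatchPoint
    level: int
    precs: set["DagNode"] = field(default_factory=set)

    def __hash__(self) -> int:  # identity hash; nodes are unique per registry
        return id(self)


@dataclass
class MiniDAG:
    """The pruned DAG: a coords-to-node registry plus pruning statistics."""

    nodes: dict[tuple[int, ...], DagNode]
    stats: dict[str, int]

    @property
    def max_level(self) -> int:
        return max(n.level for n in self.nodes.values())


@dataclass
class MLCSResult:
    """All longest common subsequences plus engine statistics.

    ``mlcs_set`` holds every distinct MLCS string (or ``{""}`` when the
    inputs share no character); ``stats`` includes the DAG counters and
    the ``Lower(R)`` the run used.  ``truncated`` is set when a reporting
    cap stopped the enumeration early.
    """

    length: int
    mlcs_set: frozenset[str]
    stats: dict[str, int]
    truncated: bool = False


def should_prune(
    q: MatchPoint, level_q: int, state: BoundsState, cfg: BoundsConfig
) -> tuple[bool, str | None]:
    """Branch-and-bound test for a candidate point at a candidate level.

    Returns ``(True, rule)`` when ``level_q + Upper(q, ∞) < Lower(R)``
    (strict), where ``rule`` names the first enabled bound, in the order
    remaining-length, character-count, pairwise suffix-LCS, that already
    triggers the cut on its own — used only for statistics attribution.
    """
    values: dict[str, int] = {}
    theorem1 = min(n - c for n, c in zip(state.lengths, q.coords))
    if "theorem1" in cfg.strategies:
        values["theorem1"] = theorem1
    if "strategy2" in cfg.strategies and state.suffix_counts:
        values["strategy2"] = upper_strategy2(q, state)
    if "strategy3" in cfg.strategies and state.pair_lcs:
        values["strategy3"] = upper_strategy3(q, state)
    upper = min(values.values()) if values else theorem1
    if level_q + upper >= state.lower:
        return False, None
    for rule in _RULE_ORDER:
        if rule in values and level_q + values[rule] < state.lower:
            return True, rule
    return True, "theorem1"  # no strategy enabled: fallback bound triggered


def construct_mini_dag(
    seqs: SequenceSet,
    st: SuccessorTable,
    state: BoundsState,
    cfg: BoundsConfig | None = None,
) -> MiniDAG:
    """Grow the pruned DAG level by level until no successors remain."""
    cfg = cfg or BoundsConfig()
    o = DagNode(point=origin(seqs.d), level=0)
    registry: dict[tuple[int, ...], DagNode] = {o.point.coords: o}
    frontier: dict[tuple[int, ...], DagNode] = {o.point.coords: o}
    stats = {
        "nodes_created": 1,
        "edges": 0,
        "pruned_theorem1": 0,
        "pruned_strategy2": 0,
        "pruned_strategy3": 0,
        "duplicates_merged": 0,
    }
    while frontier:
        nxt: dict[tuple[int, ...], DagNode] = {}
        for p in frontier.values():
            level = p.level + 1
            for q in st.successors(p.point):
                prune, rule = should_prune(q, level, state, cfg)
                if prune:
                    stats[f"pruned_{rule}"] += 1
                    continue
                node = registry.get(q.coords)
                if node is None:
                    node = DagNode(point=q, level=level, precs={p})
                    registry[q.coords] = node
                    nxt[q.coords] = node
                    stats["nodes_created"] += 1
                elif node.level == level:
                    stats["duplicates_merged"] += 1
                    node.precs.add(p)
                elif node.level > level:
                    # already reached on a longer path; nothing to add
                    stats["duplicates_merged"] += 1
                else:
                    # deeper rediscovery: re-level, reset paths, re-expand
                    node.level = level
                    node.precs = {p}
                    nxt[q.coords] = node
        frontier = nxt
    stats["edges"] = sum(len(n.precs) for n in registry.values())
    return MiniDAG(nodes=registry, stats=stats)


def extract_mlcs(
    dag: MiniDAG, seqs: SequenceSet | None = None, max_mlcs: int | None = None
) -> MLCSResult:
    """Backtrack predecessor links from the deepest level to spell all MLCSs.

    ``R`` is the maximum level in the DAG; every node at that level ends a
    longest path.  Distinct paths can spell the same string, so results
    are deduplicated.  ``max_mlcs`` optionally caps the number of distinct
    strings reported (the length is exact regardless).
    """
    r = dag.max_level
    if r == 0:
        return MLCSResult(length=0, mlcs_set=frozenset({""}), stats=dict(dag.stats))
    found: set[str] = set()
    tops = [n for n in dag.nodes.values() if n.level == r]
    for top in tops:
        # DFS over predecessor links; chars accumulate end-to-start
        stack: list[tuple[DagNode, list[str]]] = [(top, [top.point.char])]
        while stack:
            node, chars = stack.pop()
            for prev in node.precs:
                if prev.level == 0:
                    found.add("".join(reversed(chars)))
                    if max_mlcs is not None and len(found) >= max_mlcs:
                        return MLCSResult(
                            length=r,
                            mlcs_set=frozenset(found),
                            stats=dict(dag.stats),
                            truncated=True,
                        )
                else:
                    stack.append((prev, chars + [prev.point.char]))
    return MLCSResult(length=r, mlcs_set=frozenset(found), stats=dict(dag.stats))


def mini_mlcs(
    seqs: SequenceSet,
    cfg: BoundsConfig | None = None,
    max_mlcs: int | None = None,
) -> MLCSResult:
    """End-to-end pipeline: index, bounds, lower estimate, prune, extract."""
    cfg = cfg or BoundsConfig()
    st = build_successor_table(seqs)
    state = prepare_bounds(seqs, st, cfg)
    dag = construct_mini_dag(seqs, st, state, cfg)
    result = extract_mlcs(dag, seqs, max_mlcs=max_mlcs)
    result.stats["lower_bound"] = state.lower
    return result


def to_dot(dag: MiniDAG) -> str:
    """Render the DAG in DOT format (node label = char+coords, rank = level)."""
    lines = ["digraph minidag {", "  rankdir=LR;"]
    ids = {coords: f"n{k}" for k, coords in enumerate(dag.nodes)}
    by_level: dict[int, list[tuple[int, ...]]] = {}
    for coords, node in dag.nodes.items():
        by_level.setdefault(node.level, []).append(coords)
        label = repr(node.point)
        lines.append(f'  {ids[coords]} [label="{label}"];')
    for coords, node in dag.nodes.items():
        for prev in node.precs:
            lines.append(f"  {ids[prev.point.coords]} -> {ids[coords]};")
    for level, members in sorted(by_level.items()):
        ranked = "; ".join(ids[c] for c in members)
        lines.append(f"  {{ rank=same; {ranked}; }}")
    lines.append("}")
    return "\n".join(lines)
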