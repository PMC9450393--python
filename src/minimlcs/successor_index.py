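"""Match points and the next-occurrence successor table.

A match point of ``d`` sequences is a vector ``p = (p_1, ..., p_d)`` of
1-based positions that all hold the same character ``Ch(p)``.  The virtual
origin ``O = (0, ..., 0)`` precedes every match point.  A point ``q`` is an
immediate successor of ``p`` when ``p`` strictly dominates ``q`` in every
coordinate and no match point lies strictly between them; each character of
the alphabet contributes at most one immediate successor, so a point has at
most ``|Σ|`` of them.

The successor table stores, for every sequence, character and position
``j``, the smallest position ``k > j`` carrying that character.  It is
built in one backward scan per sequence and makes successor generation an
``O(d·|Σ|)`` table lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .sequence_io import SequenceSet

__all__ = ["MatchPoint", "SuccessorTable", "build_successor_table", "successors", "origin"]


@dataclass(frozen=True, eq=False)
class MatchPoint:
    """A d-vector of 1-based positions sharing one character.

    Equality and hashing consider the coordinates only; ``char`` is derived
    data (``None`` for the origin).
    """

    coords: tuple[int, ...]
    char: str | None = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MatchPoint):
            return NotImplemented
        return self.coords == other.coords

    def __hash__(self) -> int:
        return hash(self.coords)

    def __repr__(self) -> str:
        label = self.char if self.char is not None else "O"
        return f"{label}{self.coords}"

    @property
    def is_origin(self) -> bool:
        return all(c == 0 for c in self.coords)


def origin(d: int) -> MatchPoint:
    """The virtual origin ``O = (0, ..., 0)`` of a d-sequence instance."""
    return MatchPoint(coords=(0,) * d, char=None)


class SuccessorTable:
    """Per-sequence, per-character next-occurrence index.

    For sequence ``i`` and character index ``ci``, ``table[i][ci, j]`` is
    the smallest 1-based position ``k > j`` with that character, for
    ``j in 0..|s_i|``.  Absence is encoded by the sentinel ``|s_i| + 1``,
    strictly larger than any valid position, so lookups stay branch-free
    and a successor is emitted only when every coordinate is non-sentinel.
    """

    def __init__(self, seqs: SequenceSet):
        self.seqs = seqs
        self.alphabet = tuple(sorted(seqs.alphabet))
        self._char_index = {c: k for k, c in enumerate(self.alphabet)}
        self.tables: list[np.ndarray] = []
        for s in seqs.sequences:
            n = len(s)
            tab = np.full((len(self.alphabet), n + 1), n + 1, dtype=np.int64)
            # backward scan: row j inherits row j+1 except for the char at j+1
            for j in range(n - 1, -1, -1):
                tab[:, j] = tab[:, j + 1]
                tab[self._char_index[s[j]], j] = j + 1
            self.tables.append(tab)

    def next_pos(self, i: int, c: str, j: int) -> int | None:
        """Smallest position ``k > j`` of character ``c`` in sequence ``i``.

        Returns ``None`` when no further occurrence exists.
        """
        n = len(self.seqs.sequences[i])
        ci = self._char_index.get(c)
        if ci is None:
            return None
        k = int(self.tables[i][ci, j])
        return None if k > n else k

    def successors(self, p: MatchPoint) -> list[MatchPoint]:
        """All immediate successors of ``p`` (at most ``|Σ|``)."""
        out = []
        coords = p.coords
        for ci, c in enumerate(self.alphabet):
            q = []
            ok = True
            for i, tab in enumerate(self.tables):
                k = int(tab[ci, coords[i]])
                if k > len(self.seqs.sequences[i]):
                    ok = False
                    break
                q.append(k)
            if ok:
                out.append(MatchPoint(coords=tuple(q), char=c))
        return out

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.tables)


def build_successor_table(seqs: SequenceSet) -> SuccessorTable:
    """Build the next-occurrence table for ``seqs`` (one backward scan each)."""
    return SuccessorTable(seqs)


def successors(p: MatchPoint, st: SuccessorTable) -> list[MatchPoint]:
    """Immediate successors of ``p`` under the indexed sequence set."""
    return st.successors(p)
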