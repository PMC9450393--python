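"""Reading, validating and writing sets of sequences.

All positions in this package are 1-based: position ``i`` of a sequence
``s`` addresses the character ``s[i]`` with ``1 <= i <= |s|``.  Index 0 is
reserved for the virtual origin of the match-point DAG, so the ``i``-th
prefix of a sequence is its first ``i`` characters and the corresponding
suffix starts at character ``i + 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceSet",
    "SequenceSetError",
    "read_sequences",
    "write_sequences",
    "prefix_suffix",
]


class SequenceSetError(ValueError):
    """Raised when an input sequence set violates a validity constraint."""


@dataclass(frozen=True)
class SequenceSet:
    """An ordered, immutable collection of ``d >= 2`` non-empty sequences.

    Parameters
    ----------
    sequences
        The input strings, in file (or construction) order.
    alphabet
        The character set the sequences are drawn from.  When built through
        :func:`read_sequences` or :meth:`from_strings` this is inferred from
        the observed characters unless a declared alphabet is supplied, in
        which case out-of-alphabet characters are an error.
    """

    sequences: tuple[str, ...]
    alphabet: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise SequenceSetError(
                f"fewer than 2 sequences (got {len(self.sequences)})"
            )
        for k, s in enumerate(self.sequences, start=1):
            if not s:
                raise SequenceSetError(f"sequence {k} is empty")
            extra = set(s) - self.alphabet
            if extra:
                raise SequenceSetError(
                    f"sequence {k} contains characters outside the declared "
                    f"alphabet: {sorted(extra)}"
                )

    @classmethod
    def from_strings(
        cls,
        sequences: Iterable[str],
        alphabet: Iterable[str] | None = None,
    ) -> "SequenceSet":
        """Build a validated set, uppercasing and inferring Σ if needed."""
        seqs = tuple(str(s).upper() for s in sequences)
        if alphabet is None:
            sigma = frozenset().union(*(set(s) for s in seqs)) if seqs else frozenset()
        else:
            sigma = frozenset(str(c).upper() for c in alphabet)
        return cls(sequences=seqs, alphabet=sigma)

    @property
    def d(self) -> int:
        """Number of sequences."""
        return len(self.sequences)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.sequences)

    def char(self, i: int, pos: int) -> str:
        """Character at 1-based position ``pos`` of sequence ``i`` (0-based i)."""
        return self.sequences[i][pos - 1]

    def __iter__(self):
        return iter(self.sequences)


def prefix_suffix(s: str, i: int) -> tuple[str, str]:
    """Split ``s`` into its ``i``-th prefix and the suffix after position ``i``.

    The prefix holds characters ``1..i`` and the suffix characters
    ``i+1..|s|``; ``i = 0`` gives the empty prefix and the whole sequence,
    ``i = |s|`` the whole sequence and the empty suffix.

    >>> prefix_suffix("AACGTCGT", 5)
    ('AACGT', 'CGT')
    """
    if not 0 <= i <= len(s):
        raise ValueError(f"split index {i} out of range for length {len(s)}")
    return s[:i], s[i:]


def _read_lines(path: Path) -> list[str]:
    out = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(line)
    return out


def _read_fasta(path: Path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def read_sequences(
    path: str | Path,
    format: str = "lines",
    alphabet: Iterable[str] | None = None,
) -> SequenceSet:
    """Read a sequence set from ``path``.

    ``format`` is ``"lines"`` (one sequence per line, ``#`` comments and
    blank lines ignored) or ``"fasta"`` (one input sequence per record).
    Sequences are uppercased.  With a declared ``alphabet``, characters
    outside it (including IUPAC ambiguity codes) are rejected rather than
    expanded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "lines":
        raw = _read_lines(path)
    elif format == "fasta":
        raw = _read_fasta(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'lines' or 'fasta')")
    if not raw:
        raise SequenceSetError(f"no sequences found in {path}")
    return SequenceSet.from_strings(raw, alphabet=alphabet)


def write_sequences(
    seqs: SequenceSet, path: str | Path, format: str = "lines"
) -> None:
    """Write a sequence set in ``lines`` or ``fasta`` format."""
    path = Path(path)
    if format == "lines":
        path.write_text("\n".join(seqs.sequences) + "\n")
    elif format == "fasta":
        with path.open("w") as fh:
            for k, s in enumerate(seqs.sequences, start=1):
                fh.write(f">seq{k}\n{s}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def format_report(report: dict, as_json: bool = False) -> str:
    """Render a run report as JSON or aligned plain text."""
    if as_json:
        return json.dumps(report, indent=2, default=list, sort_keys=True)
    lines = []
    for key, val in report.items():
        if isinstance(val, dict):
            lines.append(f"{key}:")
            for k2, v2 in val.items():
                lines.append(f"  {k2}: {v2}")
        elif isinstance(val, (list, tuple, set, frozenset)):
            lines.append(f"{key}: {', '.join(map(str, sorted(val)))}")
        else:
            lines.append(f"{key}: {val}")
    return "\n".join(lines)
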