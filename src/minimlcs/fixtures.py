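"""Packaged example data and seeded synthetic sequence generation."""

from __future__ import annotations

import random
from dataclasses import dataclass

from .sequence_io import SequenceSet

__all__ = ["GeneratorSpec", "worked_example", "generate_random_set"]

#: Three short DNA sequences used throughout the documentation and tests;
#: their unique MLCS is ACGTC (length 5).
WORKED_EXAMPLE = ("AACGTCGT", "CGACGTCC", "GACCGTCT")


def worked_example() -> SequenceSet:
    """The three packaged example sequences (d=3, n=8, Σ = {A, C, G, T})."""
    return SequenceSet.from_strings(WORKED_EXAMPLE)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters for seeded random instance generation.

    ``n`` is either a fixed length or an inclusive ``(lo, hi)`` range
    sampled per sequence.  Characters are i.i.d. uniform over the
    alphabet, emulating randomly generated DNA benchmark instances.
    """

    d: int = 3
    n: int | tuple[int, int] = 10
    alphabet: str = "ACGT"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError("d must be >= 2")
        lo = self.n[0] if isinstance(self.n, tuple) else self.n
        if lo < 1:
            raise ValueError("sequence length must be >= 1")
        if not self.alphabet:
            raise ValueError("alphabet must be non-empty")


def generate_random_set(spec: GeneratorSpec) -> SequenceSet:
    """Draw ``d`` uniform random sequences; identical specs give identical sets."""
    rng = random.Random(spec.seed)
    chars = sorted(set(spec.alphabet.upper()))
    seqs = []
    for _ in range(spec.d):
        if isinstance(spec.n, tuple):
            length = rng.randint(*spec.n)
        else:
            length = spec.n
        seqs.append("".join(rng.choice(chars) for _ in range(length)))
    return SequenceSet.from_strings(seqs, alphabet=chars)
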