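from itertools import product

import pytest

from minimlcs import (
    GeneratorSpec,
    SequenceSet,
    build_successor_table,
    generate_random_set,
    worked_example,
)
from minimlcs.successor_index import MatchPoint


@pytest.fixture(scope="session")
def example():
    """The three packaged example sequences (unique MLCS: ACGTC)."""
    return worked_example()


@pytest.fixture(scope="session")
def example_table(example):
    return build_successor_table(example)


def random_instances(count, seed_base=1000, dims=(3, 4, 5), n_range=(5, 15)):
    """Deterministic stream of small random DNA instances for oracle tests."""
    lo, hi = n_range
    span = hi - lo + 1
    for i in range(count):
        d = dims[i % len(dims)]
        n = tuple(sorted((lo + (i * 7) % span, lo + (i * 3) % span)))
        yield i, generate_random_set(
            GeneratorSpec(d=d, n=n, alphabet="ACGT", seed=seed_base + i)
        )


def all_match_points(seqs: SequenceSet) -> list[MatchPoint]:
    """Exhaustive match-point enumeration by position products per character."""
    pts = []
    for c in sorted(seqs.alphabet):
        pos = [[k + 1 for k, ch in enumerate(s) if ch == c] for s in seqs.sequences]
        if any(not p for p in pos):
            continue
        pts.extend(MatchPoint(combo, c) for combo in product(*pos))
    return pts
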