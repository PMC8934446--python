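import functools
import random

import pytest

BASES = "ACGT"


@pytest.fixture
def rnd():
    return random.Random(20240)


def random_dna(rnd, n):
    return "".join(rnd.choice(BASES) for _ in range(n))


def brute_levenshtein(a: str, b: str) -> int:
    """Plain recursive unit-cost edit distance (independent oracle)."""

    @functools.lru_cache(maxsize=None)
    def go(i, j):
        if i == 0 or j == 0:
            return max(i, j)
        k = 0 if a[i - 1] == b[j - 1] else 1
        return min(go(i - 1, j) + 1, go(i, j - 1) + 1, go(i - 1, j - 1) + k)

    return go(len(a), len(b))


def brute_truncated_min(a: str, b: str, f: int) -> int:
    """Min unit edits allowing one string's tail to be truncated by <= f."""
    best = min(brute_levenshtein(a, b[: len(b) - d]) for d in range(min(f, len(b)) + 1))
    return min(
        best,
        min(brute_levenshtein(a[: len(a) - d], b) for d in range(min(f, len(a)) + 1)),
    )
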