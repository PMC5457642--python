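"""Shared fixtures and independent test oracles."""

from __future__ import annotations

from itertools import combinations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

_CAN_PAIR = {
    frozenset(("A", "U")),
    frozenset(("G", "C")),
    frozenset(("G", "U")),
}


def subset_oracle_max_pairs(residues: str, min_loop: int = 0) -> int:
    """Maximum non-crossing complementary matching by raw subset search.

    Deliberately naive and structurally different from both the dynamic
    program and the package's recursive enumerator: list every bondable
    index pair, try every subset in decreasing size order, and keep the
    first subset that is index-disjoint and non-crossing.  Only usable for
    very small N.
    """
    n = len(residues)
    cand = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if j - i > min_loop and frozenset((residues[i], residues[j])) in _CAN_PAIR
    ]
    for size in range(min(len(cand), n // 2), 0, -1):
        for combo in combinations(cand, size):
            used: set[int] = set()
            ok = True
            for i, j in combo:
                if i in used or j in used:
                    ok = False
                    break
                used.update((i, j))
            if not ok:
                continue
            if any(
                a < c < b < d
                for (a, b) in combo
                for (c, d) in combo
                if (a, b) != (c, d)
            ):
                continue
            return size
    return 0


@pytest.fixture
def oracle_max_pairs():
    return subset_oracle_max_pairs
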