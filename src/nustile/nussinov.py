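"""Reference serial base-pair maximization (Nussinov dynamic program).

The dynamic program computes, for every subsequence ``x_i..x_j``, the
maximum number of non-crossing complementary base pairs ``S(i, j)``:

    S(i, j) = max( S(i+1, j-1) + delta(i, j),
                   max_{i <= k < j} S(i, k) + S(k+1, j) ),

with ``S(i, j) = 0`` whenever ``i >= j``.  Indices are 0-based over
``0 <= i < j <= N-1``.

The reference kernel is written as the imperfectly nested loop form with two
statements whose dependence structure drives the tiling machinery in the
rest of the package:

    for i = N-2 down to 0:
      for j = i+1 .. N-1:
        for k = 0 .. j-i-1:                       # statement s0
          S(i,j) = max(S(i,j), S(i, i+k) + S(i+k+1, j))
        S(i,j) = max(S(i,j), S(i+1, j-1) + delta(i,j))   # statement s1

This loop order is the ground truth against which the tiled and wavefront
executors are compared integer-exactly, and the statement instances of s0
and s1 are exactly the iteration points of :mod:`nustile.dependence_graph`.

The module also provides a standard traceback to one optimal structure, the
closed-form count of bonding-function calls, and an exhaustive enumeration
of non-crossing structures that serves as a validation oracle at small N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .sequence_io import RNASequence, delta


@dataclass(frozen=True)
class DPMatrix:
    """The N x N dynamic-programming matrix S.

    Only the strict upper triangle carries information; entries with
    ``i >= j`` are represented explicitly and are zero.
    """

    S: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if self.S.shape != (self.n, self.n):
            raise ValueError(f"S must be {self.n}x{self.n}, got {self.S.shape}")

    def max_pairs(self) -> int:
        """S(0, N-1): the optimum for the full sequence."""
        return int(self.S[0, self.n - 1]) if self.n > 1 else 0


@dataclass(frozen=True)
class Structure:
    """A set of base pairs (i, j), i < j, at most one pair per index,
    non-crossing, every pair complementary for its sequence."""

    pairs: frozenset[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.pairs)

    def validate(self, seq: RNASequence, min_loop: int = 0) -> None:
        """Raise ValueError if any structure invariant is violated."""
        used: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < seq.n):
                raise ValueError(f"pair ({i},{j}) out of range")
            if i in used or j in used:
                raise ValueError(f"index reused in pair ({i},{j})")
            used.update((i, j))
            if delta(seq, i, j, min_loop) != 1:
                raise ValueError(f"pair ({i},{j}) is not complementary")
        plist = sorted(self.pairs)
        for a, (i, j) in enumerate(plist):
            for k, l in plist[a + 1:]:
                if i < k < j < l:
                    raise ValueError(f"pairs ({i},{j}) and ({k},{l}) cross")


def fold_serial(
    seq: RNASequence,
    min_loop: int = 0,
    delta_fn: Callable[[RNASequence, int, int, int], int] | None = None,
) -> DPMatrix:
    """Run the reference serial kernel and return the filled matrix.

    ``delta_fn`` may replace the bonding function (used for instrumentation);
    it is called exactly once per statement-s1 instance.
    """
    d = delta_fn if delta_fn is not None else delta
    n = seq.n
    S = [[0] * n for _ in range(n)]
    for i in range(n - 2, -1, -1):
        Si = S[i]
        for j in range(i + 1, n):
            best = Si[j]
            for k in range(j - i):  # s0
                v = Si[i + k] + S[i + k + 1][j]
                if v > best:
                    best = v
            v = S[i + 1][j - 1] + d(seq, i, j, min_loop)  # s1
            if v > best:
                best = v
            Si[j] = best
    return DPMatrix(S=np.array(S, dtype=np.int64).reshape(n, n), n=n)


def fold_serial_instrumented(
    seq: RNASequence, min_loop: int = 0
) -> tuple[DPMatrix, int]:
    """Like :func:`fold_serial` but also count bonding-function calls."""
    calls = 0

    def counting_delta(s: RNASequence, i: int, j: int, ml: int = 0) -> int:
        nonlocal calls
        calls += 1
        return delta(s, i, j, ml)

    mat = fold_serial(seq, min_loop, delta_fn=counting_delta)
    return mat, calls


def max_pairs(seq: RNASequence, min_loop: int = 0) -> int:
    """Maximum number of non-crossing complementary base pairs."""
    return fold_serial(seq, min_loop).max_pairs()


def delta_call_count(n: int) -> int:
    """Number of bonding-function invocations of the kernel at length n.

    One call per statement-s1 instance, i.e. one per matrix cell with
    ``0 <= i < j <= N-1``: N(N-1)/2.
    """
    if n < 1:
        raise ValueError(f"N must be >= 1, got {n}")
    return n * (n - 1) // 2


def traceback(seq: RNASequence, mat: DPMatrix, min_loop: int = 0) -> Structure:
    """Recover one optimal structure with ``|pairs| == S(0, N-1)``.

    Deterministic tie-break: the pairing branch (statement s1 with
    ``delta = 1``) is preferred when it attains the maximum; otherwise the
    smallest split point k.  Iterative (explicit stack) so that long
    sequences do not hit the recursion limit.
    """
    S = mat.S
    n = mat.n
    pairs: set[tuple[int, int]] = set()
    stack: list[tuple[int, int]] = [(0, n - 1)] if n > 1 else []
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        target = int(S[i, j])
        if target == 0:
            continue
        inner = int(S[i + 1, j - 1]) if i + 1 <= j - 1 else 0
        d = delta(seq, i, j, min_loop)
        if inner + d == target:
            if d == 1:
                pairs.add((i, j))
            stack.append((i + 1, j - 1))
            continue
        for k in range(i, j):
            left = int(S[i, k]) if i < k else 0
            right = int(S[k + 1, j]) if k + 1 < j else 0
            if left + right == target:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
        else:  # pragma: no cover - would indicate an inconsistent matrix
            raise RuntimeError(f"inconsistent DP matrix at cell ({i}, {j})")
    st = Structure(pairs=frozenset(pairs))
    if len(st) != mat.max_pairs():
        raise RuntimeError("traceback lost pairs: matrix inconsistent")
    return st


def fold(seq: RNASequence, min_loop: int = 0) -> tuple[DPMatrix, Structure]:
    """Convenience: matrix plus one optimal structure."""
    mat = fold_serial(seq, min_loop)
    return mat, traceback(seq, mat, min_loop)


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle (small N)
# ---------------------------------------------------------------------------

def enumerate_structures(
    seq: RNASequence, min_loop: int = 0, limit_n: int = 16
) -> list[frozenset[tuple[int, int]]]:
    """All non-crossing complementary pair sets of ``seq`` (exponential!).

    Exhaustive recursion: position i is either unpaired or paired with some
    complementary j, the pair splitting the remainder into an inside and an
    outside that are enumerated independently (which is exactly the
    non-crossing condition).  Intended as a validation oracle; guarded to
    ``N <= limit_n``.
    """
    if seq.n > limit_n:
        raise ValueError(f"enumeration oracle limited to N <= {limit_n}")

    def rec(i: int, j: int) -> list[frozenset[tuple[int, int]]]:
        # all structures of the region [i, j] inclusive
        if i >= j:
            return [frozenset()]
        out = []
        for rest in rec(i + 1, j):  # i unpaired
            out.append(rest)
        for k in range(i + 1, j + 1):
            if delta(seq, i, k, min_loop) == 1:
                for inside in rec(i + 1, k - 1):
                    for outside in rec(k + 1, j):
                        out.append(inside | outside | {(i, k)})
        return out

    return rec(0, seq.n - 1)


def brute_force_max_pairs(seq: RNASequence, min_loop: int = 0) -> int:
    """Maximum pair count by exhaustive enumeration (oracle for small N)."""
    return max(len(s) for s in enumerate_structures(seq, min_loop))
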