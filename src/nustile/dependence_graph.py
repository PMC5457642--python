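"""Concrete dependence model of the base-pair-maximization loop nest.

The two-statement kernel (see :mod:`nustile.nussinov`) reads and writes the
matrix S; statement instances are *iteration points*: ``s0`` instances carry
coordinates ``(i, j, k)`` and ``s1`` instances ``(i, j)``.  The data
dependences between instances form a finite directed acyclic graph for each
sequence length N.  The edges are given in closed form by four relations
(one per ordered statement pair), each a union of affine clauses mapping a
source instance to the instances that must execute later because they touch
the same S cell:

    s0 -> s0 : [i,j,k] -> [i,  j', j-i]     for j < j' < N
               [i,j,k] -> [i', j,  i-i'-1]  for 0 <= i' < i
               [i,j,k] -> [i,  j,  k']      for k < k' <= j-i-1
    s0 -> s1 : [i,j,k] -> [i-1, j+1]        for i >= 1, j <= N-2
               [i,j,k] -> [i,   j]
    s1 -> s0 : [i,j]   -> [i,  j', j-i]     for j < j' < N
               [i,j]   -> [i', j,  i-i'-1]  for 0 <= i' < i
    s1 -> s1 : [i,j]   -> [i-1, j+1]        for 1 <= i < j <= N-2

(sources range over their statement domains: ``0 <= k`` and ``i+k < j`` for
s0, ``0 <= i < j <= N-1`` for s1).  The non-uniform clauses — image offsets
depending on i and j — are what puts this kernel outside the reach of
standard rectangular tiling and motivates correction of tiles through the
positive transitive closure R+ of this graph.

Everything here is materialized concretely for a fixed N (no symbolic
relation arithmetic): per-point ``successors``, a graph object, a vectorized
bulk edge generator for grid-scale checks, and an iterative transitive
closure whose oracle is plain breadth-first reachability.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, NamedTuple

import numpy as np

S0 = "s0"
S1 = "s1"


class IterationPoint(NamedTuple):
    """A statement instance: s0 with (i, j, k), or s1 with (i, j) (k fixed 0)."""

    stmt: str
    i: int
    j: int
    k: int = 0

    @property
    def coords(self) -> tuple[int, ...]:
        return (self.i, self.j, self.k) if self.stmt == S0 else (self.i, self.j)

    def __repr__(self) -> str:  # compact: s0(1,5,2) / s1(1,5)
        return f"{self.stmt}{self.coords}"


def s0(i: int, j: int, k: int) -> IterationPoint:
    return IterationPoint(S0, i, j, k)


def s1(i: int, j: int) -> IterationPoint:
    return IterationPoint(S1, i, j, 0)


def in_domain(p: IterationPoint, n: int) -> bool:
    """Does p satisfy its statement's domain constraints for size n?"""
    if p.stmt == S0:
        return 0 <= p.i < p.j <= n - 1 and 0 <= p.k and p.i + p.k < p.j
    if p.stmt == S1:
        return 0 <= p.i < p.j <= n - 1 and p.k == 0
    return False


def iteration_space(n: int) -> set[IterationPoint]:
    """All statement instances executed at sequence length n."""
    if n < 1:
        raise ValueError(f"N must be >= 1, got {n}")
    pts: set[IterationPoint] = set()
    for i in range(n - 1):
        for j in range(i + 1, n):
            for k in range(j - i):
                pts.add(s0(i, j, k))
            pts.add(s1(i, j))
    return pts


def execution_key(p: IterationPoint) -> tuple[int, int, int, int]:
    """Sort key reproducing the serial kernel's execution order.

    i descending, then j ascending, all s0 instances (k ascending) before
    the cell's s1 instance.
    """
    return (-p.i, p.j, 0 if p.stmt == S0 else 1, p.k)


# ---------------------------------------------------------------------------
# The four dependence relations, clause by clause
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DependenceRelation:
    """One ordered statement pair's relation as a union of affine clauses.

    Each clause maps an in-domain source point to its image points for every
    admissible value of the clause's free variable (j', i' or k').
    """

    name: str
    source_stmt: str
    clauses: tuple[Callable[[IterationPoint, int], Iterator[IterationPoint]], ...]

    def apply(self, p: IterationPoint, n: int) -> Iterator[IterationPoint]:
        for clause in self.clauses:
            yield from clause(p, n)


def _c_s0s0_jprime(p: IterationPoint, n: int) -> Iterator[IterationPoint]:
    # [i,j,k] -> [i, j', j-i] : j < j' < N
    for jp in range(p.j + 1, n):
        yield s0(p.i, jp, p.j - p.i)


def _c_s0s0_iprime(p: IterationPoint, n: int) -> Iterator[IterationPoint]:
    # [i,j,k] -> [i', j, i-i'-1] : 0 <= i' < i
    for ip in range(p.i):
        yield s0(ip, p.j, p.i - ip - 1)


def _c_s0s0_kprime(p: IterationPoint, n: int) -> Iterator[IterationPoint]:
    # [i,j,k] -> [i, j, k'] : k < k' <= j-i-1
    for kp in range(p.k + 1, p.j - p.i):
        yield s0(p.i, p.j, kp)


def _c_s0s1_diag(p: IterationPoint, n: int) -> Iterator[IterationPoint]:
    # [i,j,k] -> [i-1, j+1] : 1 <= i, j <= N-2
    if p.i >= 1 and p.j <= n - 2:
        yield s1(p.i - 1, p.j + 1)


def _c_s0s1_cell(p: IterationPoint, n: int) -> Iterator[IterationPoint]:
    # [i,j,k] -> [i, j]
    yield s1(p.i, p.j)


def _c_s1s0_jprime(p: IterationPoint, n: int) -> Iterator[IterationPoint]:
    # [i,j] -> [i, j', j-i] : j < j' < N
    for jp in range(p.j + 1, n):
        yield s0(p.i, jp, p.j - p.i)


def _c_s1s0_iprime(p: IterationPoint, n: int) -> Iterator[IterationPoint]:
    # [i,j] -> [i', j, i-i'-1] : 0 <= i' < i
    for ip in range(p.i):
        yield s0(ip, p.j, p.i - ip - 1)


def _c_s1s1_diag(p: IterationPoint, n: int) -> Iterator[IterationPoint]:
    # [i,j] -> [i-1, j+1] : 1 <= i < j <= N-2
    if p.i >= 1 and p.j <= n - 2:
        yield s1(p.i - 1, p.j + 1)


RELATIONS: tuple[DependenceRelation, ...] = (
    DependenceRelation("s0->s0", S0, (_c_s0s0_jprime, _c_s0s0_iprime, _c_s0s0_kprime)),
    DependenceRelation("s0->s1", S0, (_c_s0s1_diag, _c_s0s1_cell)),
    DependenceRelation("s1->s0", S1, (_c_s1s0_jprime, _c_s1s0_iprime)),
    DependenceRelation("s1->s1", S1, (_c_s1s1_diag,)),
)


def successors(p: IterationPoint, n: int) -> set[IterationPoint]:
    """All dependence targets of p at size n (union over matching clauses)."""
    if not in_domain(p, n):
        raise ValueError(f"{p!r} is not in the iteration space for N={n}")
    out: set[IterationPoint] = set()
    for rel in RELATIONS:
        if rel.source_stmt == p.stmt:
            out.update(rel.apply(p, n))
    return out


# ---------------------------------------------------------------------------
# Graph and transitive closure
# ---------------------------------------------------------------------------

@dataclass
class DependenceGraph:
    """The materialized dependence graph at a fixed size n."""

    n: int
    vertices: set[IterationPoint]
    adjacency: dict[IterationPoint, set[IterationPoint]]

    def edges(self) -> Iterator[tuple[IterationPoint, IterationPoint]]:
        for src, tgts in self.adjacency.items():
            for tgt in tgts:
                yield src, tgt

    @property
    def n_edges(self) -> int:
        return sum(len(t) for t in self.adjacency.values())

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges())
        return g


def build_graph(n: int) -> DependenceGraph:
    """Vertices = iteration space, edges = clause images (per-point route)."""
    verts = iteration_space(n)
    adj = {p: successors(p, n) for p in verts}
    return DependenceGraph(n=n, vertices=verts, adjacency=adj)


def write_edgelist(g: DependenceGraph, path: str | Path) -> None:
    """Export edges as 'source<TAB>target' text lines."""
    with open(path, "w") as fh:
        for src, tgt in sorted(g.edges(), key=lambda e: (execution_key(e[0]), execution_key(e[1]))):
            fh.write(f"{src!r}\t{tgt!r}\n")


@dataclass
class ClosureRelation:
    """Positive transitive closure R+ of a dependence graph.

    ``reach(v)`` is the set of vertices connected to v by a directed path of
    length >= 1; the reflexive variant R* adds v itself.  Stored as one
    bitmask per vertex over a fixed vertex ordering.
    """

    order: list[IterationPoint]
    index: dict[IterationPoint, int]
    _reach_bits: list[int]

    def reach(self, p: IterationPoint) -> frozenset[IterationPoint]:
        """R+(p)."""
        bits = self._reach_bits[self.index[p]]
        return frozenset(self._decode(bits))

    def reach_star(self, p: IterationPoint) -> frozenset[IterationPoint]:
        """R*(p) = R+(p) plus p itself."""
        return self.reach(p) | {p}

    def image(self, pts: Iterable[IterationPoint]) -> frozenset[IterationPoint]:
        """R+(X) for a set X: union of reach over X."""
        bits = 0
        for p in pts:
            bits |= self._reach_bits[self.index[p]]
        return frozenset(self._decode(bits))

    def contains(self, src: IterationPoint, tgt: IterationPoint) -> bool:
        return bool(self._reach_bits[self.index[src]] >> self.index[tgt] & 1)

    @property
    def reach_map(self) -> dict[IterationPoint, frozenset[IterationPoint]]:
        """Materialized vertex -> R+(vertex) mapping (small graphs only)."""
        return {p: self.reach(p) for p in self.order}

    def _decode(self, bits: int) -> Iterator[IterationPoint]:
        while bits:
            low = bits & -bits
            yield self.order[low.bit_length() - 1]
            bits ^= low


def transitive_closure(g: DependenceGraph) -> ClosureRelation:
    """Compute R+ with the (modified) Floyd-Warshall iteration on bitmasks.

    For each pivot vertex q in turn, every vertex that currently reaches q
    absorbs q's reachable set.  On the acyclic graphs produced here this
    converges to exact reachability in one sweep when pivots are taken in
    reverse execution order; equality with per-vertex BFS is what the test
    suite asserts.
    """
    order = sorted(g.vertices, key=execution_key, reverse=True)
    index = {p: i for i, p in enumerate(order)}
    nv = len(order)
    reach = [0] * nv
    for p, tgts in g.adjacency.items():
        bits = 0
        for t in tgts:
            bits |= 1 << index[t]
        reach[index[p]] = bits
    for q in range(nv):
        rq = reach[q]
        if not rq:
            continue
        bit = 1 << q
        for v in range(nv):
            if reach[v] & bit:
                reach[v] |= rq
    return ClosureRelation(order=order, index=index, _reach_bits=reach)


# ---------------------------------------------------------------------------
# Vectorized bulk edge generation (grid-scale checks)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeArrays:
    """All dependence edges of one size as parallel integer arrays.

    ``(ss, si, sj, sk)`` describe sources, ``(ts, ti, tj, tk)`` targets;
    statement code 0 for s0, 1 for s1 (k is 0 for s1 rows).  Equal, row for
    row, to the edge set of :func:`build_graph` — asserted in tests.
    """

    n: int
    ss: np.ndarray
    si: np.ndarray
    sj: np.ndarray
    sk: np.ndarray
    ts: np.ndarray
    ti: np.ndarray
    tj: np.ndarray
    tk: np.ndarray

    @property
    def n_edges(self) -> int:
        return int(self.ss.size)


def _s0_domain(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    m = j > i
    i, j = i[m], j[m]
    # expand k = 0..j-i-1 per (i, j)
    reps = (j - i).astype(np.int64)
    if reps.size == 0:
        e = np.zeros(0, dtype=np.int64)
        return e, e, e
    ii = np.repeat(i, reps)
    jj = np.repeat(j, reps)
    kk = np.arange(reps.sum(), dtype=np.int64) - np.repeat(
        np.concatenate(([0], np.cumsum(reps)[:-1])), reps
    )
    return ii, jj, kk


def edge_arrays(n: int) -> EdgeArrays:
    """Generate every dependence edge at size n with numpy (no per-edge Python)."""
    if n < 1:
        raise ValueError(f"N must be >= 1, got {n}")
    s0i, s0j, s0k = _s0_domain(n)
    iu, ju = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    mu = ju > iu
    s1i, s1j = iu[mu].astype(np.int64), ju[mu].astype(np.int64)

    srcs, tgts = [], []

    def emit(sstmt, si, sj, sk, tstmt, ti, tj, tk):
        srcs.append((np.full(si.shape, sstmt, dtype=np.int64), si, sj, sk))
        tgts.append((np.full(ti.shape, tstmt, dtype=np.int64), ti, tj, tk))

    zeros = np.zeros_like
    # s0 -> s0 : [i,j,k] -> [i, j+d, j-i], d >= 1
    for d in range(1, n):
        m = s0j + d < n
        if not m.any():
            break
        emit(0, s0i[m], s0j[m], s0k[m], 0, s0i[m], s0j[m] + d, s0j[m] - s0i[m])
    # s0 -> s0 : [i,j,k] -> [i-a, j, a-1], a >= 1 (i' = i-a)
    for a in range(1, n):
        m = s0i - a >= 0
        if not m.any():
            break
        emit(0, s0i[m], s0j[m], s0k[m], 0, s0i[m] - a, s0j[m],
             np.full(int(m.sum()), a - 1, dtype=np.int64))
    # s0 -> s0 : [i,j,k] -> [i, j, k+a], a >= 1, k+a <= j-i-1
    for a in range(1, n):
        m = s0k + a <= s0j - s0i - 1
        if not m.any():
            break
        emit(0, s0i[m], s0j[m], s0k[m], 0, s0i[m], s0j[m], s0k[m] + a)
    # s0 -> s1 : [i,j,k] -> [i-1, j+1]
    m = (s0i >= 1) & (s0j <= n - 2)
    if m.any():
        emit(0, s0i[m], s0j[m], s0k[m], 1, s0i[m] - 1, s0j[m] + 1, zeros(s0i[m]))
    # s0 -> s1 : [i,j,k] -> [i, j]
    emit(0, s0i, s0j, s0k, 1, s0i, s0j, zeros(s0i))
    # s1 -> s0 : [i,j] -> [i, j+d, j-i], d >= 1
    for d in range(1, n):
        m = s1j + d < n
        if not m.any():
            break
        emit(1, s1i[m], s1j[m], zeros(s1i[m]), 0, s1i[m], s1j[m] + d, s1j[m] - s1i[m])
    # s1 -> s0 : [i,j] -> [i-a, j, a-1], a >= 1
    for a in range(1, n):
        m = s1i - a >= 0
        if not m.any():
            break
        emit(1, s1i[m], s1j[m], zeros(s1i[m]), 0, s1i[m] - a, s1j[m],
             np.full(int(m.sum()), a - 1, dtype=np.int64))
    # s1 -> s1 : [i,j] -> [i-1, j+1]
    m = (s1i >= 1) & (s1j <= n - 2)
    if m.any():
        emit(1, s1i[m], s1j[m], zeros(s1i[m]), 1, s1i[m] - 1, s1j[m] + 1, zeros(s1i[m]))

    if not srcs:
        e = np.zeros(0, dtype=np.int64)
        return EdgeArrays(n, e, e, e, e, e, e, e, e)
    cat = lambda parts, idx: np.concatenate([p[idx] for p in parts])
    return EdgeArrays(
        n,
        cat(srcs, 0), cat(srcs, 1), cat(srcs, 2), cat(srcs, 3),
        cat(tgts, 0), cat(tgts, 1), cat(tgts, 2), cat(tgts, 3),
    )
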