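"""Execute the folding dynamic program in corrected-tile order.

Three modes fill the same matrix S and must agree integer-exactly:

* ``reference`` — the plain serial kernel (:func:`nustile.nussinov.fold_serial`);
* ``tiled_serial`` — corrected tiles visited in lexicographic tile order,
  points within a tile in schedule-tuple order;
* ``wavefront`` — wavefronts executed serially with a barrier between
  consecutive time values; within a wavefront the (ii, jj) block tasks are
  handed to a worker pool one task at a time (dynamic dispatch, chunk 1).

Workers share S in memory; the proven wavefront independence (no dependence
edge between distinct same-time blocks) is what makes concurrent task
execution safe, and an optional seeded shuffle of the task order serves as
an adversarial probe of that property.  Validity of the tile schedule is
checked (and cached) before tiled execution for sizes up to
``VALIDATION_LIMIT``; beyond that the check must be requested explicitly
with ``force_validate`` since it enumerates every dependence edge.

The default tile size is 16x16x16 — the empirically best-performing block
for this kernel — with dynamic chunk-1 dispatch.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .nussinov import DPMatrix, fold_serial
from .sequence_io import RNASequence, bond_matrix, random_rna
from .dependence_graph import S0
from .scheduling import check_validity, wavefront_cross_edge_count, wavefronts
from .tiling import TileSize, corrected_tiles

logger = logging.getLogger(__name__)

DEFAULT_TILE = TileSize(16, 16, 16)
#: Largest N for which tiled execution re-derives schedule validity itself
#: (the check materializes every dependence edge, ~N^4/8 of them).
VALIDATION_LIMIT = 96


class ScheduleInvalidError(RuntimeError):
    """Raised when tiled execution is requested under an invalid schedule."""

    def __init__(self, report):
        self.report = report
        super().__init__(
            f"tile schedule invalid for N={report.n}, B={tuple(report.b)}: "
            f"{len(report.violations)} violating tile pairs"
        )


@dataclass
class ExecutionResult:
    """Filled matrix plus execution accounting."""

    matrix: DPMatrix
    mode: str
    n: int
    b: TileSize | None
    points_executed: int
    delta_calls: int
    tiles_executed: int
    wavefronts: int
    workers: int

    def max_pairs(self) -> int:
        return self.matrix.max_pairs()


@lru_cache(maxsize=64)
def _validity_empty(n: int, b: TileSize) -> bool:
    return check_validity(b, n).empty


def _require_valid(n: int, b: TileSize, force_validate: bool) -> None:
    if n < 2:
        return
    if n <= VALIDATION_LIMIT or force_validate:
        if not _validity_empty(n, b):
            raise ScheduleInvalidError(check_validity(b, n))


def _run_tile(points, S, bond) -> int:
    """Apply the kernel statements to one tile's points, in stored order.

    Returns the number of bonding-function (s1) evaluations.
    """
    calls = 0
    for p in points:
        i, j = p.i, p.j
        if p.stmt == S0:
            k = p.k
            v = S[i][i + k] + S[i + k + 1][j]
            if v > S[i][j]:
                S[i][j] = v
        else:
            v = S[i + 1][j - 1] + bond[i][j]
            calls += 1
            if v > S[i][j]:
                S[i][j] = v
    return calls


def execute_reference(seq: RNASequence, min_loop: int = 0) -> ExecutionResult:
    """Serial reference kernel wrapped in an ExecutionResult."""
    n = seq.n
    mat = fold_serial(seq, min_loop)
    n_points = n * (n - 1) * (n + 1) // 6 + n * (n - 1) // 2
    return ExecutionResult(
        matrix=mat,
        mode="reference",
        n=n,
        b=None,
        points_executed=n_points,
        delta_calls=n * (n - 1) // 2,
        tiles_executed=0,
        wavefronts=0,
        workers=1,
    )


def execute_tiled_serial(
    seq: RNASequence,
    b: TileSize = DEFAULT_TILE,
    min_loop: int = 0,
    force_validate: bool = False,
) -> ExecutionResult:
    """Run the corrected tiles in lexicographic order (serial tiled code)."""
    n = seq.n
    _require_valid(n, b, force_validate)
    ts = corrected_tiles(n, b)
    S = [[0] * n for _ in range(n)]
    bond = bond_matrix(seq, min_loop).tolist()
    calls = 0
    n_points = 0
    for t in ts.ordered_ids():
        pts = ts.tiles[t]
        calls += _run_tile(pts, S, bond)
        n_points += len(pts)
    return ExecutionResult(
        matrix=DPMatrix(S=np.array(S, dtype=np.int64).reshape(n, n), n=n),
        mode="tiled_serial",
        n=n,
        b=b,
        points_executed=n_points,
        delta_calls=calls,
        tiles_executed=len(ts.tiles),
        wavefronts=0,
        workers=1,
    )


def execute_wavefront(
    seq: RNASequence,
    b: TileSize = DEFAULT_TILE,
    workers: int = 4,
    shuffle_seed: int | None = None,
    min_loop: int = 0,
    force_validate: bool = False,
) -> ExecutionResult:
    """Run wavefronts serially, same-time block tasks concurrently.

    ``shuffle_seed`` randomly permutes the task order inside every
    wavefront (adversarial schedule); the result must not depend on it, nor
    on ``workers``.
    """
    if workers < 1:
        raise ValueError(f"workers must be >= 1, got {workers}")
    n = seq.n
    _require_valid(n, b, force_validate)
    ts = corrected_tiles(n, b)
    fronts = wavefronts(ts)
    S = [[0] * n for _ in range(n)]
    bond = bond_matrix(seq, min_loop).tolist()
    rng = np.random.default_rng(shuffle_seed) if shuffle_seed is not None else None
    calls = 0
    n_points = 0
    n_tiles = 0

    def run_task(task) -> tuple[int, int]:
        pts_done = 0
        task_calls = 0
        for tid in task.tiles:
            pts = ts.tiles[tid]
            task_calls += _run_tile(pts, S, bond)
            pts_done += len(pts)
        return pts_done, task_calls

    with ThreadPoolExecutor(max_workers=workers) as pool:
        for wf in fronts:
            tasks = list(wf.tasks)
            if rng is not None:
                rng.shuffle(tasks)
            # one task per submission = dynamic dispatch with chunk size 1
            futures = [pool.submit(run_task, task) for task in tasks]
            for fut in futures:  # barrier between consecutive time values
                pts_done, task_calls = fut.result()
                n_points += pts_done
                calls += task_calls
            n_tiles += sum(len(task.tiles) for task in tasks)
    return ExecutionResult(
        matrix=DPMatrix(S=np.array(S, dtype=np.int64).reshape(n, n), n=n),
        mode="wavefront",
        n=n,
        b=b,
        points_executed=n_points,
        delta_calls=calls,
        tiles_executed=n_tiles,
        wavefronts=len(fronts),
        workers=workers,
    )


# ---------------------------------------------------------------------------
# Self-test battery
# ---------------------------------------------------------------------------

@dataclass
class SelfTestCase:
    case: str
    check: str
    passed: bool
    detail: str = ""


def selftest(
    ns: Sequence[int],
    bs: Sequence[TileSize],
    seeds: Sequence[int],
    include_negative_control: bool = False,
    workers: int = 4,
) -> list[SelfTestCase]:
    """Run the full invariant battery over a grid; failures become entries.

    Checks per N: dependence-graph acyclicity and closure-vs-BFS equality
    (closure checks capped at N <= 20).  Per (N, B): corrected-tile
    partition, R_VALID emptiness, wavefront block independence.  Per
    (N, B, seed): three-way executor equivalence.  With
    ``include_negative_control``, the broken skew ii' = ii - jj is also
    evaluated and *expected* to produce violations.
    """
    from . import dependence_graph as dg

    out: list[SelfTestCase] = []
    for n in ns:
        if n <= 20:
            g = dg.build_graph(n)
            gx = g.to_networkx()
            import networkx as nx

            out.append(
                SelfTestCase(f"N={n}", "graph_acyclic", nx.is_directed_acyclic_graph(gx))
            )
            closure = dg.transitive_closure(g)
            ok = all(
                closure.reach(v) == frozenset(nx.descendants(gx, v)) for v in g.vertices
            )
            out.append(SelfTestCase(f"N={n}", "closure_equals_bfs", ok))
        for b in bs:
            ts = corrected_tiles(n, b)
            space_n = len(dg.iteration_space(n)) if n >= 2 else 0
            out.append(
                SelfTestCase(
                    f"N={n},B={tuple(b)}",
                    "corrected_partition",
                    ts.n_points == space_n and ts.multi_claims == 0,
                )
            )
            rep = check_validity(b, n, tiles=ts)
            out.append(SelfTestCase(f"N={n},B={tuple(b)}", "rvalid_empty", rep.empty))
            out.append(
                SelfTestCase(
                    f"N={n},B={tuple(b)}",
                    "wavefront_independent",
                    wavefront_cross_edge_count(b, n) == 0,
                )
            )
            if include_negative_control:
                neg = check_validity(b, n, skew="minus", tiles=ts)
                out.append(
                    SelfTestCase(
                        f"N={n},B={tuple(b)},skew=minus",
                        "rvalid_nonempty_negative_control",
                        not neg.empty,
                        detail=f"{len(neg.violations)} violating tile pairs",
                    )
                )
            for seed in seeds:
                seq = random_rna(max(n, 1), seed)
                ref = execute_reference(seq)
                ser = execute_tiled_serial(seq, b)
                par = execute_wavefront(seq, b, workers=workers, shuffle_seed=seed)
                same = bool(
                    np.array_equal(ref.matrix.S, ser.matrix.S)
                    and np.array_equal(ref.matrix.S, par.matrix.S)
                )
                out.append(
                    SelfTestCase(f"N={n},B={tuple(b)},seed={seed}", "executor_equivalence", same)
                )
    return out
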