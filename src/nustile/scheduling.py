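"""Skewed tile schedule, wavefronts, and the executable validity check.

Serial tiled execution visits corrected tiles in lexicographic
(ii, jj, g, kk) order.  To expose parallelism the tile space is skewed:
``ii' = ii + jj`` becomes a serial time coordinate, and all tile blocks
sharing one time value form a *wavefront* whose blocks are mutually
independent and can run concurrently between barriers.  A full schedule
tuple for a point p in tile (ii, jj, g, kk) is

    (ii + jj, jj, g, kk, -i, j, s, k)

compared lexicographically (s is the statement digit; constant separator
digits of the underlying schedule encoding are dropped as they never affect
comparisons).  The i coordinate is negated because the kernel decrements i.

``check_validity`` is the executable counterpart of the R_VALID relation:
it enumerates every dependence edge I -> J, locates the corrected tiles II
and JJ owning the endpoints, and records (II, JJ) whenever the schedule
fails to run the source strictly before the target — at the tile level via
the prefix (t, jj, g, kk) for distinct tiles, and at the point level inside
a tile.  An empty report proves the skewed tiled schedule legal for that
(N, B); the deliberately broken skew ``ii' = ii - jj`` is provided as a
negative control and is expected to fail.

The parallel unit is the whole (ii, jj) block (its g/kk tiles carry serial
intra-block dependences), so wavefront safety additionally requires that no
dependence edge connects two *different* blocks of the same wavefront;
``wavefront_cross_edge_count`` verifies exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Literal

import numpy as np

from .dependence_graph import EdgeArrays, IterationPoint, S0, S1, edge_arrays
from .tiling import TileID, TileSet, TileSize, corrected_tiles

Skew = Literal["plus", "minus"]


def skewed_time(t: TileID, skew: Skew = "plus") -> int:
    """Wavefront time of a tile: ii + jj (or ii - jj for the negative control)."""
    return t.ii + t.jj if skew == "plus" else t.ii - t.jj


def tile_prefix(t: TileID, skew: Skew = "plus") -> tuple[int, int, int, int]:
    """Tile-level schedule prefix (time, jj, g, kk)."""
    return (skewed_time(t, skew), t.jj, t.g, t.kk)


def schedule_tuple(
    p: IterationPoint, t: TileID, skew: Skew = "plus"
) -> tuple[int, int, int, int, int, int, int, int]:
    """Full schedule tuple of point p inside tile t (lexicographic order)."""
    s_digit = 0 if p.stmt == S0 else 1
    return (*tile_prefix(t, skew), -p.i, p.j, s_digit, p.k)


@dataclass(frozen=True)
class Task:
    """One (ii, jj) block of a wavefront: its corrected tiles in (g, kk) order."""

    ii: int
    jj: int
    time: int
    tiles: tuple[TileID, ...]


@dataclass(frozen=True)
class Wavefront:
    """All blocks sharing one skewed time value."""

    time: int
    tasks: tuple[Task, ...]


def wavefronts(ts: TileSet, skew: Skew = "plus") -> list[Wavefront]:
    """Partition a corrected tile set into time-ordered wavefronts."""
    blocks: dict[tuple[int, int], list[TileID]] = {}
    for t in ts.ordered_ids():
        blocks.setdefault((t.ii, t.jj), []).append(t)
    by_time: dict[int, list[Task]] = {}
    for (ii, jj), tids in blocks.items():
        time = skewed_time(TileID(ii, jj, 0, 0), skew)
        by_time.setdefault(time, []).append(
            Task(ii=ii, jj=jj, time=time, tiles=tuple(sorted(tids)))
        )
    return [
        Wavefront(time=time, tasks=tuple(sorted(by_time[time], key=lambda t: (t.ii, t.jj))))
        for time in sorted(by_time)
    ]


@dataclass
class ValidityReport:
    """Outcome of the R_VALID check: tile pairs whose order breaks a dependence."""

    n: int
    b: TileSize
    skew: Skew
    violations: set[tuple[TileID, TileID]]
    witnesses: dict[tuple[TileID, TileID], tuple[IterationPoint, IterationPoint]]
    n_edges_checked: int

    @property
    def empty(self) -> bool:
        return not self.violations


@lru_cache(maxsize=2)
def _edges(n: int) -> EdgeArrays:
    return edge_arrays(n)


def _tile_coords(
    ea: EdgeArrays, b: TileSize, n: int, which: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if which == "src":
        s, i, j, k = ea.ss, ea.si, ea.sj, ea.sk
    else:
        s, i, j, k = ea.ts, ea.ti, ea.tj, ea.tk
    ii = (n - 1 - i) // b.b1
    jj = (j - i - 1) // b.b2
    g = s.copy()
    kk = np.where(s == 0, k // b.b3, 0)
    return ii, jj, g, kk


def _pack_codes(s, i, j, k, n: int) -> np.ndarray:
    return ((i.astype(np.int64) * n + j) * n + k) * 2 + s


def check_validity(
    b: TileSize,
    n: int,
    skew: Skew = "plus",
    tiles: TileSet | None = None,
) -> ValidityReport:
    """Evaluate the R_VALID relation for (N, B) under the given skew.

    Every dependence edge is checked against the corrected-tile schedule;
    the report is empty iff the schedule is valid.
    """
    b.validate()
    if tiles is None:
        tiles = corrected_tiles(n, b)
    ea = _edges(n)
    if ea.n_edges == 0:
        return ValidityReport(n, b, skew, set(), {}, 0)

    sii, sjj, sg, skk = _tile_coords(ea, b, n, "src")
    tii, tjj, tg, tkk = _tile_coords(ea, b, n, "tgt")
    # structural fact the task-local correction relies on: (ii, jj) is
    # componentwise non-decreasing along every dependence edge
    if not ((tii >= sii).all() and (tjj >= sjj).all()):
        raise AssertionError("dependence edge decreases a tile block coordinate")

    # corrected owners: migrations only ever change (g, kk) within a block
    if tiles.migrations:
        over = {}
        for p, (_t0, t1) in tiles.migrations.items():
            code = ((p.i * n + p.j) * n + p.k) * 2 + (0 if p.stmt == S0 else 1)
            over[code] = (t1.g, t1.kk)
        mig_codes = np.fromiter(over.keys(), dtype=np.int64, count=len(over))
        for g_arr, kk_arr, s_arr, i_arr, j_arr, k_arr in (
            (sg, skk, ea.ss, ea.si, ea.sj, ea.sk),
            (tg, tkk, ea.ts, ea.ti, ea.tj, ea.tk),
        ):
            codes = _pack_codes(s_arr, i_arr, j_arr, k_arr, n)
            hit = np.isin(codes, mig_codes)
            for idx in np.nonzero(hit)[0]:
                g2, kk2 = over[int(codes[idx])]
                g_arr[idx] = g2
                kk_arr[idx] = kk2

    st = sii + sjj if skew == "plus" else sii - sjj
    tt = tii + tjj if skew == "plus" else tii - tjj
    # pack prefixes (time, jj, g, kk) into one comparable int64 per endpoint
    pfx_s = (((st + n).astype(np.int64) * n + sjj) * 2 + sg) * n + skk
    pfx_t = (((tt + n).astype(np.int64) * n + tjj) * 2 + tg) * n + tkk
    same = (sii == tii) & (sjj == tjj) & (sg == tg) & (skk == tkk)
    inter_bad = ~same & (pfx_s >= pfx_t)
    # intra-tile: full tuples reduce to the point order (-i, j, s, k)
    pk_s = (((n - 1 - ea.si).astype(np.int64) * n + ea.sj) * 2 + ea.ss) * n + ea.sk
    pk_t = (((n - 1 - ea.ti).astype(np.int64) * n + ea.tj) * 2 + ea.ts) * n + ea.tk
    intra_bad = same & (pk_s >= pk_t)

    bad = np.nonzero(inter_bad | intra_bad)[0]
    violations: set[tuple[TileID, TileID]] = set()
    witnesses: dict[tuple[TileID, TileID], tuple[IterationPoint, IterationPoint]] = {}
    for idx in bad:
        ii_pair = (
            TileID(int(sii[idx]), int(sjj[idx]), int(sg[idx]), int(skk[idx])),
            TileID(int(tii[idx]), int(tjj[idx]), int(tg[idx]), int(tkk[idx])),
        )
        if ii_pair not in violations:
            violations.add(ii_pair)
            src = IterationPoint(
                S0 if ea.ss[idx] == 0 else S1, int(ea.si[idx]), int(ea.sj[idx]), int(ea.sk[idx])
            )
            tgt = IterationPoint(
                S0 if ea.ts[idx] == 0 else S1, int(ea.ti[idx]), int(ea.tj[idx]), int(ea.tk[idx])
            )
            witnesses[ii_pair] = (src, tgt)
    return ValidityReport(n, b, skew, violations, witnesses, ea.n_edges)


def wavefront_cross_edge_count(b: TileSize, n: int, skew: Skew = "plus") -> int:
    """Dependence edges between *different* blocks of the same wavefront.

    Zero means the blocks of every wavefront are mutually independent, so
    they may run concurrently.  Block membership is read off the original
    tile coordinates: correction never moves a point across blocks (the
    componentwise (ii, jj) monotonicity asserted in check_validity).
    """
    b.validate()
    ea = _edges(n)
    if ea.n_edges == 0:
        return 0
    sii, sjj, _, _ = _tile_coords(ea, b, n, "src")
    tii, tjj, _, _ = _tile_coords(ea, b, n, "tgt")
    st = sii + sjj if skew == "plus" else sii - sjj
    tt = tii + tjj if skew == "plus" else tii - tjj
    cross = (st == tt) & ((sii != tii) | (sjj != tjj))
    return int(cross.sum())


def write_violations(report: ValidityReport, path: str | Path) -> None:
    """Export 'VIOLATION: (ii,jj,g,kk) -> (ii,jj,g,kk) via I -> J' lines."""
    with open(path, "w") as fh:
        for pair in sorted(report.violations):
            src, tgt = report.witnesses[pair]
            fh.write(
                f"VIOLATION: {tuple(pair[0])} -> {tuple(pair[1])} via {src!r} -> {tgt!r}\n"
            )
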