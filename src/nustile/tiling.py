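"""Rectangular 3D tiles over the iteration space and their correction.

Original tiles block the loop indices rectangularly with a size vector
``B = (b1, b2, b3)``: the outer index i is blocked downward from N-1 (it is
decremented by the kernel), j is blocked on its offset ``d = j - i - 1``
from the lower bound i+1, and the innermost index k in blocks of b3:

    ii = floor((N-1-i) / b1),  jj = floor((j-i-1) / b2),  kk = floor(k / b3)

A tile identifier is ``(ii, jj, g, kk)`` with a statement-group bit g: the
s0 instances of a block live in g=0 tiles (one per kk), the block's s1
instances in its single g=1 tile (kk = 0).  Tiles are totally ordered by
lexicographic comparison of (ii, jj, g, kk), which realizes the schedule
digit layout 0,ii,0,jj,g,kk — all s0 tiles of a block precede its s1 tile.

Because the dependences are non-uniform, rectangular tiles are not atomic:
some tile holds a dependence target whose source lies in a lexicographically
later tile.  Correction repairs this with the positive transitive closure
R+ of the dependence graph.  For each tile T, with TILE_GT / TILE_LT the
unions of all original tiles after / before T:

    TILE_ITR = TILE - R+(TILE_GT)
    TVLD_LT  = (R+(TILE_ITR) ∩ TILE_LT) - R+(TILE_GT)
    TILE_VLD = TILE_ITR ∪ TVLD_LT

so T first sheds every point reachable from a later tile, then absorbs the
stragglers it reaches in earlier tiles (unless a later tile also reaches
them).  The corrected tiles partition the iteration space and the induced
inter-tile graph is acyclic, which is what makes a valid tile schedule
possible.

Two equivalent routes compute the correction: a literal transcription of
the set algebra above driven by a :class:`ClosureRelation` (small N; also
the cross-check oracle in tests), and a fast task-local route.  The fast
route rests on a structural fact checked at run time: every dependence edge
is componentwise non-decreasing in (ii, jj) — i never increases and the
offset j-i never decreases along any clause — so any dependence path that
leaves a (ii, jj) block never returns, and the correction decomposes into
independent per-block problems using only intra-block edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import NamedTuple

from .dependence_graph import (
    S0,
    ClosureRelation,
    IterationPoint,
    in_domain,
    iteration_space,
    s0,
    s1,
)

logger = logging.getLogger(__name__)

BEFORE, EQUAL, AFTER = -1, 0, 1


class TileSize(NamedTuple):
    """Tile size vector B = (b1, b2, b3)."""

    b1: int
    b2: int
    b3: int

    @staticmethod
    def parse(text: str) -> "TileSize":
        parts = text.split(",")
        if len(parts) != 3:
            raise ValueError(f"tile size must be 'b1,b2,b3', got {text!r}")
        b = TileSize(*(int(p) for p in parts))
        b.validate()
        return b

    def validate(self) -> None:
        if min(self) < 1:
            raise ValueError(f"tile sizes must be >= 1, got {tuple(self)}")


class TileID(NamedTuple):
    """Tile identifier (ii, jj, g, kk); g=1 tiles (statement s1) have kk=0."""

    ii: int
    jj: int
    g: int
    kk: int


def tile_id_of(p: IterationPoint, b: TileSize, n: int) -> TileID:
    """Original (pre-correction) tile owning iteration point p."""
    if not in_domain(p, n):
        raise ValueError(f"{p!r} is not in the iteration space for N={n}")
    ii = (n - 1 - p.i) // b.b1
    jj = (p.j - p.i - 1) // b.b2
    if p.stmt == S0:
        return TileID(ii, jj, 0, p.k // b.b3)
    return TileID(ii, jj, 1, 0)


def tile_members(t: TileID, b: TileSize, n: int) -> set[IterationPoint]:
    """All iteration points whose original tile id is t.

    An empty result signals that t violates the tile-identifier constraints
    (its rectangular block misses the iteration space entirely).
    """
    if min(t) < 0:
        raise ValueError(f"tile components must be non-negative, got {t}")
    out: set[IterationPoint] = set()
    if t.g == 1 and t.kk != 0:
        return out
    i_hi = n - 1 - b.b1 * t.ii
    i_lo = max(0, n - b.b1 * (t.ii + 1))
    for i in range(i_lo, i_hi + 1):
        d_lo, d_hi = b.b2 * t.jj, b.b2 * (t.jj + 1) - 1
        for d in range(d_lo, d_hi + 1):
            j = i + 1 + d
            if j > n - 1:
                break
            if t.g == 1:
                out.add(s1(i, j))
            else:
                for k in range(b.b3 * t.kk, min(b.b3 * (t.kk + 1) - 1, d) + 1):
                    out.add(s0(i, j, k))
    return out


def constr_ok(t: TileID, b: TileSize, n: int) -> bool:
    """Tile-identifier constraint: the tile intersects the iteration space."""
    return bool(tile_members(t, b, n))


def compare_tiles(t1: TileID, t2: TileID) -> int:
    """Lexicographic order on (ii, jj, g, kk): BEFORE (-1), EQUAL (0), AFTER (1)."""
    return BEFORE if t1 < t2 else AFTER if t1 > t2 else EQUAL


def _point_key(p: IterationPoint) -> tuple[int, int, int, int]:
    # within-tile execution order: i desc, j asc, s0 before s1, k asc
    return (-p.i, p.j, 0 if p.stmt == S0 else 1, p.k)


@dataclass
class TileSet:
    """Mapping from tile id to its member points, plus correction bookkeeping.

    ``tiles[t]`` is ordered by the within-tile execution order.  For the
    corrected stage, ``migrations`` maps each point that changed tiles to
    its (original, corrected) pair, and the tiles partition the space.
    """

    b: TileSize
    n: int
    stage: str  # "original" | "corrected"
    tiles: dict[TileID, tuple[IterationPoint, ...]]
    migrations: dict[IterationPoint, tuple[TileID, TileID]] = field(default_factory=dict)
    multi_claims: int = 0

    def ordered_ids(self) -> list[TileID]:
        return sorted(self.tiles)

    def points(self, t: TileID) -> set[IterationPoint]:
        return set(self.tiles[t])

    @property
    def n_points(self) -> int:
        return sum(len(v) for v in self.tiles.values())

    def owner_of(self, p: IterationPoint) -> TileID:
        if p in self.migrations:
            return self.migrations[p][1]
        return tile_id_of(p, self.b, self.n)


def original_tiles(b: TileSize, n: int) -> TileSet:
    """Group the iteration space by original rectangular tile id."""
    b.validate()
    grouped: dict[TileID, list[IterationPoint]] = {}
    if n >= 2:
        for p in iteration_space(n):
            grouped.setdefault(tile_id_of(p, b, n), []).append(p)
    tiles = {t: tuple(sorted(v, key=_point_key)) for t, v in grouped.items()}
    return TileSet(b=b, n=n, stage="original", tiles=tiles)


# ---------------------------------------------------------------------------
# Correction, literal route (driven by a ClosureRelation)
# ---------------------------------------------------------------------------

def _correct_via_closure(b: TileSize, n: int, closure: ClosureRelation) -> TileSet:
    orig = original_tiles(b, n)
    order = orig.ordered_ids()
    vld: dict[TileID, set[IterationPoint]] = {}
    gt: set[IterationPoint] = set()
    # reverse sweep: gt accumulates members of tiles after the current one
    for t in reversed(order):
        members = orig.points(t)
        r_gt = closure.image(gt)
        itr = members - r_gt
        tvld = {
            q
            for q in closure.image(itr) - r_gt
            if tile_id_of(q, b, n) < t
        }
        vld[t] = itr | tvld
        gt |= members
    return _assemble_corrected(b, n, orig, vld)


# ---------------------------------------------------------------------------
# Correction, task-local route
# ---------------------------------------------------------------------------

def _intra_block_successors(
    p: IterationPoint, b: TileSize, n: int, ii: int, jj: int
) -> list[IterationPoint]:
    """Dependence targets of p that stay inside block (ii, jj).

    The self-cell clause [i,j,k] -> [i,j,k'] is thinned to its consecutive
    step k' = k+1, which preserves reachability (the full clause is the
    transitive closure of the chain and never leaves the (i, j) cell).
    """
    i, j = p.i, p.j
    out: list[IterationPoint] = []
    # j' sharing the block: same i, offset d' = j'-i-1 in jj's range
    j_hi = min(n - 1, i + b.b2 * (jj + 1))
    # i' sharing the block: (N-1-i')//b1 == ii and (j-i'-1)//b2 == jj
    i_lo = max(0, n - b.b1 * (ii + 1), j - b.b2 * (jj + 1))
    if p.stmt == S0:
        for jp in range(j + 1, j_hi + 1):
            out.append(s0(i, jp, j - i))
        for ip in range(i_lo, i):
            out.append(s0(ip, j, i - ip - 1))
        if p.k + 1 <= j - i - 1:
            out.append(s0(i, j, p.k + 1))
        if i >= 1 and j <= n - 2 and (n - 1 - (i - 1)) // b.b1 == ii and (j - i + 1) // b.b2 == jj:
            out.append(s1(i - 1, j + 1))
        out.append(s1(i, j))
    else:
        for jp in range(j + 1, j_hi + 1):
            out.append(s0(i, jp, j - i))
        for ip in range(i_lo, i):
            out.append(s0(ip, j, i - ip - 1))
        if i >= 1 and j <= n - 2 and (n - 1 - (i - 1)) // b.b1 == ii and (j - i + 1) // b.b2 == jj:
            out.append(s1(i - 1, j + 1))
    return out


def _correct_task_local(b: TileSize, n: int) -> TileSet:
    orig = original_tiles(b, n)
    # group tiles by their (ii, jj) block
    blocks: dict[tuple[int, int], list[TileID]] = {}
    for t in orig.ordered_ids():
        blocks.setdefault((t.ii, t.jj), []).append(t)
    vld: dict[TileID, set[IterationPoint]] = {}
    for (ii, jj), tids in blocks.items():
        members = {t: orig.points(t) for t in tids}
        adj: dict[IterationPoint, list[IterationPoint]] = {}
        for pts in members.values():
            for p in pts:
                adj[p] = _intra_block_successors(p, b, n, ii, jj)
        own = {p: t for t, pts in members.items() for p in pts}
        d: set[IterationPoint] = set()  # R+(TILE_GT) within the block
        for t in reversed(tids):  # tids is ascending (g, kk)
            itr = [p for p in members[t] if p not in d]
            # forward reach of itr, pruned at d (anything entered there is
            # in R+(TILE_GT) and subtracted by the formulas anyway)
            reach: set[IterationPoint] = set()
            expanded: set[IterationPoint] = set()
            stack = list(itr)
            while stack:
                p = stack.pop()
                if p in expanded:
                    continue
                expanded.add(p)
                for q in adj[p]:
                    if q not in d and q not in reach:
                        reach.add(q)
                        stack.append(q)
            tvld = {q for q in reach if own[q] < t}
            vld[t] = set(itr) | tvld
            # fold this tile's members into TILE_GT: grow d = R+(GT)
            stack = []
            for p in members[t]:
                for q in adj[p]:
                    if q not in d:
                        d.add(q)
                        stack.append(q)
            while stack:
                p = stack.pop()
                for q in adj[p]:
                    if q not in d:
                        d.add(q)
                        stack.append(q)
    return _assemble_corrected(b, n, orig, vld)


def _assemble_corrected(
    b: TileSize, n: int, orig: TileSet, vld: dict[TileID, set[IterationPoint]]
) -> TileSet:
    """Resolve claims, verify the partition, build the corrected TileSet."""
    claimants: dict[IterationPoint, list[TileID]] = {}
    for t, pts in vld.items():
        for p in pts:
            claimants.setdefault(p, []).append(t)
    multi = 0
    assignment: dict[IterationPoint, TileID] = {}
    for p, ts in claimants.items():
        if len(ts) > 1:
            multi += 1
            logger.warning("point %r claimed by %d tiles %s; keeping earliest", p, len(ts), sorted(ts))
        assignment[p] = min(ts)
    space = iteration_space(n) if n >= 2 else set()
    if set(assignment) != space:
        missing = space - set(assignment)
        raise RuntimeError(
            f"corrected tiles do not partition the space for N={n}, B={tuple(b)}: "
            f"{len(missing)} unassigned points (e.g. {sorted(missing)[:3]})"
        )
    tiles: dict[TileID, list[IterationPoint]] = {}
    migrations: dict[IterationPoint, tuple[TileID, TileID]] = {}
    for p, t in assignment.items():
        tiles.setdefault(t, []).append(p)
        t0 = tile_id_of(p, b, n)
        if t0 != t:
            migrations[p] = (t0, t)
    if migrations:
        logger.debug(
            "N=%d B=%s: %d points migrated during correction", n, tuple(b), len(migrations)
        )
    return TileSet(
        b=b,
        n=n,
        stage="corrected",
        tiles={t: tuple(sorted(v, key=_point_key)) for t, v in tiles.items()},
        migrations=migrations,
        multi_claims=multi,
    )


def correct_tiles(b: TileSize, n: int, closure: ClosureRelation | None = None) -> TileSet:
    """Correct original tiles into valid tiles (TILE_VLD) for size n.

    With ``closure`` given, the correction transcribes the TILE_ITR /
    TVLD_LT / TILE_VLD set algebra literally through R+ (practical up to a
    few thousand iteration points).  Without it, the task-local route is
    used; both produce identical tile sets.
    """
    b.validate()
    if closure is not None:
        return _correct_via_closure(b, n, closure)
    return _correct_task_local(b, n)


@lru_cache(maxsize=24)
def corrected_tiles(n: int, b: TileSize) -> TileSet:
    """Cached task-local correction, keyed by (N, B)."""
    return correct_tiles(b, n)


def write_tile_map(ts: TileSet, path: str | Path) -> None:
    """Export 'ii jj g kk : stmt i j [k]' lines for inspection."""
    with open(path, "w") as fh:
        for t in ts.ordered_ids():
            for p in ts.tiles[t]:
                coords = " ".join(str(c) for c in p.coords)
                fh.write(f"{t.ii} {t.jj} {t.g} {t.kk} : {p.stmt} {coords}\n")
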