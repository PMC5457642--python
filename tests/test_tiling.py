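"""Tile formation, ordering, and closure-based correction."""

from __future__ import annotations

import networkx as nx
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nustile.dependence_graph import (
    build_graph,
    iteration_space,
    s0,
    s1,
    transitive_closure,
)
from nustile.tiling import (
    TileID,
    TileSize,
    compare_tiles,
    correct_tiles,
    original_tiles,
    tile_id_of,
    tile_members,
    write_tile_map,
)

B_GRID = [
    TileSize(1, 1, 1),
    TileSize(2, 2, 2),
    TileSize(3, 2, 4),
    TileSize(4, 4, 4),
    TileSize(16, 16, 16),
]


class TestTileID:
    def test_block_formulas(self):
        b = TileSize(2, 2, 2)
        assert tile_id_of(s0(4, 5, 0), b, 6) == TileID(0, 0, 0, 0)
        assert tile_id_of(s1(0, 5), b, 6) == TileID(2, 2, 1, 0)

    def test_unit_blocks_isolate_s0_points(self):
        b = TileSize(1, 1, 1)
        ids = [tile_id_of(p, b, 5) for p in iteration_space(5) if p.stmt == "s0"]
        assert len(ids) == len(set(ids))

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            tile_id_of(s0(3, 2, 0), TileSize(2, 2, 2), 6)

    @given(st.integers(2, 12), st.sampled_from(B_GRID))
    def test_inverse_consistency(self, n, b):
        for p in iteration_space(n):
            assert p in tile_members(tile_id_of(p, b, n), b, n)


class TestTileMembers:
    def test_single_tile_holds_everything(self):
        b = TileSize(8, 8, 8)
        s0_points = {p for p in iteration_space(6) if p.stmt == "s0"}
        assert tile_members(TileID(0, 0, 0, 0), b, 6) == s0_points

    def test_constraint_violation_is_empty(self):
        # block entirely below i = 0: N-1 - b1*ii < 0
        assert tile_members(TileID(5, 0, 0, 0), TileSize(2, 2, 2), 6) == set()

    def test_members_partition_space(self):
        for n in (5, 9):
            for b in B_GRID:
                ts = original_tiles(b, n)
                assert ts.n_points == len(iteration_space(n))
                seen = set()
                for t in ts.ordered_ids():
                    pts = ts.points(t)
                    assert not (pts & seen)
                    seen |= pts


class TestCompareTiles:
    def test_group_digit_orders_s0_before_s1(self):
        assert compare_tiles(TileID(0, 0, 0, 1), TileID(0, 0, 1, 0)) == -1

    def test_lexicographic(self):
        assert compare_tiles(TileID(0, 1, 0, 0), TileID(1, 0, 0, 0)) == -1
        assert compare_tiles(TileID(2, 0, 1, 0), TileID(2, 0, 1, 0)) == 0


class TestCorrection:
    def test_routes_agree(self):
        for n in (4, 7, 10):
            closure = transitive_closure(build_graph(n))
            for b in B_GRID:
                via_closure = correct_tiles(b, n, closure=closure)
                task_local = correct_tiles(b, n)
                assert {t: set(v) for t, v in via_closure.tiles.items()} == {
                    t: set(v) for t, v in task_local.tiles.items()
                }

    def test_degenerate_single_block(self):
        # one s0 tile + one s1 tile; the set algebra moves exactly the s0
        # points reachable from s1 instances into the later s1 tile
        n = 6
        b = TileSize(n, n, n)
        orig = original_tiles(b, n)
        corr = correct_tiles(b, n)
        assert set(corr.tiles) == {TileID(0, 0, 0, 0), TileID(0, 0, 1, 0)}
        closure = transitive_closure(build_graph(n))
        s1_points = orig.points(TileID(0, 0, 1, 0))
        absorbed = closure.image(s1_points) - s1_points
        assert corr.points(TileID(0, 0, 1, 0)) == s1_points | absorbed
        assert corr.points(TileID(0, 0, 0, 0)) == (
            orig.points(TileID(0, 0, 0, 0)) - absorbed
        )

    def test_unit_tiles_are_identity(self):
        # b = (1,1,1): no dependence runs against the tile order, so
        # correction changes nothing
        n = 7
        orig = original_tiles(TileSize(1, 1, 1), n)
        corr = correct_tiles(TileSize(1, 1, 1), n)
        assert {t: set(v) for t, v in corr.tiles.items()} == {
            t: set(v) for t, v in orig.tiles.items()
        }

    def test_partition_and_no_multi_claims(self):
        for n in (4, 12, 25):
            for b in B_GRID:
                ts = correct_tiles(b, n)
                assert ts.n_points == len(iteration_space(n))
                assert ts.multi_claims == 0

    def test_migrations_move_points_forward_only(self):
        # TVLD_LT absorbs stragglers from earlier tiles, never later ones
        for n in (8, 16):
            for b in B_GRID:
                ts = correct_tiles(b, n)
                for p, (t_orig, t_new) in ts.migrations.items():
                    assert t_orig < t_new

    def test_s1_tiles_absorb_s0_stragglers(self):
        # the characteristic correction: g=1 tiles end up holding s0 points
        ts = correct_tiles(TileSize(2, 2, 2), 10)
        mixed = [
            t
            for t in ts.ordered_ids()
            if t.g == 1 and any(p.stmt == "s0" for p in ts.tiles[t])
        ]
        assert mixed, "expected corrected s1 tiles to contain s0 instances"

    def test_quotient_graph_acyclic(self):
        for n in (6, 10):
            for b in (TileSize(2, 2, 2), TileSize(3, 2, 4)):
                ts = correct_tiles(b, n)
                g = build_graph(n)
                q = nx.DiGraph()
                for src, tgt in g.edges():
                    a, bb = ts.owner_of(src), ts.owner_of(tgt)
                    if a != bb:
                        q.add_edge(a, bb)
                assert nx.is_directed_acyclic_graph(q)

    def test_tile_map_export(self, tmp_path):
        ts = correct_tiles(TileSize(2, 2, 2), 6)
        p = tmp_path / "tiles.txt"
        write_tile_map(ts, p)
        lines = p.read_text().splitlines()
        assert len(lines) == ts.n_points
        assert all(" : " in ln for ln in lines)
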