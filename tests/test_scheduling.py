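"""Skewed schedule tuples, wavefronts, and the validity relation."""

from __future__ import annotations

import pytest

from nustile.dependence_graph import build_graph, iteration_space, s0, s1
from nustile.scheduling import (
    check_validity,
    schedule_tuple,
    skewed_time,
    tile_prefix,
    wavefront_cross_edge_count,
    wavefronts,
    write_violations,
)
from nustile.tiling import TileID, TileSize, correct_tiles


class TestSkewedTime:
    def test_values(self):
        assert skewed_time(TileID(0, 0, 0, 0)) == 0
        assert skewed_time(TileID(2, 3, 0, 1)) == 5

    def test_monotone_in_block_coords(self):
        t = TileID(3, 4, 0, 0)
        assert skewed_time(TileID(4, 4, 0, 0)) == skewed_time(t) + 1
        assert skewed_time(TileID(3, 5, 0, 0)) == skewed_time(t) + 1

    def test_negative_control_skew(self):
        assert skewed_time(TileID(1, 3, 0, 0), skew="minus") == -2


class TestScheduleTuple:
    def test_direct_substitution(self):
        assert schedule_tuple(s1(0, 1), TileID(0, 0, 1, 0)) == (0, 0, 1, 0, 0, 1, 1, 0)

    def test_within_tile_order_j_then_k(self):
        t = TileID(0, 0, 0, 0)
        assert schedule_tuple(s0(3, 4, 0), t) < schedule_tuple(s0(3, 5, 1), t)

    def test_i_negated_smaller_i_later(self):
        t = TileID(0, 0, 0, 0)
        assert schedule_tuple(s0(2, 5, 0), t) > schedule_tuple(s0(3, 5, 0), t)

    def test_injective_within_tile(self):
        n, b = 12, TileSize(3, 2, 4)
        ts = correct_tiles(b, n)
        for t in ts.ordered_ids():
            tuples = [schedule_tuple(p, t) for p in ts.tiles[t]]
            assert len(set(tuples)) == len(tuples)


class TestWavefronts:
    def test_single_block_single_wavefront(self):
        n = 6
        ts = correct_tiles(TileSize(n, n, n), n)
        fronts = wavefronts(ts)
        assert len(fronts) == 1 and fronts[0].time == 0 and len(fronts[0].tasks) == 1

    def test_times_sorted_first_front_single_task(self):
        ts = correct_tiles(TileSize(2, 2, 2), 12)
        fronts = wavefronts(ts)
        times = [w.time for w in fronts]
        assert times == sorted(times)
        assert len(fronts[0].tasks) == 1
        assert fronts[0].tasks[0].ii == 0 and fronts[0].tasks[0].jj == 0
        max_t = max(t.ii + t.jj for t in ts.ordered_ids())
        assert times[-1] == max_t

    def test_tasks_cover_distinct_blocks(self):
        ts = correct_tiles(TileSize(2, 2, 2), 12)
        fronts = wavefronts(ts)
        blocks = {(t.ii, t.jj) for t in ts.ordered_ids()}
        tasks = [task for w in fronts for task in w.tasks]
        assert len(tasks) == len(blocks)
        assert all(task.ii + task.jj == task.time for w in fronts for task in w.tasks)

    def test_union_of_tasks_is_iteration_space(self):
        n = 14
        ts = correct_tiles(TileSize(4, 4, 4), n)
        fronts = wavefronts(ts)
        pts = set()
        for w in fronts:
            for task in w.tasks:
                for tid in task.tiles:
                    pts.update(ts.tiles[tid])
        assert pts == iteration_space(n)


class TestValidity:
    @pytest.mark.parametrize("b", [TileSize(4, 4, 4), TileSize(16, 16, 16)])
    def test_empty_for_skewed_schedule(self, b):
        assert check_validity(b, 20).empty

    def test_unit_tiles_empty(self):
        assert check_validity(TileSize(1, 1, 1), 3).empty

    def test_negative_control_nonempty(self):
        rep = check_validity(TileSize(2, 2, 2), 8, skew="minus")
        assert not rep.empty
        # every recorded pair must be a real dependence crossing backwards in time
        for (ii, jj), (src, tgt) in rep.witnesses.items():
            assert tile_prefix(ii, "minus") >= tile_prefix(jj, "minus")

    def test_violation_export(self, tmp_path):
        rep = check_validity(TileSize(2, 2, 2), 8, skew="minus")
        p = tmp_path / "viol.txt"
        write_violations(rep, p)
        lines = p.read_text().splitlines()
        assert len(lines) == len(rep.violations)
        assert all(ln.startswith("VIOLATION: ") for ln in lines)


class TestWavefrontIndependence:
    def test_no_cross_edges_small_grid(self):
        for n in (6, 12, 20):
            for b in (TileSize(1, 1, 1), TileSize(2, 2, 2), TileSize(4, 4, 4)):
                assert wavefront_cross_edge_count(b, n) == 0

    def test_negative_control_has_cross_edges(self):
        assert wavefront_cross_edge_count(TileSize(2, 2, 2), 8, skew="minus") > 0

    def test_wavefront_concatenation_topologically_sorts(self):
        # serial wavefront order (tasks in reverse within a front) must still
        # place every dependence source before its target
        n, b = 10, TileSize(2, 2, 2)
        ts = correct_tiles(b, n)
        pos = {}
        c = 0
        for w in wavefronts(ts):
            for task in reversed(w.tasks):
                for tid in task.tiles:
                    for p in ts.tiles[tid]:
                        pos[p] = c
                        c += 1
        for src, tgt in build_graph(n).edges():
            assert pos[src] < pos[tgt]
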