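"""TE-sphere life cycle: nucleation, motion, coalescence, splitting, attachment."""

import numpy as np
import pytest

from elastoca.monomer_field import MonomerField
from elastoca.scaffold_geometry import ScaffoldMask, build_scaffold
from elastoca.sphere_dynamics import (
    SphereSet,
    attach_spheres,
    merge_contacting,
    move_spheres,
    nucleate,
    split_oversized,
)

SIGMA1 = 0.7


def make_set(n=40, spheres=()):
    ss = SphereSet(n, SIGMA1)
    for x, y, mass, *rest in spheres:
        ss.add(x, y, mass, attached=bool(rest[0]) if rest else False)
    return ss


def empty_scaffold(n):
    return ScaffoldMask(np.zeros((n, n), bool), "square", 1, 1.0, (n, n))


def scaffold_from_cells(n, cells):
    g = np.zeros((n, n), bool)
    for c in cells:
        g[c] = True
    return ScaffoldMask(g, "square", 1, 1.0, (n, n))


class TestNucleate:
    def test_sigma1_cell_spawns_unit_sphere(self, rng):
        f = MonomerField.zeros(10)
        f.grid[4, 5] = 0.7
        ss = make_set(10)
        created = nucleate(f, ss, 0.7, 2.0, rng)
        assert created == 1 and len(ss) == 1
        assert ss.mass[0] == pytest.approx(0.7)
        assert ss.area_px[0] == 1
        assert (ss.x[0], ss.y[0]) == (4, 5)
        assert f.total() == 0.0

    def test_moore_neighborhood_spawns_and_consumes_nine_cells(self, rng):
        f = MonomerField.zeros(10)
        f.grid[3:6, 3:6] = 0.25  # Moore sum 2.25 >= sigma2 = 2
        ss = make_set(10)
        nucleate(f, ss, 0.7, 2.0, rng)
        assert len(ss) == 1
        assert ss.mass[0] == pytest.approx(2.25)
        assert ss.area_px[0] == 3  # round(2.25 / 0.7)
        assert f.total() == 0.0

    def test_below_both_thresholds_nothing_happens(self, rng):
        f = MonomerField(np.full((10, 10), 0.05))
        before = f.grid.copy()
        ss = make_set(10)
        assert nucleate(f, ss, 0.7, 2.0, rng) == 0
        assert len(ss) == 0
        assert np.array_equal(f.grid, before)

    def test_content_consumed_at_most_once(self, rng):
        # two overlapping super-threshold neighborhoods: total sphere mass
        # equals the consumed content exactly, nothing double-counted
        f = MonomerField.zeros(10)
        f.grid[2:6, 2:6] = 0.3
        before = f.total()
        ss = make_set(10)
        nucleate(f, ss, 0.7, 2.0, rng)
        assert ss.total_mass() + f.total() == pytest.approx(before, rel=1e-12)

    def test_sigma1_above_sigma2_warns(self, rng):
        f = MonomerField.zeros(10)
        with pytest.warns(UserWarning, match="sigma1 > sigma2"):
            nucleate(f, make_set(10), 3.0, 2.0, rng)


class TestMoveSpheres:
    def test_attached_spheres_never_move(self, rng):
        ss = make_set(20, [(5, 5, 30.0, True), (10, 10, 28.0, True)])
        sc = empty_scaffold(20)
        move_spheres(ss, sc, rng)
        assert list(ss.x) == [5, 10] and list(ss.y) == [5, 10]

    def test_direction_frequencies_uniform(self):
        rng = np.random.default_rng(11)
        ss = make_set(1000, [(500, 500, 0.7)])
        sc = empty_scaffold(1000)
        counts = {(1, 0): 0, (-1, 0): 0, (0, 1): 0, (0, -1): 0}
        for _ in range(10_000):
            x0, y0 = int(ss.x[0]), int(ss.y[0])
            move_spheres(ss, sc, rng)
            counts[(int(ss.x[0] - x0), int(ss.y[0] - y0))] += 1
        for c in counts.values():
            assert abs(c / 10_000 - 0.25) < 0.02

    def test_fully_blocked_sphere_stays(self, rng):
        sc = scaffold_from_cells(20, [(9, 10), (11, 10), (10, 9), (10, 11)])
        ss = make_set(20, [(10, 10, 0.7)])
        for _ in range(20):
            move_spheres(ss, sc, rng)
        assert (ss.x[0], ss.y[0]) == (10, 10)

    def test_moves_wrap_periodically(self):
        rng = np.random.default_rng(0)
        ss = make_set(8, [(0, 0, 0.7)])
        sc = empty_scaffold(8)
        for _ in range(50):
            move_spheres(ss, sc, rng)
            assert 0 <= ss.x[0] < 8 and 0 <= ss.y[0] < 8


def oracle_partition(ss):
    """Brute-force pairwise union-find over the contact graph."""
    m = len(ss)
    rad = ss.radius
    parent = list(range(m))

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for i in range(m):
        for j in range(i + 1, m):
            dx = (ss.x[i] - ss.x[j] + ss.n // 2) % ss.n - ss.n // 2
            dy = (ss.y[i] - ss.y[j] + ss.n // 2) % ss.n - ss.n // 2
            if np.hypot(dx, dy) <= rad[i] + rad[j] + 1.0 + 1e-9:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


class TestMergeContacting:
    def test_two_contacting_spheres_merge_additively(self):
        ss = make_set(40, [(10, 10, 14.0), (10, 14, 14.0)])  # area 20 each, r~2.52
        merge_contacting(ss)
        assert len(ss) == 1
        assert ss.mass[0] == pytest.approx(28.0)
        assert ss.area_px[0] == 40

    def test_chain_of_three_merges_to_one(self):
        ss = make_set(40, [(10, 10, 14.0), (10, 14, 14.0), (10, 18, 14.0)])
        merge_contacting(ss)
        assert len(ss) == 1
        assert ss.mass[0] == pytest.approx(42.0)

    def test_distant_spheres_untouched(self):
        ss = make_set(40, [(5, 5, 0.7), (25, 25, 0.7)])
        merge_contacting(ss)
        assert len(ss) == 2

    def test_matches_union_find_oracle_on_random_sets(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ss = make_set(50)
            for _ in range(30):
                ss.add(rng.integers(0, 50), rng.integers(0, 50), rng.uniform(0.7, 20.0))
            expected = oracle_partition(ss)
            expected_masses = sorted(float(ss.mass[g].sum()) for g in expected)
            total = ss.total_mass()
            merge_contacting(ss)
            assert len(ss) == len(expected)
            assert sorted(ss.mass) == pytest.approx(expected_masses)
            assert ss.total_mass() == pytest.approx(total, rel=1e-12)

    def test_free_sphere_absorbed_by_attached_without_moving_it(self):
        ss = make_set(40, [(10, 10, 14.0, True), (10, 13, 7.0)])
        merge_contacting(ss)
        assert len(ss) == 1
        assert bool(ss.attached[0])
        assert (ss.x[0], ss.y[0]) == (10, 10)  # crosslinked sphere stays put
        assert ss.mass[0] == pytest.approx(21.0)

    def test_attached_spheres_never_merge_together(self):
        ss = make_set(40, [(10, 10, 14.0, True), (10, 13, 14.0, True)])
        merge_contacting(ss)
        assert len(ss) == 2


class TestSplitOversized:
    def test_area_43_splits_into_22_and_21(self, rng):
        ss = make_set(40, [(20, 20, 43 * SIGMA1)])
        total = ss.total_mass()
        split_oversized(ss, 42, rng)
        assert sorted(ss.area_px) == [21, 22]
        assert ss.total_mass() == pytest.approx(total, rel=1e-12)
        dx = abs(int(ss.x[0]) - int(ss.x[1])) % 40
        dy = abs(int(ss.y[0]) - int(ss.y[1])) % 40
        assert dx + dy == 1  # centers one cell apart

    def test_area_exactly_42_does_not_split(self, rng):
        ss = make_set(40, [(20, 20, 42 * SIGMA1)])
        split_oversized(ss, 42, rng)
        assert len(ss) == 1

    def test_mass_conserved_and_bounded_after_repeated_split(self, rng):
        ss = make_set(64, [(20, 20, 200 * SIGMA1), (40, 40, 97 * SIGMA1)])
        total = ss.total_mass()
        split_oversized(ss, 42, rng)
        assert ss.total_mass() == pytest.approx(total, rel=1e-9)
        assert (ss.area_px <= 42).all()

    def test_delta1_below_two_rejected(self, rng):
        with pytest.raises(ValueError):
            split_oversized(make_set(10), 1, rng)


class TestAttachSpheres:
    def test_area_above_delta2_adjacent_attaches(self):
        sc = scaffold_from_cells(40, [(10, 10)])
        ss = make_set(40, [(10, 13, 39 * SIGMA1)])  # r ~ 3.52, adjacency at dist 2
        assert attach_spheres(ss, sc, 38) == 1
        assert bool(ss.attached[0])

    def test_area_at_delta2_does_not_attach(self):
        sc = scaffold_from_cells(40, [(10, 10)])
        ss = make_set(40, [(10, 13, 38 * SIGMA1)])
        assert attach_spheres(ss, sc, 38) == 0
        assert not ss.attached[0]

    def test_far_sphere_never_attaches(self):
        sc = scaffold_from_cells(40, [(0, 0)])
        ss = make_set(40, [(20, 20, 50 * SIGMA1)])
        assert attach_spheres(ss, sc, 38) == 0

    def test_attachment_is_permanent_under_motion(self, rng):
        sc = build_scaffold("square", 20, 100.0, 2)
        ss = make_set(20, [(5, 5, 39 * SIGMA1, True)])
        for _ in range(10):
            move_spheres(ss, sc, rng)
        assert bool(ss.attached[0]) and (ss.x[0], ss.y[0]) == (5, 5)
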