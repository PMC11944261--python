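"""24-2 geometry: location census, adjacency, clusters, sectors."""

import numpy as np
import pytest

from vfstack.grid import (build_grid, feature_name_to_index, find_clusters,
                          grid_from_table, mirror_grid, neighbors,
                          packaged_grid_table, sector_of, write_grid_table)


def brute_force_components(flagged, coords, connectivity=8):
    """Independent union-find over coordinate-distance adjacency."""
    parent = {i: i for i in flagged}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    flagged = list(flagged)
    for a in flagged:
        for b in flagged:
            if a >= b:
                continue
            dx = abs(coords[a][0] - coords[b][0])
            dy = abs(coords[a][1] - coords[b][1])
            if connectivity == 8:
                adj = dx <= 6 and dy <= 6
            else:
                adj = dx + dy == 6
            if adj:
                ra, rb = find(a), find(b)
                parent[ra] = rb
    comps = {}
    for i in flagged:
        comps.setdefault(find(i), set()).add(i)
    return sorted((frozenset(c) for c in comps.values()),
                  key=lambda c: (-len(c), min(c)))


class TestGeometry:
    def test_location_census(self, grid):
        assert len(grid.locations) == 54
        assert len(grid.blind_spot_indices) == 2
        assert len(grid.test_indices) == 52

    def test_superior_hemifield_count(self, grid):
        sup = [l for l in grid.locations
               if l.hemifield == "superior" and not l.is_blind_spot]
        assert len(sup) == 26

    def test_lattice_offsets(self, grid):
        for l in grid.locations:
            assert l.y != 0 and l.x != 0
            assert l.x % 6 == 3 or l.x % 6 == 3 - 6
            assert abs(l.y) % 6 == 3

    def test_blind_spot_is_temporal(self, grid):
        for i in grid.blind_spot_indices:
            l = grid.location(i)
            assert (l.x, abs(l.y)) == (15, 3)

    def test_os_mirror_involution(self, grid):
        os_grid = build_grid("OS")
        mirrored = {(-l.x, l.y) for l in os_grid.locations}
        assert mirrored == {(l.x, l.y) for l in grid.locations}
        for a, b in zip(grid.locations, os_grid.locations):
            assert (a.index, a.y, a.sector, a.is_edge) == \
                (b.index, b.y, b.sector, b.is_edge)
            assert a.x == -b.x

    def test_unknown_laterality_rejected(self):
        with pytest.raises(ValueError, match="laterality"):
            build_grid("OU")


class TestAdjacency:
    @pytest.mark.parametrize("connectivity", [8, 4])
    def test_census_matches_distance_oracle(self, connectivity):
        g = build_grid("OD", connectivity=connectivity)
        coords = {l.index: (l.x, l.y) for l in g.locations if not l.is_blind_spot}
        for a in coords:
            expected = set()
            for b in coords:
                if a == b:
                    continue
                dx = abs(coords[a][0] - coords[b][0])
                dy = abs(coords[a][1] - coords[b][1])
                if (connectivity == 8 and dx <= 6 and dy <= 6) or \
                        (connectivity == 4 and dx + dy == 6):
                    expected.add(b)
            assert neighbors(g, a) == expected

    def test_symmetry_and_irreflexivity(self, grid):
        for a in grid.test_indices:
            assert a not in neighbors(grid, a)
            for b in neighbors(grid, a):
                assert a in neighbors(grid, b)

    def test_corner_degree_under_4_connectivity(self):
        g4 = build_grid("OD", connectivity=4)
        degrees = [len(neighbors(g4, i)) for i in g4.test_indices]
        assert min(degrees) <= 3

    def test_blind_spot_never_appears(self, grid):
        for a in grid.test_indices:
            assert not neighbors(grid, a) & set(grid.blind_spot_indices)
        with pytest.raises(ValueError):
            neighbors(grid, grid.blind_spot_indices[0])


class TestClusters:
    def test_empty_map(self, grid):
        flags = {i: False for i in grid.test_indices}
        assert find_clusters(flags, grid) == []

    def test_constructed_triple(self, grid):
        flags = {i: i in (21, 22, 23) for i in grid.test_indices}
        comps = find_clusters(flags, grid)
        assert comps == [frozenset({21, 22, 23})]

    def test_random_maps_match_union_find(self, grid):
        coords = {l.index: (l.x, l.y) for l in grid.locations}
        rng = np.random.default_rng(42)
        for _ in range(200):
            on = set(np.array(grid.test_indices)[
                rng.random(52) < rng.uniform(0.05, 0.6)])
            flags = {i: i in on for i in grid.test_indices}
            assert find_clusters(flags, grid) == brute_force_components(on, coords)

    def test_mirror_invariance(self, grid):
        os_grid = mirror_grid(grid)
        rng = np.random.default_rng(7)
        for _ in range(25):
            on = set(np.array(grid.test_indices)[rng.random(52) < 0.3])
            flags = {i: i in on for i in grid.test_indices}
            # indices are laterality-invariant, so the same flag map on the
            # mirrored grid is the x-mirrored field
            assert find_clusters(flags, grid) == find_clusters(flags, os_grid)

    def test_non_edge_and_hemifield_options(self, grid):
        edge = next(iter(grid.edge_indices & {11}))
        flags = {i: i in (edge, 12, 13) for i in grid.test_indices}
        with_edge = find_clusters(flags, grid)
        without_edge = find_clusters(flags, grid, non_edge_only=True)
        assert max(len(c) for c in with_edge) > max(
            (len(c) for c in without_edge), default=0)
        # a straddling pair splits when the meridian is severed
        flags = {i: i in (21, 30) for i in grid.test_indices}  # (9,3),(9,-3)
        assert len(find_clusters(flags, grid)) == 1
        assert len(find_clusters(flags, grid, same_hemifield=True)) == 2


class TestSectors:
    def test_sectors_partition(self, grid):
        labels = [sector_of(grid, i) for i in grid.test_indices]
        assert len(labels) == 52
        assert set(labels) <= {"ST", "SN", "IT", "IN", "T", "N", "central"}

    def test_published_feature_names_map_to_expected_sectors(self, grid):
        assert sector_of(grid, feature_name_to_index("td11")) == "ST"
        assert sector_of(grid, feature_name_to_index("td34")) == "IN"

    def test_hemifield_sector_consistency(self, grid):
        for l in grid.locations:
            if l.is_blind_spot:
                continue
            if l.hemifield == "superior":
                assert l.sector not in ("IT", "IN")
            else:
                assert l.sector not in ("ST", "SN")

    def test_blind_spot_sector_rejected(self, grid):
        with pytest.raises(ValueError):
            sector_of(grid, 20)

    def test_out_of_frame_feature_names_rejected(self):
        for bad in ("pd56", "td20", "td0"):
            with pytest.raises(ValueError):
                feature_name_to_index(bad)


def test_packaged_table_matches_build(grid, tmp_path):
    df = packaged_grid_table()
    p = tmp_path / "grid.csv"
    write_grid_table(grid, p)
    import pandas as pd
    regenerated = pd.read_csv(p)
    pd.testing.assert_frame_equal(df, regenerated)
    loaded = grid_from_table(p)
    assert loaded.adjacency == grid.adjacency
    assert [l.sector for l in loaded.locations] == [l.sector for l in grid.locations]
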