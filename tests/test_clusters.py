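"""Island/cluster statistics: adjacency, connected components, histograms,
footprints, and lateral percolation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import flood_fill_clusters
from mtwedge import fixtures
from mtwedge.clusters import (
    adjacency_edges, cluster_histogram, find_clusters, footprint,
    is_laterally_percolating)
from mtwedge.lattice import LatticeConfiguration, sample_composition


def _grid(arr, **kw):
    arr = np.asarray(arr, np.uint8)
    return LatticeConfiguration(n_rows=arr.shape[0], n_pf=arr.shape[1],
                                composition=arr, tether_rows=0, **kw)


class TestAdjacency:
    def test_two_by_two_patch_bond_counts(self):
        cfg = LatticeConfiguration(n_rows=2, n_pf=2,
                                   composition=np.ones((2, 2), np.uint8),
                                   tether_rows=0, seam_pf_pair=(1, 0))
        edges = adjacency_edges(cfg, seam="none")
        lateral = [e for e in edges if e[2].startswith("lateral")]
        vertical = [e for e in edges if e[2] == "vertical"]
        assert len(lateral) == 4  # alpha-alpha and beta-beta per contact
        assert len(vertical) == 2

    def test_single_ring_wrap_convention(self):
        cfg = _grid(np.ones((1, 13)))
        edges = adjacency_edges(cfg, seam="wrap")
        contacts = {(a, b) for a, b, k in edges if k.startswith("lateral")}
        assert len(contacts) == 13  # circular

    def test_seam_partners_shifted_up(self):
        cfg = _grid(np.ones((10, 13)))
        edges = adjacency_edges(cfg, seam="shifted")
        seam = [(a, b) for a, b, k in edges if k.startswith("seam")
                and a == (5, 12)]
        assert sorted(b for _, b in seam) == [(6, 0), (7, 0)]


class TestFindClusters:
    def test_fully_uncompressed_single_cluster(self):
        cfg = _grid(np.ones((5, 13)))
        cs = find_clusters(cfg)
        assert len(cs.clusters) == 1
        assert cs.sizes.tolist() == [65]

    def test_isolated_dimer(self):
        grid = np.zeros((6, 13), np.uint8)
        grid[3, 7] = 1
        cs = find_clusters(_grid(grid))
        assert cs.sizes.tolist() == [1]
        assert cs.clusters[0] == [(3, 7)]

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.6])
    @pytest.mark.parametrize("seam", ["shifted", "wrap"])
    def test_matches_flood_fill_oracle(self, p, seam):
        for seed in range(20):
            cfg = sample_composition(20, p, seed=1000 * seed + int(100 * p))
            cs = find_clusters(cfg, seam=seam)
            assert [sorted(c) for c in cs.clusters] == \
                flood_fill_clusters(cfg, seam)

    @given(st.integers(0, 10 ** 6), st.floats(0.05, 0.9))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_partition_property(self, seed, p):
        cfg = sample_composition(12, p, seed=seed)
        cs = find_clusters(cfg)
        assert int(cs.sizes.sum()) == int(cfg.composition.sum())

    def test_seam_toggle_noop_on_seam_free_grid(self):
        grid = np.zeros((12, 13), np.uint8)
        grid[2:8, 2:7] = 1  # island away from the seam columns
        a = find_clusters(_grid(grid), seam="shifted")
        b = find_clusters(_grid(grid), seam="none")
        assert [sorted(c) for c in a.clusters] == [sorted(c) for c in b.clusters]

    def test_isolated_site_probability_in_bulk(self):
        """P(size-1 cluster at a site) -> p(1-p)^4 without seam effects."""
        p = 0.2
        n_rows = 400
        count = 0
        n_lat = 0
        for seed in range(12):
            cfg = sample_composition(n_rows, p, seed=seed)
            cs = find_clusters(cfg, seam="none")
            # interior, non-seam-column sites only
            for c in cs.clusters:
                if len(c) == 1:
                    r, k = c[0]
                    if 1 <= r < n_rows - 1 and 1 <= k < 12:
                        count += 1
        n_sites = 12 * (n_rows - 2) * 11
        expect = n_sites * p * (1 - p) ** 4
        sd = np.sqrt(expect)
        assert abs(count - expect) < 3 * sd


class TestHistogram:
    def test_average_count_per_five_um(self):
        # 20 lattices of 2.4 um holding 96 clusters of size 2 in total
        grid = np.zeros((555, 13), np.uint8)
        # place isolated vertical dominoes on even protofilaments
        sets = []
        rows = np.arange(3, 500, 105)
        for i in range(20):
            g = grid.copy()
            for j, r in enumerate(rows[:5 if i < 16 else 4]):
                g[r:r + 2, (2 * j + 1) % 12] = 1
            cfg = _grid(g)
            sets.append(find_clusters(cfg, seam="none"))
        total = sum(len(cs.clusters) for cs in sets)
        assert total == 16 * 5 + 4 * 4  # 96 dominoes
        hist = cluster_histogram(sets)
        assert hist.h == {2: pytest.approx(96 * 5 / 48.0)}
        assert hist.nh()[2] == pytest.approx(20.0)

    def test_empty_lattices(self):
        sets = [find_clusters(_grid(np.zeros((555, 13)))) for _ in range(3)]
        hist = cluster_histogram(sets)
        assert hist.h == {}

    def test_mass_balance(self):
        sets = []
        total_unc = 0
        for seed in range(5):
            cfg = sample_composition(200, 0.3, seed=seed)
            total_unc += int(cfg.composition.sum())
            sets.append(find_clusters(cfg))
        hist = cluster_histogram(sets)
        mass = sum(n * h for n, h in hist.h.items())
        assert mass == pytest.approx(total_unc * 5.0 / hist.total_um)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            cluster_histogram([])


class TestFootprint:
    def test_rectangular_island(self):
        members = [(r, k) for r in range(2, 8) for k in range(0, 11)]
        assert footprint(members) == (6, 11)

    def test_single_dimer(self):
        assert footprint([(0, 5)]) == (1, 1)

    def test_circular_arc_across_seam(self):
        assert footprint([(0, 12), (0, 0), (0, 1)]) == (1, 3)

    def test_21_dimer_island_fixture(self):
        cfg = fixtures.make_fixture("island_21dimer")
        cs = find_clusters(cfg)
        assert cs.sizes.tolist() == [21]
        assert footprint(cs.clusters[0]) == (6, 11)

    @given(st.lists(st.tuples(st.integers(0, 30), st.integers(0, 12)),
                    min_size=1, max_size=40, unique=True))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_circular_span_matches_rotation_oracle(self, members):
        _, width = footprint(members)
        pfs = {m[1] for m in members}
        best = 13
        for rot in range(13):
            shifted = sorted((k - rot) % 13 for k in pfs)
            best = min(best, shifted[-1] - shifted[0] + 1)
        assert width == best

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            footprint([])


class TestPercolation:
    def test_full_ring_row_percolates(self):
        assert is_laterally_percolating([(0, k) for k in range(13)])

    def test_narrow_cluster_does_not(self):
        assert not is_laterally_percolating([(r, 3) for r in range(30)])

    def test_percolation_frequency_increases_with_composition(self):
        def frac_percolating(p):
            hits = 0
            for seed in range(20):
                cfg = sample_composition(200, p, seed=seed)
                cs = find_clusters(cfg)
                if any(is_laterally_percolating(c) for c in cs.clusters):
                    hits += 1
            return hits / 20
        assert frac_percolating(0.6) > frac_percolating(0.3)
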