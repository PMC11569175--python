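"""Hex geometry, neighborhood enrichment and interface annotation rules,
checked against brute-force oracles."""

import networkx as nx
import numpy as np
import pytest

from scmregions.spatial_graph import (
    DISTANT,
    FOCAL_ANCHORED,
    FOCAL_SPORADIC,
    PROXIMAL,
    ParityError,
    SampleExcluded,
    annotate_interface,
    annotate_proximity,
    axial_coords,
    build_hex_graph,
    cohort_enrichment,
    hex_distance,
    neighborhood_enrichment,
)
from scmregions.synthetic_data import generate_hex_lattice


# ---------------------------------------------------------------------------
# brute-force oracles


def bfs_distances(coords, cutoff=None):
    """Shortest-path lengths on the 6-neighbor lattice graph (oracle)."""
    ax = axial_coords(coords)
    d1 = hex_distance(ax[:, None, :], ax[None, :, :]) == 1
    G = nx.Graph()
    G.add_nodes_from(range(len(coords)))
    G.add_edges_from(zip(*np.nonzero(d1)))
    return dict(nx.all_pairs_shortest_path_length(G, cutoff=cutoff))


def brute_proximity(labels, coords, focal, min_focal=10):
    """Direct restatement of the proximity rules, all pairs explicitly."""
    labels = np.asarray(labels)
    n = len(labels)
    ax = axial_coords(coords)
    D = hex_distance(ax[:, None, :], ax[None, :, :])
    focal_mask = labels == focal
    if focal_mask.sum() < min_focal:
        raise SampleExcluded("floor")
    anchored = np.array(
        [focal_mask[i] and any(focal_mask[j] for j in range(n) if D[i, j] == 1)
         for i in range(n)]
    )
    status = []
    for i in range(n):
        if focal_mask[i]:
            status.append(FOCAL_ANCHORED if anchored[i] else FOCAL_SPORADIC)
            continue
        prox = False
        for a in range(n):
            for b in range(a + 1, n):
                if (anchored[a] and anchored[b] and D[a, b] == 1
                        and D[i, a] <= 3 and D[i, b] <= 3):
                    prox = True
        status.append(PROXIMAL if prox else DISTANT)
    return np.array(status)


def brute_interface(labels, coords, f, g, min_spots=10):
    labels = np.asarray(labels)
    n = len(labels)
    ax = axial_coords(coords)
    D = hex_distance(ax[:, None, :], ax[None, :, :])

    def interacting(region, other):
        out = np.zeros(n, bool)
        for i in range(n):
            if labels[i] != region:
                continue
            anchored = any(labels[j] == region and D[i, j] == 1 for j in range(n))
            n_other = sum(1 for j in range(n) if labels[j] == other and D[i, j] <= 3)
            out[i] = anchored and n_other >= 2
        return out

    inter_f, inter_g = interacting(f, g), interacting(g, f)
    if inter_f.sum() < min_spots or inter_g.sum() < min_spots:
        raise SampleExcluded("floor")
    return inter_f, inter_g


# ---------------------------------------------------------------------------


class TestHexDistance:
    def test_adjacent_on_staggered_grid(self):
        d = hex_distance(axial_coords([[0, 0]])[0], axial_coords([[0, 2]])[0])
        assert d == 1

    def test_interior_ring_counts(self):
        coords = generate_hex_lattice(20, 20)
        g = build_hex_graph(coords, n_rings=3)
        center = int(np.argmin(np.abs(coords - coords.mean(0)).sum(1)))
        within = g.within(3)[center].indices
        assert len(within) == 36  # 6 + 12 + 18

    def test_matches_bfs_on_random_subsets(self):
        rng = np.random.default_rng(0)
        coords = generate_hex_lattice(12, 12)
        keep = np.sort(rng.choice(len(coords), size=90, replace=False))
        sub = coords[keep]
        ax = axial_coords(sub)
        D = hex_distance(ax[:, None, :], ax[None, :, :])
        # oracle BFS runs on the FULL lattice graph (hex distance is defined
        # by the lattice, not the subset)
        full = bfs_distances(coords, cutoff=5)
        for ii, i in enumerate(keep):
            for jj, j in enumerate(keep):
                if j in full[i] and full[i][j] <= 5:
                    assert D[ii, jj] == full[i][j]

    def test_parity_violation_named(self):
        with pytest.raises(ParityError, match="spot 1"):
            build_hex_graph([[0, 0], [0, 1]])

    def test_metric_properties(self):
        rng = np.random.default_rng(1)
        coords = generate_hex_lattice(10, 10)
        ax = axial_coords(coords)
        for _ in range(200):
            i, j, k = rng.integers(0, len(coords), 3)
            dij = hex_distance(ax[i], ax[j])
            assert dij == hex_distance(ax[j], ax[i])
            assert hex_distance(ax[i], ax[i]) == 0
            assert dij <= hex_distance(ax[i], ax[k]) + hex_distance(ax[k], ax[j])


class TestNeighborhoodEnrichment:
    def test_deterministic(self):
        coords = generate_hex_lattice(10, 10)
        g = build_hex_graph(coords)
        labels = np.random.default_rng(0).integers(1, 4, len(coords))
        z1 = neighborhood_enrichment(labels, g, n_perms=100, seed=5)
        z2 = neighborhood_enrichment(labels, g, n_perms=100, seed=5)
        assert np.array_equal(z1, z2)

    def test_two_blocks_sign_structure(self):
        coords = generate_hex_lattice(12, 12)
        g = build_hex_graph(coords)
        labels = np.where(coords[:, 0] < 6, 1, 2)
        z = neighborhood_enrichment(labels, g, n_perms=300, seed=0)
        assert z[0, 0] > 0 and z[1, 1] > 0
        assert z[0, 1] < 0 and z[1, 0] < 0

    def test_single_region_all_zero(self):
        coords = generate_hex_lattice(6, 6)
        g = build_hex_graph(coords)
        z = neighborhood_enrichment(np.ones(len(coords), int), g, n_perms=50, seed=0)
        assert np.allclose(z, 0.0)

    def test_missing_region_zeroed_and_cohort_mean(self):
        coords = generate_hex_lattice(8, 8)
        g = build_hex_graph(coords)
        labels = np.where(coords[:, 0] < 4, 1, 2)
        z = neighborhood_enrichment(labels, g, region_ids=[1, 2, 3], n_perms=100, seed=1)
        assert np.allclose(z[2, :], 0) and np.allclose(z[:, 2], 0)
        mean = cohort_enrichment([z, np.zeros_like(z)])
        assert np.allclose(mean, z / 2)


class TestProximity:
    def test_isolated_focal_spot_sporadic(self):
        coords = generate_hex_lattice(8, 8)
        g = build_hex_graph(coords)
        labels = np.full(len(coords), 2)
        labels[20] = 1  # a single lone focal spot
        status = annotate_proximity(labels, g, 1, min_focal_spots=1)
        assert status[20] == FOCAL_SPORADIC
        assert PROXIMAL not in status  # a lone spot creates no proximal band

    def test_domino_pair_oracle(self):
        coords = generate_hex_lattice(12, 12)
        g = build_hex_graph(coords)
        labels = np.full(len(coords), 2)
        # two adjacent focal spots near the middle
        center = int(np.argmin(np.abs(coords - coords.mean(0)).sum(1)))
        nbr = g.neighbors(center, 1)[0]
        labels[[center, nbr]] = 1
        status = annotate_proximity(labels, g, 1, min_focal_spots=2)
        oracle = brute_proximity(labels, coords, 1, min_focal=2)
        assert np.array_equal(status, oracle)
        # every non-focal spot within 3 of BOTH spots is proximal
        ax = axial_coords(coords)
        D = hex_distance(ax[:, None, :], ax[None, :, :])
        expected = (D[:, center] <= 3) & (D[:, nbr] <= 3) & (labels != 1)
        assert np.array_equal(status == PROXIMAL, expected)

    def test_focal_floor_nine_excluded_ten_kept(self):
        coords = generate_hex_lattice(10, 10)
        g = build_hex_graph(coords)
        labels = np.full(len(coords), 2)
        labels[:9] = 1
        with pytest.raises(SampleExcluded):
            annotate_proximity(labels, g, 1, min_focal_spots=10)
        labels[9] = 1
        status = annotate_proximity(labels, g, 1, min_focal_spots=10)
        assert len(status) == len(coords)

    def test_partition_of_non_focal_spots(self):
        rng = np.random.default_rng(4)
        coords = generate_hex_lattice(12, 12)
        g = build_hex_graph(coords)
        labels = rng.integers(1, 4, len(coords))
        status = annotate_proximity(labels, g, 1, min_focal_spots=1)
        non_focal = labels != 1
        assert (np.isin(status[non_focal], [PROXIMAL, DISTANT])).all()
        assert (np.isin(status[~non_focal], [FOCAL_ANCHORED, FOCAL_SPORADIC])).all()

    def test_random_labelings_match_bruteforce(self):
        rng = np.random.default_rng(7)
        coords = generate_hex_lattice(12, 12)
        g = build_hex_graph(coords)
        for _ in range(10):
            labels = rng.integers(1, 4, len(coords))
            status = annotate_proximity(labels, g, 1, min_focal_spots=1)
            oracle = brute_proximity(labels, coords, 1, min_focal=1)
            assert np.array_equal(status, oracle)

    def test_translation_and_rotation_invariance(self):
        rng = np.random.default_rng(9)
        coords = generate_hex_lattice(10, 10)
        labels = rng.integers(1, 3, len(coords))
        g = build_hex_graph(coords)
        base = annotate_proximity(labels, g, 1, min_focal_spots=1)
        # translation by a lattice vector
        shifted = coords + np.array([2, 4])
        g2 = build_hex_graph(shifted)
        assert np.array_equal(base, annotate_proximity(labels, g2, 1, min_focal_spots=1))
        # 60-degree rotation in axial space: (q, r) -> (-r, q + r)
        ax = axial_coords(coords)
        q, r = -ax[:, 1], ax[:, 0] + ax[:, 1]
        rotated = np.column_stack([r, 2 * q + r])  # back to staggered (row, col)
        g3 = build_hex_graph(rotated)
        assert np.array_equal(base, annotate_proximity(labels, g3, 1, min_focal_spots=1))


class TestInterface:
    def test_straight_border_bands(self):
        coords = generate_hex_lattice(12, 12)
        g = build_hex_graph(coords)
        labels = np.where(coords[:, 0] < 6, 1, 2)
        iface = annotate_interface(labels, g, 1, 2, min_spots=10)
        inter_f_oracle, inter_g_oracle = brute_interface(labels, coords, 1, 2)
        assert np.array_equal(iface.interacting_f, inter_f_oracle)
        assert np.array_equal(iface.interacting_g, inter_g_oracle)
        # bands are at most 3 rings deep from the border
        rows = coords[:, 0]
        assert rows[iface.interacting_f].min() >= 3
        assert rows[iface.interacting_g].max() <= 8

    def test_separated_regions_no_interface(self):
        coords = generate_hex_lattice(14, 14)
        g = build_hex_graph(coords)
        labels = np.full(len(coords), 3)
        labels[coords[:, 0] < 4] = 1
        labels[coords[:, 0] > 9] = 2  # > 3 rings of region 3 between
        with pytest.raises(SampleExcluded):
            annotate_interface(labels, g, 1, 2, min_spots=1)

    def test_spot_floor_ten_vs_nine(self):
        coords = generate_hex_lattice(12, 12)
        g = build_hex_graph(coords)
        labels = np.where(coords[:, 0] < 6, 1, 2)
        iface = annotate_interface(labels, g, 1, 2, min_spots=10)
        n_f = iface.n_f
        with pytest.raises(SampleExcluded):
            annotate_interface(labels, g, 1, 2, min_spots=n_f + 1)

    def test_random_labelings_match_bruteforce(self):
        rng = np.random.default_rng(13)
        coords = generate_hex_lattice(12, 12)
        g = build_hex_graph(coords)
        checked = 0
        for _ in range(10):
            labels = rng.integers(1, 4, len(coords))
            try:
                iface = annotate_interface(labels, g, 1, 2, min_spots=1)
            except SampleExcluded:
                continue
            inter_f, inter_g = brute_interface(labels, coords, 1, 2, min_spots=1)
            assert np.array_equal(iface.interacting_f, inter_f)
            assert np.array_equal(iface.interacting_g, inter_g)
            checked += 1
        assert checked >= 5
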