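"""Generator ground-truth guarantees: geometry, coherence, planted effects."""

import numpy as np
import pytest

from scmregions.spatial_graph import axial_coords, build_hex_graph, hex_distance
from scmregions.st_io import filter_sample
from scmregions.synthetic_data import (
    SimConfig,
    generate_abundance,
    generate_counts,
    generate_hex_lattice,
    generate_region_field,
    _build_gene_table,
    plant_lr_coexpression,
    region_state_profiles,
)


class TestLattice:
    def test_single_spot(self):
        coords = generate_hex_lattice(1, 1)
        assert coords.shape == (1, 2)
        g = build_hex_graph(coords, n_rings=1)
        assert len(g.neighbors(0)) == 0

    def test_parity_convention(self):
        coords = generate_hex_lattice(5, 7)
        assert ((coords[:, 0] + coords[:, 1]) % 2 == 0).all()

    def test_interior_ring_sizes(self):
        coords = generate_hex_lattice(20, 20)
        g = build_hex_graph(coords, n_rings=3)
        center = int(np.argmin(np.abs(coords - coords.mean(0)).sum(1)))
        assert len(g.neighbors(center, 1)) == 6
        assert len(g.neighbors(center, 2)) == 12
        assert len(g.neighbors(center, 3)) == 18

    def test_corner_neighbors_match_bfs_oracle(self):
        import networkx as nx

        coords = generate_hex_lattice(6, 6)
        g = build_hex_graph(coords, n_rings=3)
        # oracle: BFS on the ring-1 graph
        G = nx.Graph()
        G.add_nodes_from(range(len(coords)))
        ax = axial_coords(coords)
        d = hex_distance(ax[:, None, :], ax[None, :, :])
        G.add_edges_from(zip(*np.nonzero(d == 1)))
        sp_len = dict(nx.all_pairs_shortest_path_length(G, cutoff=3))
        corner = 0
        for ring in (1, 2, 3):
            oracle = {v for v, L in sp_len[corner].items() if L == ring}
            assert set(g.neighbors(corner, ring)) == oracle
        assert len(g.neighbors(corner, 1)) < 6


class TestRegionField:
    def test_single_region(self):
        coords = generate_hex_lattice(4, 4)
        labels = generate_region_field(coords, 1, seed=0)
        assert (labels == 1).all()

    def test_deterministic(self):
        coords = generate_hex_lattice(12, 12)
        a = generate_region_field(coords, 5, seed=42)
        b = generate_region_field(coords, 5, seed=42)
        assert np.array_equal(a, b)

    def test_too_many_regions_raises(self):
        with pytest.raises(ValueError):
            generate_region_field(generate_hex_lattice(2, 2), 5, seed=0)

    def test_spatial_coherence(self):
        # mean fraction of ring-1 neighbors sharing the spot's label
        coords = generate_hex_lattice(16, 16)
        graph = build_hex_graph(coords, n_rings=1)
        fracs = []
        for seed in range(10):
            labels = generate_region_field(coords, 8, seed=seed)
            assert set(labels) == set(range(1, 9))
            for i in range(len(coords)):
                nb = graph.neighbors(i, 1)
                if len(nb):
                    fracs.append(np.mean(labels[nb] == labels[i]))
        assert np.mean(fracs) >= 0.6


class TestAbundance:
    def test_noiseless_argmax_is_dominant_state(self):
        cfg = SimConfig(abundance_noise_sd=0.0, lattice_rows=8, lattice_cols=8)
        coords = generate_hex_lattice(8, 8)
        labels = generate_region_field(coords, cfg.k_true, seed=1)
        ab = generate_abundance(labels, cfg, np.random.default_rng(0))
        assert np.array_equal(np.argmax(ab, axis=1), labels - 1)

    def test_rows_positive(self, small_cfg, small_cohort):
        _, abundance, *_ = small_cohort
        assert (abundance.to_numpy().sum(axis=1) > 0).all()

    def test_default_noise_argmax_mostly_correct(self):
        cfg = SimConfig(lattice_rows=16, lattice_cols=16)
        coords = generate_hex_lattice(16, 16)
        labels = generate_region_field(coords, cfg.k_true, seed=5)
        ab = generate_abundance(labels, cfg, np.random.default_rng(5))
        frac = np.mean(np.argmax(ab, axis=1) == labels - 1)
        assert frac >= 0.95


class TestCounts:
    def test_deterministic(self):
        cfg = SimConfig(lattice_rows=8, lattice_cols=8, n_genes=200)
        coords = generate_hex_lattice(8, 8)
        labels = generate_region_field(coords, cfg.k_true, seed=2)
        gt = _build_gene_table(cfg)
        a = generate_counts(labels, "BPH", cfg, gt, np.random.default_rng(9))
        b = generate_counts(labels, "BPH", cfg, gt, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_marker_fold_change_recovered(self):
        # empirical in/out mean ratio of a marker gene ~ 2**log2fc within 10%
        cfg = SimConfig(lattice_rows=24, lattice_cols=24, n_genes=400, marker_log2fc=2.0)
        coords = generate_hex_lattice(24, 24)
        labels = generate_region_field(coords, cfg.k_true, seed=3)
        gt = _build_gene_table(cfg)
        counts = generate_counts(labels, "BPH", cfg, gt, np.random.default_rng(3))
        ratios = []
        for r, genes in gt.marker_genes.items():
            inside = labels == r
            if inside.sum() < 30 or (~inside).sum() < 30:
                continue
            m_in = counts[inside][:, genes].mean(axis=0)
            m_out = counts[~inside][:, genes].mean(axis=0)
            ratios.extend(m_in / np.maximum(m_out, 1e-12))
        assert np.median(ratios) == pytest.approx(2.0**2, rel=0.10)

    def test_ar_downshift_only_in_treated_categories(self):
        cfg = SimConfig(lattice_rows=16, lattice_cols=16, n_genes=300)
        coords = generate_hex_lattice(16, 16)
        labels = generate_region_field(coords, cfg.k_true, seed=4)
        gt = _build_gene_table(cfg)
        pre = generate_counts(labels, "TRNA", cfg, gt, np.random.default_rng(8))
        post = generate_counts(labels, "NEADT", cfg, gt, np.random.default_rng(8))
        ar = gt.gene_sets["AR-like"]
        club = gt.marker_genes[1]
        ratio_ar = post[:, ar].mean() / pre[:, ar].mean()
        ratio_club = post[:, club].mean() / pre[:, club].mean()
        assert ratio_ar == pytest.approx(0.5, rel=0.15)
        assert ratio_club == pytest.approx(1.0, rel=0.15)


class TestLRPlanting:
    @pytest.fixture()
    def setup(self):
        cfg = SimConfig(lattice_rows=16, lattice_cols=16, n_genes=300)
        coords = generate_hex_lattice(16, 16)
        labels = generate_region_field(coords, cfg.k_true, seed=6)
        gt = _build_gene_table(cfg)
        counts = generate_counts(labels, "BPH", cfg, gt, np.random.default_rng(6))
        graph = build_hex_graph(coords, n_rings=3)
        spec = {
            "ligand_idx": gt.lr_genes[0],
            "receptor_idx": gt.lr_genes[1],
            "source_region": 1,
            "target_region": 2,
        }
        return cfg, labels, counts, graph, spec

    def test_zero_effect_identity(self, setup):
        _, labels, counts, graph, spec = setup
        out = plant_lr_coexpression(counts, labels, graph, [spec], 0.0, np.random.default_rng(0))
        assert np.array_equal(out, counts)

    def test_receptor_elevated_only_near_source(self, setup):
        _, labels, counts, graph, spec = setup
        out = plant_lr_coexpression(counts, labels, graph, [spec], 20.0, np.random.default_rng(0))
        src = labels == spec["source_region"]
        near = np.asarray(graph.within(3).astype(float) @ src.astype(float)).ravel() > 0
        tgt_prox = (labels == 2) & near
        tgt_dist = (labels == 2) & ~near
        assert tgt_prox.sum() and tgt_dist.sum()
        rec = spec["receptor_idx"]
        assert out[tgt_prox, rec].mean() > out[tgt_dist, rec].mean()
        # distant target spots untouched
        assert np.array_equal(out[tgt_dist, rec], counts[tgt_dist, rec])

    def test_other_genes_untouched(self, setup):
        _, labels, counts, graph, spec = setup
        out = plant_lr_coexpression(counts, labels, graph, [spec], 20.0, np.random.default_rng(0))
        untouched = np.ones(counts.shape[1], bool)
        untouched[[spec["ligand_idx"], spec["receptor_idx"]]] = False
        assert np.array_equal(out[:, untouched], counts[:, untouched])

    def test_unknown_gene_raises(self, setup):
        _, labels, counts, graph, spec = setup
        bad = dict(spec, ligand_idx=counts.shape[1] + 5)
        with pytest.raises(ValueError):
            plant_lr_coexpression(counts, labels, graph, [bad], 1.0, np.random.default_rng(0))


class TestCohortContracts:
    def test_full_determinism(self, small_cfg):
        from scmregions.synthetic_data import generate_cohort

        c1, ab1, *_ = generate_cohort(small_cfg)
        c2, ab2, *_ = generate_cohort(small_cfg)
        for s1, s2 in zip(c1, c2):
            assert (s1.counts != s2.counts).nnz == 0
        assert np.array_equal(ab1.to_numpy(), ab2.to_numpy())

    def test_marker_lists_disjoint(self, small_cohort):
        truth = small_cohort[2]
        all_markers = [g for genes in truth.marker_genes.values() for g in genes]
        assert len(all_markers) == len(set(all_markers))

    def test_samples_pass_default_qc(self, small_cohort):
        cohort, *_ = small_cohort
        for s in cohort:
            f = filter_sample(s)
            assert f.n_spots == s.n_spots  # no spot lost at defaults

    def test_adding_sample_preserves_earlier_ones(self, small_cfg):
        from dataclasses import replace
        from scmregions.synthetic_data import generate_cohort

        bigger = replace(small_cfg, samples_per_category={"BPH": 1, "TRNA": 1, "NEADT": 2, "CRPC": 1})
        c1, *_ = generate_cohort(small_cfg)
        c2, *_ = generate_cohort(bigger)
        for s1 in c1:
            s2 = c2[s1.sample_id]
            assert (s1.counts != s2.counts).nnz == 0
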