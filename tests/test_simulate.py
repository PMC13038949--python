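"""Synthetic-data generators: determinism, contracts, and distributional laws."""

import numpy as np
import pytest
from scipy import stats

from ecophylo import molevol
from ecophylo.simulate import (SimConfig, TreeSimulationError,
                               sample_occurrences, simulate_codon_alignment,
                               simulate_landscape, simulate_trait,
                               simulate_tree, write_dataset)
from ecophylo.trees import Phylogeny, node_ages, write_newick

from .conftest import two_taxon_tree


class TestSimulateTree:
    def test_tip_count_and_ultrametricity(self):
        t = simulate_tree(SimConfig(seed=1, n_species=3))
        assert t.n_tips == 3
        assert t.n_nodes == 5
        ages = node_ages(t)
        np.testing.assert_allclose(ages[:3], 0.0)

    def test_determinism(self):
        cfg = SimConfig(seed=7, n_species=5)
        assert write_newick(simulate_tree(cfg)) == write_newick(simulate_tree(cfg))

    def test_distinct_seeds_differ(self):
        a = write_newick(simulate_tree(SimConfig(seed=1, n_species=8)))
        b = write_newick(simulate_tree(SimConfig(seed=2, n_species=8)))
        assert a != b

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(birth_rate=0.5, death_rate=0.5)

    def test_extinction_failure_reports_rates(self):
        cfg = SimConfig(seed=0, n_species=3, birth_rate=0.011, death_rate=0.01)
        with pytest.raises(TreeSimulationError, match="birth"):
            simulate_tree(cfg, max_attempts=1)

    def test_yule_root_age_matches_harmonic_expectation(self):
        """Mean root age of pure-birth trees equals sum_{k=2..n} 1/(k b)."""
        n = 50
        heights = [
            simulate_tree(SimConfig(seed=s, n_species=n, birth_rate=1.0,
                                    death_rate=0.0)).height
            for s in range(500)
        ]
        expected = sum(1.0 / k for k in range(2, n + 1))
        assert np.mean(heights) == pytest.approx(expected, rel=0.15)


class TestLandscape:
    def test_no_evolution_gives_identical_grids(self):
        cfg = SimConfig(seed=2, n_species=4, bm_rate_niche=0.0)
        t = simulate_tree(cfg)
        _, _, grids = simulate_landscape(t, cfg)
        ref = grids[t.tip_labels[0]]
        for sp in t.tip_labels[1:]:
            np.testing.assert_allclose(grids[sp], ref)

    def test_zero_divergence_tips_share_grid(self):
        # cherry with zero-length terminal branches = duplicated tip
        t = Phylogeny(parent=np.array([3, 3, 4, 4, -1]),
                      children=[[], [], [0, 1], [], [2, 3]],
                      edge_length=np.array([0.0, 0.0, 1.0, 1.0, 0.0]),
                      tip_labels=["A", "B", "C"])
        cfg = SimConfig(seed=5, n_species=3, bm_rate_niche=0.3)
        _, _, grids = simulate_landscape(t, cfg)
        np.testing.assert_allclose(grids["A"], grids["B"])

    def test_degenerate_breadth_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(niche_breadth=0.0)

    def test_grids_nonnegative_not_all_zero(self):
        cfg = SimConfig(seed=3, n_species=5)
        t = simulate_tree(cfg)
        _, _, grids = simulate_landscape(t, cfg)
        for g in grids.values():
            assert (g >= 0).all() and g.sum() > 0

    def test_cherry_optimum_distance_follows_bm_law(self):
        """Mean |mu_A - mu_B| for a cherry at divergence t is the half-normal
        mean sqrt(2 * (2 t rate) / pi), checked over replicate simulations."""
        t_div, rate = 0.8, 0.4
        tree = two_taxon_tree(2 * t_div)
        diffs = []
        for s in range(200):
            cfg = SimConfig(seed=s, n_species=3, bm_rate_niche=rate,
                            n_env_layers=5, grid_shape=(8, 8))
            _, params, _ = simulate_landscape(tree, cfg)
            diffs.extend(np.abs(params.optima[0] - params.optima[1]))
        expected = np.sqrt(2.0 * (2 * t_div * rate) / np.pi)
        assert np.mean(diffs) == pytest.approx(expected, rel=0.15)


class TestOccurrences:
    def test_single_nonzero_cell_forces_all_points(self):
        grid = np.zeros((4, 4))
        grid[2, 3] = 5.0
        occ = sample_occurrences(grid, 20, seed=1)
        assert occ.cells == [(2, 3)] * 20

    def test_n_zero_gives_empty_set(self):
        occ = sample_occurrences(np.ones((3, 3)), 0, seed=1)
        assert occ.cells == []

    def test_all_zero_grid_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            sample_occurrences(np.zeros((3, 3)), 5, seed=1)

    def test_uniform_grid_counts_multinomial(self):
        grid = np.ones((5, 5))
        occ = sample_occurrences(grid, 10_000, seed=11)
        counts = np.zeros(25)
        for r, c in occ.cells:
            counts[5 * r + c] += 1
        chi2 = ((counts - 400.0) ** 2 / 400.0).sum()
        p = stats.chi2.sf(chi2, df=24)
        assert p > 0.001

    def test_determinism(self):
        grid = np.random.default_rng(0).random((6, 6))
        a = sample_occurrences(grid, 30, seed=9)
        b = sample_occurrences(grid, 30, seed=9)
        assert a.cells == b.cells


class TestTraits:
    def test_zero_rate_discrete_inherits_root(self):
        cfg = SimConfig(seed=4, n_species=6, mk_rate=0.0)
        t = simulate_tree(cfg)
        vals = simulate_trait(t, "discrete", cfg, seed=2)
        assert len(set(vals)) == 1

    def test_zero_rate_continuous_is_constant(self):
        cfg = SimConfig(seed=4, n_species=6, bm_rate_trait=0.0)
        t = simulate_tree(cfg)
        vals = simulate_trait(t, "continuous", cfg, seed=2)
        np.testing.assert_allclose(vals, 0.0)

    def test_invalid_state_count_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(mk_states=1)

    def test_fast_evolution_reaches_stationary_mix(self):
        """With >= 20 expected changes per branch and k=2, tip states are
        close to 50/50 across replicates (uniform stationary distribution)."""
        tree = two_taxon_tree(2.0)
        cfg = SimConfig(seed=0, n_species=3, mk_states=2, mk_rate=20.0)
        vals = [simulate_trait(tree, "discrete", cfg, seed=s)
                for s in range(1000)]
        frac = np.mean(np.concatenate(vals))
        assert abs(frac - 0.5) < 0.05

    def test_branch_change_fraction_matches_mk_formula(self):
        """For k=2 the chance a branch of length t ends in a different state
        is (1 - exp(-2 q t)) / 2; checked within binomial error."""
        q, t_len, reps = 0.7, 0.9, 2000
        tree = two_taxon_tree(2 * t_len)
        cfg = SimConfig(seed=0, n_species=3, mk_states=2, mk_rate=q)
        changed = 0
        for s in range(reps):
            a, b = simulate_trait(tree, "discrete", cfg, seed=s)
            changed += int(a != b)
        # A and B are independent given the root; P(differ) for the 2-branch
        # path of total length 2*t_len:
        p_expected = 0.5 * (1 - np.exp(-2 * q * (2 * t_len)))
        se = np.sqrt(p_expected * (1 - p_expected) / reps)
        assert abs(changed / reps - p_expected) < 4 * se


class TestCodonAlignment:
    def test_zero_branch_lengths_copy_root(self):
        tree = two_taxon_tree(0.0)
        cfg = SimConfig(seed=6, n_species=3, n_codons=50)
        aln = simulate_codon_alignment(tree, cfg, seed=1)
        assert aln.records[0][1] == aln.records[1][1]

    def test_no_stop_codons_or_frameshifts(self):
        cfg = SimConfig(seed=8, n_species=6, n_codons=100, omega=1.0)
        t = simulate_tree(cfg)
        aln = simulate_codon_alignment(t, cfg, seed=3)
        for _, seq in aln.records:
            assert len(seq) == 300
            codons = {seq[i:i + 3] for i in range(0, 300, 3)}
            assert not codons & set(molevol.STOP_CODONS)

    def test_determinism(self):
        cfg = SimConfig(seed=8, n_species=4, n_codons=30)
        t = simulate_tree(cfg)
        a = simulate_codon_alignment(t, cfg, seed=5)
        b = simulate_codon_alignment(t, cfg, seed=5)
        assert a.records == b.records


def test_write_dataset_round_trips(tmp_path):
    cfg = SimConfig(seed=12, n_species=4, n_codons=40, grid_shape=(10, 10),
                    n_env_layers=3, n_occurrences=25)
    truth = write_dataset(tmp_path, cfg)
    assert (tmp_path / "tree.nwk").exists()
    assert len(list((tmp_path / "rasters").glob("*.csv"))) == 4
    assert set(truth["niche_optima"]) == {"sp1", "sp2", "sp3", "sp4"}
    from ecophylo.simulate import read_raster_csv
    g = read_raster_csv(tmp_path / "rasters" / "sp1.csv")
    assert g.shape == (10, 10)
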