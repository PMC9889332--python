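import numpy as np
import pytest

from divfacets.beta import sorensen_taxonomic
from divfacets.complementarity import species_complementarity
from divfacets.io import DataError, validate_dataset
from divfacets.simulate import (
    SimulationConfig,
    simulate_communities,
    simulate_dataset,
    simulate_grid,
    simulate_phylogeny,
    simulate_traits,
)


class TestPhylogenySim:
    def test_tip_count(self):
        phy = simulate_phylogeny(5, seed=0)
        assert phy.n_tips == 5
        assert np.all(phy.edge_lengths > 0)

    def test_determinism(self):
        a = simulate_phylogeny(12, birth_rate=2.0, seed=123)
        b = simulate_phylogeny(12, birth_rate=2.0, seed=123)
        assert a.to_newick() == b.to_newick()

    def test_too_few_tips(self):
        with pytest.raises(DataError):
            simulate_phylogeny(1)

    def test_total_length_matches_yule_expectation(self):
        # E[L] = sum_{k=2..n} k * E[Exp(k*rate)] = (n-1)/rate,
        # Var[L] = (n-1)/rate^2; check the 200-replicate mean within 3 SEM
        n, rate, reps = 40, 1.0, 200
        lengths = [simulate_phylogeny(n, rate, seed=s).total_length
                   for s in range(reps)]
        expected = (n - 1) / rate
        sem = np.sqrt((n - 1) / rate ** 2 / reps)
        assert abs(np.mean(lengths) - expected) < 3 * sem


class TestTraitSim:
    def test_zero_rate_continuous_constant(self):
        phy = simulate_phylogeny(6, seed=1)
        tt = simulate_traits(phy, [{"name": "x", "kind": "continuous", "rate": 0.0}],
                             seed=0)
        assert np.ptp(tt.data["x"].to_numpy()) == 0.0

    def test_zero_rate_categorical_constant(self):
        phy = simulate_phylogeny(6, seed=1)
        tt = simulate_traits(phy, [{"name": "c", "kind": "categorical",
                                    "states": 4, "rate": 0.0}], seed=0)
        assert tt.data["c"].nunique() == 1

    def test_determinism(self):
        phy = simulate_phylogeny(8, seed=2)
        schema = [{"name": "x", "kind": "continuous"},
                  {"name": "c", "kind": "categorical"}]
        a = simulate_traits(phy, schema, seed=9)
        b = simulate_traits(phy, schema, seed=9)
        assert a.data.equals(b.data)

    def test_unknown_kind_errors(self):
        phy = simulate_phylogeny(4, seed=0)
        with pytest.raises(DataError):
            simulate_traits(phy, [{"name": "x", "kind": "fancy"}], seed=0)

    def test_brownian_tip_variance_scales_with_depth(self):
        # across replicate evolutions on a fixed tree, Var(tip value) must
        # approximate rate * (root-to-tip depth) for every tip
        phy = simulate_phylogeny(8, seed=33)
        rate = 2.0
        reps = 400
        vals = np.array([
            simulate_traits(phy, [{"name": "x", "kind": "continuous",
                                   "rate": rate}], seed=s).data["x"].to_numpy()
            for s in range(reps)
        ])
        depths = np.array([phy.edge_lengths[list(phy.tip_paths[t])].sum()
                           for t in phy.tip_labels])
        observed = vals.var(axis=0, ddof=1)
        expected = rate * depths
        # sampling error of a variance over n reps ~ sqrt(2/(n-1)) * var
        tol = 4 * np.sqrt(2 / (reps - 1)) * expected
        assert np.all(np.abs(observed - expected) < tol)

    def test_ordinal_integer_codes(self):
        phy = simulate_phylogeny(10, seed=3)
        tt = simulate_traits(phy, [{"name": "o", "kind": "ordinal", "levels": 3}],
                             seed=0)
        codes = tt.data["o"].to_numpy()
        assert set(np.unique(codes)) <= {0.0, 1.0, 2.0}


class TestCommunitySim:
    def test_full_homogenization_identical_farmland_rows(self):
        cfg = SimulationConfig(homogenization_h=1.0, seed=4)
        phy = simulate_phylogeny(cfg.n_tips, seed=4)
        cm = simulate_communities(cfg, phy)
        farm_rows = cm.incidence[[cm.site_index(s)
                                  for s in cm.sites_by_habitat("farmland")]]
        assert np.all(farm_rows == farm_rows[0])
        for a in cm.sites_by_habitat("farmland")[:3]:
            for b in cm.sites_by_habitat("farmland")[:3]:
                if a != b:
                    assert sorensen_taxonomic(
                        cm.species_at(a), cm.species_at(b)) == 0.0

    def test_zero_natural_occupancy_flagged(self):
        cfg = SimulationConfig(occupancy_natural=0.0, seed=4)
        phy = simulate_phylogeny(cfg.n_tips, seed=4)
        with pytest.warns(UserWarning, match="natural sites are empty"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("always")
                cm = simulate_communities(cfg, phy)
        rep = validate_dataset(cm)
        assert any("zero species" in w for w in rep.warnings)

    def test_farmland_alpha_exceeds_natural_alpha(self):
        wins = 0
        for seed in range(100):
            cfg = SimulationConfig(seed=seed)
            phy = simulate_phylogeny(cfg.n_tips, seed=seed)
            cm = simulate_communities(cfg, phy)
            per_site = cm.incidence.sum(axis=1)
            is_farm = np.array([h == "farmland" for h in cm.habitat])
            if per_site[is_farm].mean() > per_site[~is_farm].mean():
                wins += 1
        assert wins >= 95

    def test_homogenization_monotonically_lowers_farmland_beta(self):
        means = []
        for h in (0.0, 0.5, 1.0):
            vals = []
            for seed in range(25):
                cfg = SimulationConfig(homogenization_h=h, seed=seed)
                phy = simulate_phylogeny(cfg.n_tips, seed=seed)
                cm = simulate_communities(cfg, phy)
                farm = cm.sites_by_habitat("farmland")
                for i in range(0, len(farm) - 1, 2):
                    v = sorensen_taxonomic(cm.species_at(farm[i]),
                                           cm.species_at(farm[i + 1]))
                    if np.isfinite(v):
                        vals.append(v)
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_pool_overflow_errors(self):
        cfg = SimulationConfig(n_species_grid_extra=0, seed=0)
        phy = simulate_phylogeny(10, seed=0)  # far fewer tips than pools need
        with pytest.raises(DataError, match="exceed"):
            simulate_communities(cfg, phy)


class TestGridSim:
    def test_uniform_full_ranges_force_equal_comp(self):
        cfg = SimulationConfig(
            n_cells=10, hotspot_cells=[], hotspot_endemic_fraction=0.0,
            range_size_distribution={"kind": "fixed", "size": 10}, seed=0)
        phy = simulate_phylogeny(12, seed=0)
        grid = simulate_grid(cfg, phy)
        comp = species_complementarity(grid)["comp_s"]
        np.testing.assert_allclose(comp, 1 / 10)

    def test_single_cell_endemics_force_comp_one(self):
        cfg = SimulationConfig(
            n_cells=10, hotspot_cells=[], hotspot_endemic_fraction=0.0,
            range_size_distribution={"kind": "fixed", "size": 1}, seed=0)
        phy = simulate_phylogeny(12, seed=0)
        grid = simulate_grid(cfg, phy)
        comp = species_complementarity(grid)["comp_s"].dropna()
        np.testing.assert_allclose(comp, 1.0)

    def test_oversized_range_clipped_with_warning(self):
        import warnings
        cfg = SimulationConfig(
            n_cells=5, hotspot_cells=[], hotspot_endemic_fraction=0.0,
            range_size_distribution={"kind": "fixed", "size": 50}, seed=0)
        phy = simulate_phylogeny(6, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("always")
            with pytest.warns(UserWarning, match="clipped"):
                grid = simulate_grid(cfg, phy)
        assert np.all(grid.incidence == 1)

    def test_hotspot_cells_have_higher_complementarity(self):
        wins = 0
        for seed in range(100):
            cfg = SimulationConfig(n_cells=30, hotspot_cells=[14, 15],
                                   hotspot_endemic_fraction=0.25, seed=seed)
            phy = simulate_phylogeny(40, seed=seed)
            grid = simulate_grid(cfg, phy)
            comp = species_complementarity(grid)["comp_s"].to_numpy()
            hot = comp[[14, 15]]
            cold = np.delete(comp, [14, 15])
            if np.nanmean(hot) > np.nanmean(cold):
                wins += 1
        assert wins >= 95

    def test_determinism(self):
        cfg = SimulationConfig(seed=11)
        phy = simulate_phylogeny(cfg.n_tips, seed=11)
        a = simulate_grid(cfg, phy)
        b = simulate_grid(cfg, phy)
        assert np.array_equal(a.incidence, b.incidence)


class TestFullDataset:
    def test_passes_validation(self, small_dataset):
        rep = validate_dataset(small_dataset.cm, small_dataset.tt, small_dataset.phy)
        assert rep.ok

    def test_bit_identical_under_same_seed(self):
        cfg = dict(n_species_forest=6, n_species_savannah=5, n_species_farmland=5,
                   n_sites={"forest": 3, "savannah": 3, "farmland": 4},
                   n_species_grid_extra=4, n_cells=10, seed=7)
        a = simulate_dataset(SimulationConfig(**cfg))
        b = simulate_dataset(SimulationConfig(**cfg))
        assert a.phy.to_newick() == b.phy.to_newick()
        assert a.tt.data.equals(b.tt.data)
        assert np.array_equal(a.cm.incidence, b.cm.incidence)
        assert np.array_equal(a.grid.incidence, b.grid.incidence)

    def test_truth_records_config_and_pools(self, small_dataset):
        truth = small_dataset.truth
        assert truth["config"]["seed"] == 42
        assert set(truth["observed_pools"]) == {"forest", "savannah", "farmland"}
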