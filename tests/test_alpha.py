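import itertools

import dendropy
import numpy as np
import pytest

from divfacets.alpha import (
    assemblage_diversity,
    faith_pd,
    functional_richness,
    graft_species,
    richness,
)
from divfacets.io import CommunityMatrix, DataError, Phylogeny
from divfacets.simulate import simulate_phylogeny
from divfacets.traitspace import TraitSpace


def brute_force_pd(newick: str, species: set[str], include_root: bool = True) -> float:
    """Independent oracle: per-edge inclusion by descendant-tip membership.

    An edge counts iff at least one selected species descends from it and,
    for the MRCA variant, not all selected species descend from it.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    total = 0.0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.edge.length is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        hit = below & species
        if not hit:
            continue
        if not include_root and hit == species:
            continue  # edge above (or at) the MRCA of the full selection
        total += node.edge.length
    return total


class TestRichness:
    def test_count(self, toy_community):
        assert richness(toy_community, "s1") == 2

    def test_empty_row(self):
        cm = CommunityMatrix(["s1"], ["A", "B"], np.array([[0, 0]]), ["forest"])
        assert richness(cm, "s1") == 0

    def test_unknown_site(self, toy_community):
        with pytest.raises(KeyError):
            richness(toy_community, "nope")

    def test_pooled_union(self, toy_community):
        rec = assemblage_diversity(toy_community, None, None, ["s1", "s2"])
        assert rec.richness == 3  # {A,B} | {A,C}


class TestFunctionalRichness:
    @staticmethod
    def _space(points):
        points = np.asarray(points, float)
        return TraitSpace(labels=[f"s{i}" for i in range(len(points))],
                          coords=points, stress=0.0, k=points.shape[1])

    def test_unit_tetrahedron(self):
        ts = self._space([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        assert functional_richness(ts, ts.labels) == pytest.approx(1 / 6)

    def test_unit_cube(self):
        ts = self._space(list(itertools.product([0, 1], repeat=3)))
        assert functional_richness(ts, ts.labels) == pytest.approx(1.0)

    def test_below_dimension_is_nan(self):
        ts = self._space([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        assert np.isnan(functional_richness(ts, ts.labels[:3]))

    def test_affinely_degenerate_is_nan(self):
        ts = self._space([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 0, 0]])
        assert np.isnan(functional_richness(ts, ts.labels))

    def test_unknown_species_errors(self):
        ts = self._space([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        with pytest.raises(KeyError):
            functional_richness(ts, ["nope"])

    def test_monte_carlo_volume_oracle(self):
        rng = np.random.default_rng(11)
        from scipy.spatial import ConvexHull
        for _ in range(3):
            pts = rng.random((10, 3))
            ts = self._space(pts)
            vol = functional_richness(ts, ts.labels)
            hull = ConvexHull(pts)
            a, b = hull.equations[:, :-1], hull.equations[:, -1]
            lo, hi = pts.min(0), pts.max(0)
            samples = rng.uniform(lo, hi, size=(400_000, 3))
            inside = np.all(samples @ a.T + b <= 1e-12, axis=1)
            mc = inside.mean() * np.prod(hi - lo)
            assert vol == pytest.approx(mc, rel=0.01)


class TestFaithPD:
    def test_hand_cases(self, toy_tree):
        assert faith_pd(toy_tree, {"A", "B"}) == pytest.approx(3.0)
        assert faith_pd(toy_tree, {"A"}) == pytest.approx(2.0)
        assert faith_pd(toy_tree, {"A", "B", "C"}) == pytest.approx(5.0)

    def test_mrca_variant(self, toy_tree):
        assert faith_pd(toy_tree, {"A", "B"}, include_root=False) == pytest.approx(2.0)
        assert faith_pd(toy_tree, {"A"}, include_root=False) == 0.0
        assert faith_pd(toy_tree, {"A", "C"}, include_root=False) == pytest.approx(4.0)

    def test_empty_set_is_zero_with_warning(self, toy_tree):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("always")
            with pytest.warns(UserWarning):
                assert faith_pd(toy_tree, []) == 0.0

    def test_unknown_tip_errors(self, toy_tree):
        with pytest.raises(KeyError):
            faith_pd(toy_tree, {"Z"})

    def test_full_tip_set_equals_total_length(self):
        phy = simulate_phylogeny(20, seed=5)
        assert faith_pd(phy, phy.tip_labels) == pytest.approx(phy.total_length)

    @pytest.mark.parametrize("include_root", [True, False])
    def test_brute_force_oracle_random_trees(self, include_root):
        rng = np.random.default_rng(99)
        for rep in range(20):
            phy = simulate_phylogeny(12, seed=1000 + rep)
            newick = phy.to_newick()
            tips = phy.tip_labels
            for _ in range(10):
                k = int(rng.integers(1, 12))
                subset = set(rng.choice(tips, size=k, replace=False))
                got = faith_pd(phy, subset, include_root=include_root)
                want = brute_force_pd(newick, subset, include_root=include_root)
                assert got == pytest.approx(want, abs=1e-12)

    def test_monotone_under_superset(self):
        phy = simulate_phylogeny(15, seed=8)
        rng = np.random.default_rng(0)
        tips = list(phy.tip_labels)
        rng.shuffle(tips)
        prev = 0.0
        for k in range(1, 16):
            cur = faith_pd(phy, tips[:k])
            assert cur >= prev - 1e-12
            prev = cur


class TestGraft:
    def test_hand_construction(self):
        phy = Phylogeny.from_newick("(A:2,B:2);")
        out = graft_species(phy, "C", "A", fraction=0.5)
        assert out.total_length == pytest.approx(5.0)
        assert faith_pd(out, {"A"}) == pytest.approx(2.0)
        assert faith_pd(out, {"C"}) == pytest.approx(2.0)
        assert faith_pd(out, {"A", "C"}) == pytest.approx(3.0)
        # original untouched
        assert phy.total_length == pytest.approx(4.0)

    def test_fraction_zero_pendant(self):
        phy = Phylogeny.from_newick("(A:2,B:2);")
        out = graft_species(phy, "C", "A", fraction=0.0)
        assert out.total_length == pytest.approx(4.0)
        assert faith_pd(out, {"C"}) == pytest.approx(faith_pd(out, {"A"}))

    def test_missing_sister_errors(self, toy_tree):
        with pytest.raises(DataError, match="not found"):
            graft_species(toy_tree, "D", "Z")

    def test_name_collision_errors(self, toy_tree):
        with pytest.raises(DataError, match="already present"):
            graft_species(toy_tree, "A", "B")

    def test_length_increase_is_fraction_of_sister(self):
        phy = simulate_phylogeny(10, seed=3)
        sister = phy.tip_labels[4]
        pendant = phy.edge_lengths[
            [e for e in phy.tip_paths[sister]
             if not any(e in phy.tip_paths[t] for t in phy.tip_labels if t != sister)]
        ].sum()
        out = graft_species(phy, "newbie", sister, fraction=0.25)
        assert out.total_length - phy.total_length == pytest.approx(0.25 * pendant)


class TestAssemblageDiversity:
    def test_single_site_equals_per_site_metrics(self, toy_community, toy_tree):
        rec = assemblage_diversity(toy_community, None, toy_tree, ["s1"])
        assert rec.richness == richness(toy_community, "s1")
        assert rec.pd == pytest.approx(faith_pd(toy_tree, {"A", "B"}))

    def test_pd_subadditive_over_disjoint_sites(self, toy_tree):
        cm = CommunityMatrix(["s1", "s2"], ["A", "B", "C"],
                             np.array([[1, 1, 0], [0, 0, 1]]),
                             ["forest", "forest"])
        both = assemblage_diversity(cm, None, toy_tree, ["s1", "s2"])
        solo = [assemblage_diversity(cm, None, toy_tree, [s]) for s in ("s1", "s2")]
        assert both.richness == 3
        assert both.pd <= solo[0].pd + solo[1].pd + 1e-12

    def test_empty_site_list_errors(self, toy_community):
        with pytest.raises(DataError):
            assemblage_diversity(toy_community, None, None, [])

    def test_pooled_fric_at_least_max_per_site(self, small_dataset):
        from divfacets.pipeline import homogenization_signature  # noqa: F401
        from divfacets.traitspace import gower_distance, nmds_embed
        ds = small_dataset
        from divfacets.io import TraitTable
        tt = TraitTable(ds.tt.data.loc[ds.cm.species_ids], ds.tt.kinds, ds.tt.units)
        ts = nmds_embed(gower_distance(tt), k=3, n_starts=2, max_iter=60, seed=0)
        sites = ds.cm.site_ids[:4]
        pooled = assemblage_diversity(ds.cm, ts, ds.phy, sites)
        per_site = [assemblage_diversity(ds.cm, ts, ds.phy, [s]) for s in sites]
        defined = [r.fric for r in per_site if np.isfinite(r.fric)]
        if np.isfinite(pooled.fric) and defined:
            assert pooled.fric >= max(defined) - 1e-12
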