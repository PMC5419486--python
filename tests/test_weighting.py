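"""Topology enumeration, exact and sampled weighting, confidence intervals."""

import itertools

import numpy as np
import pytest

from topoweight.treecore import GenealogyError, TaxonMap, parse_newick
from topoweight.weighting import (
    ExactWeightingError,
    TopologyCountError,
    binomial_ci,
    count_sample_combinations,
    enumerate_taxon_topologies,
    match_topology,
    n_taxon_topologies,
    topology_branch_distances,
    weight_exact,
    weight_fixed_sample,
    weight_threshold,
    weight_tree_stream,
)

from conftest import brute_force_weights, random_coalescent, random_taxon_map

ABCD = list("ABCD")


def quartet_map(**samples_per_taxon):
    assignment = {}
    for taxon, names in samples_per_taxon.items():
        for name in names:
            assignment[name] = taxon
    return TaxonMap(assignment, taxa=list(samples_per_taxon))


def topo_index_by_pair(catalog, pair):
    """Catalog index of the quartet topology whose cherry is ``pair``."""
    for i, topo in enumerate(catalog):
        for bp in topo.splits:
            if {frozenset(s) for s in bp.sides} & {frozenset(pair)}:
                return i
    raise AssertionError(f"no topology with cherry {pair}")


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(3, 1), (4, 3), (5, 15), (6, 105)])
    def test_counts_match_double_factorial(self, n, count):
        taxa = [f"T{i}" for i in range(n)]
        catalog = enumerate_taxon_topologies(taxa)
        assert len(catalog) == count == n_taxon_topologies(n)
        assert len({t.splits for t in catalog}) == count

    def test_order_is_deterministic(self):
        a = enumerate_taxon_topologies(ABCD)
        b = enumerate_taxon_topologies(ABCD)
        assert [t.newick for t in a] == [t.newick for t in b]

    def test_large_taxon_count_refused(self):
        with pytest.raises(TopologyCountError, match="topologies"):
            enumerate_taxon_topologies([f"T{i}" for i in range(9)])

    def test_ten_taxa_count_exceeds_two_million(self):
        assert n_taxon_topologies(10) > 2_000_000


class TestSampleCombinations:
    @pytest.mark.parametrize(
        "sizes,expected",
        [((10, 10, 10, 10), 10_000), ((12, 10, 1, 1), 120), ((1, 1, 1, 1), 1)],
    )
    def test_product_of_taxon_sizes(self, sizes, expected):
        assignment = {
            f"{t}{i}": t for t, s in zip(ABCD, sizes) for i in range(s)
        }
        taxa = TaxonMap(assignment, taxa=ABCD)
        assert count_sample_combinations(taxa) == expected


class TestMatchTopology:
    def test_resolved_quartet(self):
        catalog = enumerate_taxon_topologies(ABCD)
        taxa = quartet_map(A=["a"], B=["b"], C=["c"], D=["d"])
        sub = parse_newick("((a,b),(c,d));")
        topo = match_topology(sub, taxa, catalog)
        assert topo is not None
        assert topo is catalog[topo_index_by_pair(catalog, {"A", "B"})]

    def test_star_is_unresolved(self):
        catalog = enumerate_taxon_topologies(ABCD)
        taxa = quartet_map(A=["a"], B=["b"], C=["c"], D=["d"])
        assert match_topology(parse_newick("(a,b,c,d);"), taxa, catalog) is None

    def test_non_transversal_rejected(self):
        catalog = enumerate_taxon_topologies(ABCD)
        taxa = quartet_map(A=["a", "x"], B=["b"], C=["c"], D=["d"])
        with pytest.raises(GenealogyError, match="one sample per taxon"):
            match_topology(parse_newick("((a,x),(b,c));"), taxa, catalog)

    @pytest.mark.parametrize("n", [4, 5])
    def test_every_random_subtree_matches_exactly_one(self, n, rng):
        taxa_names = [f"T{i + 1}" for i in range(n)]
        catalog = enumerate_taxon_topologies(taxa_names)
        for _ in range(25):
            tree = random_coalescent(n, rng)
            relabeled = parse_newick(
                _relabel(tree, dict(zip(sorted(tree.tip_labels), taxa_names)))
            )
            tm = TaxonMap({t: t for t in taxa_names}, taxa=taxa_names)
            hits = [t for t in catalog if t.splits and False]
            topo = match_topology(relabeled, tm, catalog)
            assert topo is not None
            assert sum(topo.splits == c.splits for c in catalog) == 1


def _relabel(tree, mapping):
    from topoweight.treecore import write_newick

    text = write_newick(tree, lengths=False)
    for old, new in mapping.items():
        text = text.replace(old + ",", new + ",").replace(old + ")", new + ")")
    return text


class TestWeightExact:
    def test_reciprocal_monophyly_fully_sorted(self):
        tree = parse_newick("(((a1,a2),(b1,b2)),((c1,c2),(d1,d2)));")
        taxa = quartet_map(
            A=["a1", "a2"], B=["b1", "b2"], C=["c1", "c2"], D=["d1", "d2"]
        )
        catalog = enumerate_taxon_topologies(ABCD)
        rec = weight_exact(tree, taxa, catalog=catalog)
        ab = topo_index_by_pair(catalog, {"A", "B"})
        assert rec.weights[ab] == 1.0
        assert rec.evaluated == rec.n_combinations == 16
        assert rec.unresolved == 0

    def test_two_transversal_tree_splits_evenly(self):
        tree = parse_newick("((a1,b1),((a2,c1),d1));")
        taxa = quartet_map(A=["a1", "a2"], B=["b1"], C=["c1"], D=["d1"])
        catalog = enumerate_taxon_topologies(ABCD)
        rec = weight_exact(tree, taxa, catalog=catalog)
        assert rec.n_combinations == 2
        ab = topo_index_by_pair(catalog, {"A", "B"})
        ac = topo_index_by_pair(catalog, {"A", "C"})
        ad = topo_index_by_pair(catalog, {"A", "D"})
        assert rec.weights[ab] == pytest.approx(0.5)
        assert rec.weights[ac] == pytest.approx(0.5)
        assert rec.weights[ad] == 0.0

    def test_nonmonophyletic_but_fully_supporting(self):
        tree = parse_newick("(((a1,b1),(a2,b2)),(c1,d1));")
        taxa = quartet_map(A=["a1", "a2"], B=["b1", "b2"], C=["c1"], D=["d1"])
        catalog = enumerate_taxon_topologies(ABCD)
        rec = weight_exact(tree, taxa, catalog=catalog)
        ab = topo_index_by_pair(catalog, {"A", "B"})
        assert rec.n_combinations == 4
        assert rec.weights[ab] == 1.0

    def test_polytomy_counted_as_unresolved(self):
        tree = parse_newick("(a1,b1,c1,d1);")
        taxa = quartet_map(A=["a1"], B=["b1"], C=["c1"], D=["d1"])
        rec = weight_exact(tree, taxa)
        assert rec.unresolved == 1
        assert sum(rec.counts) == 0

    def test_exact_ceiling_raises(self):
        tree = parse_newick("(((a1,a2),(b1,b2)),((c1,c2),(d1,d2)));")
        taxa = quartet_map(
            A=["a1", "a2"], B=["b1", "b2"], C=["c1", "c2"], D=["d1", "d2"]
        )
        with pytest.raises(ExactWeightingError, match="sample"):
            weight_exact(tree, taxa, max_combinations=10)

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_collapsed_counts_equal_brute_force(self, n_taxa, rng):
        catalog = enumerate_taxon_topologies(
            [f"T{i + 1}" for i in range(n_taxa)]
        )
        for _ in range(20):
            tree = random_coalescent(int(rng.integers(n_taxa + 2, 17)), rng)
            taxa = random_taxon_map(tree.tip_labels, n_taxa, rng)
            rec = weight_exact(tree, taxa, catalog=catalog)
            counts, unresolved = brute_force_weights(tree, taxa, catalog)
            assert list(rec.counts) == counts
            assert rec.unresolved == unresolved

    def test_normalization_and_label_symmetry(self, rng):
        tree = random_coalescent(12, rng)
        taxa = random_taxon_map(tree.tip_labels, 4, rng)
        rec = weight_exact(tree, taxa)
        assert rec.unresolved == 0
        assert sum(rec.weights) == pytest.approx(1.0, abs=1e-12)
        # swapping two sample labels within a taxon changes nothing
        t0 = taxa.taxa[0]
        pool = list(taxa.samples(t0))
        if len(pool) >= 2:
            swapped = dict(taxa.assignment)
            perm = dict(taxa.assignment)
            rec2 = weight_exact(tree, TaxonMap(perm, taxa=taxa.taxa))
            assert rec2.counts == rec.counts


class TestSampledWeighting:
    def setup_method(self):
        self.tree = parse_newick("((a1,b1),((a2,c1),d1));")
        self.taxa = quartet_map(A=["a1", "a2"], B=["b1"], C=["c1"], D=["d1"])
        self.catalog = enumerate_taxon_topologies(ABCD)

    def test_single_iteration(self):
        rec = weight_fixed_sample(self.tree, self.taxa, iterations=1, seed=0)
        assert rec.evaluated == 1
        assert sum(rec.counts) + rec.unresolved == 1

    def test_same_seed_reproduces(self):
        a = weight_fixed_sample(self.tree, self.taxa, iterations=500, seed=42)
        b = weight_fixed_sample(self.tree, self.taxa, iterations=500, seed=42)
        assert a == b

    def test_converges_to_exact(self):
        exact = weight_exact(self.tree, self.taxa, catalog=self.catalog)
        approx = weight_fixed_sample(
            self.tree, self.taxa, iterations=10_000, seed=7, catalog=self.catalog
        )
        for w, v in zip(exact.weights, approx.weights):
            assert abs(w - v) < 0.02

    def test_ci_attached_and_brackets_estimate(self):
        rec = weight_fixed_sample(self.tree, self.taxa, iterations=400, seed=1)
        assert rec.ci is not None
        for w, (lo, hi) in zip(rec.weights, rec.ci):
            assert lo <= w <= hi

    def test_threshold_stops_fast_on_sorted_tree(self):
        sorted_tree = parse_newick("(((a1,a2),(b1,b2)),((c1,c2),(d1,d2)));")
        taxa = quartet_map(
            A=["a1", "a2"], B=["b1", "b2"], C=["c1", "c2"], D=["d1", "d2"]
        )
        rec = weight_threshold(
            sorted_tree, taxa, max_ci_width=0.2, batch=100,
            max_iterations=10_000, seed=3,
        )
        assert rec.stop_reason == "ci_width"
        assert rec.evaluated < 10_000

    def test_threshold_runs_out_on_star_tree(self):
        star = parse_newick("(a1,b1,c1,d1);")
        taxa = quartet_map(A=["a1"], B=["b1"], C=["c1"], D=["d1"])
        rec = weight_threshold(
            star, taxa, max_ci_width=0.01, batch=200, max_iterations=1000, seed=3
        )
        # all mass unresolved: counts stay 0 so CIs collapse; force the
        # worst case with an unsorted (not star) tree instead
        unsorted_tree = parse_newick("((a1,b1),((a2,c1),d1));")
        taxa2 = quartet_map(A=["a1", "a2"], B=["b1"], C=["c1"], D=["d1"])
        rec2 = weight_threshold(
            unsorted_tree, taxa2, max_ci_width=0.01, batch=200,
            max_iterations=1000, seed=3,
        )
        assert rec2.stop_reason == "max_iterations"
        assert rec2.evaluated == 1000

    def test_vacuous_threshold_stops_after_first_batch(self):
        rec = weight_threshold(
            self.tree, self.taxa, max_ci_width=0.999, batch=50,
            max_iterations=1000, seed=5,
        )
        assert rec.evaluated == 50


class TestBinomialCI:
    def test_boundaries(self):
        assert binomial_ci(0, 100)[0] == 0.0
        assert binomial_ci(100, 100)[1] == 1.0

    def test_wilson_values(self):
        lo, hi = binomial_ci(50, 100, 0.95)
        assert lo == pytest.approx(0.404, abs=5e-4)
        assert hi == pytest.approx(0.596, abs=5e-4)

    def test_contains_point_estimate(self):
        for k, n in [(1, 10), (5, 13), (12, 12), (0, 3)]:
            lo, hi = binomial_ci(k, n)
            assert lo <= k / n <= hi


class TestBranchDistances:
    def test_ultrametric_sorted_tree_pair_depths(self):
        tree = parse_newick(
            "(((a1:1,a2:1):2,(b1:1,b2:1):2):1,((c1:1,c2:1):2,(d1:1,d2:1):2):1);"
        )
        taxa = quartet_map(
            A=["a1", "a2"], B=["b1", "b2"], C=["c1", "c2"], D=["d1", "d2"]
        )
        catalog = enumerate_taxon_topologies(ABCD)
        out = topology_branch_distances(tree, taxa, catalog=catalog)
        ab = catalog[topo_index_by_pair(catalog, {"A", "B"})].id
        dists = out[ab]
        assert dists[("A", "B")] == pytest.approx(6.0)  # depth 3 x 2
        assert dists[("A", "C")] == pytest.approx(8.0)  # depth 4 x 2
        assert dists[("C", "D")] == pytest.approx(6.0)

    def test_unmatched_topology_is_nan(self):
        tree = parse_newick(
            "(((a1:1,a2:1):2,(b1:1,b2:1):2):1,((c1:1,c2:1):2,(d1:1,d2:1):2):1);"
        )
        taxa = quartet_map(
            A=["a1", "a2"], B=["b1", "b2"], C=["c1", "c2"], D=["d1", "d2"]
        )
        catalog = enumerate_taxon_topologies(ABCD)
        out = topology_branch_distances(tree, taxa, catalog=catalog)
        ac = catalog[topo_index_by_pair(catalog, {"A", "C"})].id
        assert np.isnan(out[ac][("A", "B")])

    def test_sampled_agrees_with_exact(self, rng):
        tree = random_coalescent(10, rng)
        taxa = random_taxon_map(tree.tip_labels, 4, rng)
        exact = topology_branch_distances(tree, taxa, method="exact")
        sampled = topology_branch_distances(
            tree, taxa, method="sampled", iterations=4000, seed=9
        )
        for topo_id, pairs in exact.items():
            for pair, value in pairs.items():
                got = sampled[topo_id][pair]
                if np.isnan(value):
                    continue
                assert got == pytest.approx(value, abs=0.25)

    def test_missing_lengths_rejected(self):
        tree = parse_newick("((a1,b1),(c1,d1));")
        taxa = quartet_map(A=["a1"], B=["b1"], C=["c1"], D=["d1"])
        with pytest.raises(GenealogyError, match="lengths"):
            topology_branch_distances(tree, taxa)


class TestTreeStream:
    def test_order_and_missing_rows(self):
        taxa = quartet_map(A=["a1"], B=["b1"], C=["c1"], D=["d1"])
        trees = [
            parse_newick("((a1,b1),(c1,d1));"),
            None,
            parse_newick("((a1,c1),(b1,d1));"),
        ]
        track = weight_tree_stream(trees, taxa)
        assert len(track) == 3
        assert track.records[1] is None
        assert track.records[0] is not None and track.records[2] is not None

    def test_malformed_tree_becomes_missing_row(self):
        taxa = quartet_map(A=["a1"], B=["b1"], C=["c1"], D=["d1"])
        bad = parse_newick("((a1,b1),(c1,zz));")  # unknown sample
        with pytest.warns(UserWarning, match="missing row"):
            track = weight_tree_stream(
                [parse_newick("((a1,b1),(c1,d1));"), bad], taxa
            )
        assert track.records[1] is None

    def test_allow_missing_drops_absent_samples(self):
        taxa = quartet_map(A=["a1", "a2"], B=["b1"], C=["c1"], D=["d1"])
        tree = parse_newick("((a1,b1),(c1,d1));")  # a2 absent
        track = weight_tree_stream([tree], taxa, allow_missing=True)
        assert track.records[0] is not None
        assert track.records[0].n_combinations == 1
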